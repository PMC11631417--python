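"""Directional dominance and kinship-corrected marker scans.

The homozygosity-covariate mixed model quantifies directional dominance
(inbreeding depression) in a single regression coefficient:

    Y = mu + beta Ho [+ beta2 Ho^2] + A + D + eps,
    A ~ N(0, K_A s2_A),  D ~ N(0, K_D s2_D),  eps ~ N(0, I s2_eps),

where Ho is individual homozygosity (1 - observed heterozygosity) and
K_A / K_D the additive and dominance genomic kernels.  Under predominantly
positive dominance deviations, increasing homozygosity depresses the trait
and beta is negative.  The degree-1 vs degree-2 comparison uses
maximum-likelihood (not REML) likelihoods, since the models differ in their
fixed effects.

The marker scan tests each SNP's additive (dosage) effect in a mixed model
with the additive kernel; variance components are estimated once under the
null model and reused for every marker (the population-parameters-
previously-determined approximation), with exact per-marker REML available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genotypes import GenotypeMatrix
from .metrics import RelationshipMatrix
from .reml import MixedModel, MixedModelResults, RandomTerm, factor_kernel


class HodModel:
    """Homozygosity-covariate genomic mixed model.

    Parameters
    ----------
    y : per-individual response (trait EMM, BPH, or MPH), pandas Series
        indexed by individual.
    ho : per-individual homozygosity (1 - observed heterozygosity).
    K_A, K_D : additive and dominance relationship matrices (K_D optional).
    degree : 1 for a linear Ho covariate, 2 to add Ho^2.

    The Ho covariate is centred before fitting for numerical stability
    (slopes are unaffected).  A constant Ho covariate is dropped with a
    warning.
    """

    def __init__(self, y: pd.Series, ho: pd.Series,
                 K_A: RelationshipMatrix, K_D: RelationshipMatrix | None = None,
                 degree: int = 1):
        if degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        common = [s for s in y.index if s in set(ho.index)]
        yv = y.loc[common].to_numpy(float)
        hv = ho.loc[common].to_numpy(float)
        keep = np.isfinite(yv) & np.isfinite(hv)
        self.ids = [c for c, k in zip(common, keep) if k]
        self.y = yv[keep]
        hv = hv[keep]
        self.degree = degree
        self.has_ho = np.ptp(hv) > 0
        if not self.has_ho:
            import warnings

            warnings.warn("constant Ho covariate dropped")
            X = np.ones((len(self.y), 1))
            fe = ["mu"]
        else:
            hc = hv - hv.mean()
            cols = [np.ones(len(self.y)), hc]
            fe = ["mu", "Ho"]
            if degree == 2:
                cols.append(hc**2)
                fe.append("Ho2")
            X = np.column_stack(cols)
        terms = [RandomTerm("additive", Z=factor_kernel(K_A.align(self.ids)))]
        if K_D is not None:
            terms.append(RandomTerm("dominance",
                                    Z=factor_kernel(K_D.align(self.ids))))
        self._mm = MixedModel(self.y, X, terms, fe_names=fe)

    def fit(self, reml: bool = True, **kwargs) -> "HodResults":
        return HodResults(self, self._mm.fit(reml=reml, **kwargs))


@dataclass
class HodResults:
    """Fitted homozygosity-covariate model."""

    model: HodModel
    mixed: MixedModelResults = field(repr=False)

    @property
    def params(self) -> pd.Series:
        return self.mixed.params

    @property
    def llf(self) -> float:
        return self.mixed.llf

    @property
    def converged(self) -> bool:
        return self.mixed.converged

    def coef(self, name: str) -> tuple[float, float]:
        """(estimate, SE) of a fixed effect by name ('Ho', 'Ho2', 'mu')."""
        i = self.model._mm.fe_names.index(name)
        return (float(self.mixed.fe_params[i]),
                float(np.sqrt(self.mixed.cov_fe_params[i, i])))

    @property
    def beta_ho(self) -> float:
        return self.coef("Ho")[0]

    def wald_p(self, name: str) -> float:
        est, se = self.coef(name)
        return float(2.0 * stats.norm.sf(abs(est / se))) if se > 0 else np.nan

    def summary(self) -> str:
        head = f"Homozygosity-dominance model (degree {self.model.degree})\n"
        return head + self.mixed.summary()


def compare_degree(fit1: HodResults, fit2: HodResults) -> dict:
    """Likelihood-ratio comparison of the degree-1 vs degree-2 Ho models.

    The models differ in fixed effects, so maximum-likelihood (not REML)
    log-likelihoods are used; fits are redone at ML if needed.  Returns the
    chi-square statistic (1 df), its p-value, and both ML log-likelihoods.
    """
    if fit1.model.degree != 1 or fit2.model.degree != 2:
        raise ValueError("pass the degree-1 fit first and the degree-2 fit second")
    if fit1.model.ids != fit2.model.ids:
        raise ValueError("fits use different data")
    ll1 = fit1.llf if fit1.mixed.method == "ml" else fit1.model._mm.fit(reml=False).llf
    ll2 = fit2.llf if fit2.mixed.method == "ml" else fit2.model._mm.fit(reml=False).llf
    stat = max(0.0, 2.0 * (ll2 - ll1))
    return {"statistic": float(stat),
            "p_value": float(stats.chi2.sf(stat, 1)),
            "ml_llf_degree1": float(ll1), "ml_llf_degree2": float(ll2)}


@dataclass
class ScanResult:
    """Per-marker additive-effect scan."""

    table: pd.DataFrame  # marker_id, chrom, pos, effect, se, p_value, significant
    threshold: float
    null_components: pd.Series | None = None

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def marker_scan(y: pd.Series, G: GenotypeMatrix, K_A: RelationshipMatrix,
                threshold: float = 5e-8, exact: bool = False) -> ScanResult:
    """Kinship-corrected additive-effect scan over all markers.

    y is a per-individual response (e.g. trait EMMs) indexed by individual;
    only individuals present in both y and G are used.  Monomorphic markers
    are skipped (nan rows).  With exact=True the variance components are
    re-estimated by REML for every marker instead of being fixed at their
    null-model values.
    """
    ids = [s for s in G.ids if s in set(y.index) and np.isfinite(y[s])]
    if len(ids) < 3:
        raise ValueError("need >= 3 phenotyped, genotyped individuals")
    sub = G.subset(individuals=ids)
    yv = y.loc[ids].to_numpy(float)
    K = K_A.align(ids)
    Zk = factor_kernel(K)
    null = MixedModel(yv, np.ones((len(ids), 1)),
                      [RandomTerm("additive", Z=Zk)]).fit()
    d = sub.dosage_float()
    p = sub.allele_frequencies()
    fill = 2.0 * p
    miss = np.isnan(d)
    d[miss] = fill[np.where(miss)[1]]
    mono = ~(np.isfinite(p) & (p > 0) & (p < 1))
    if exact:
        eff = np.full(sub.n_markers, np.nan)
        se = np.full(sub.n_markers, np.nan)
        for j in range(sub.n_markers):
            if mono[j]:
                continue
            X = np.column_stack([np.ones(len(ids)), d[:, j]])
            r = MixedModel(yv, X, [RandomTerm("additive", Z=Zk)]).fit()
            eff[j] = r.fe_params[1]
            se[j] = np.sqrt(r.cov_fe_params[1, 1])
    else:
        # P3D: V fixed at null-model components
        V = (null.params["additive"] * K
             + null.params["residual"] * np.eye(len(ids)))
        Vinv = linalg.cho_solve(linalg.cho_factor(V), np.eye(len(ids)))
        one = np.ones(len(ids))
        Vi1 = Vinv @ one
        P0 = Vinv - np.outer(Vi1, Vi1) / float(one @ Vi1)
        xPy = d.T @ (P0 @ yv)
        xPx = np.einsum("nm,nm->m", d, P0 @ d)
        with np.errstate(divide="ignore", invalid="ignore"):
            eff = np.where(xPx > 0, xPy / xPx, np.nan)
            se = np.where(xPx > 0, np.sqrt(1.0 / xPx), np.nan)
        eff[mono] = np.nan
        se[mono] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        z = eff / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    table = sub.markers[["marker_id", "chrom", "pos"]].copy()
    table["effect"] = eff
    table["se"] = se
    table["p_value"] = pval
    table["significant"] = pval < threshold
    return ScanResult(table, threshold, null.params)


def effect_comparison(scan_subset: ScanResult, scan_full: ScanResult) -> dict:
    """Paired comparison of absolute marker effects between two scans.

    Typically scan_subset is the within-group (e.g. elite-only) scan and
    scan_full includes the wide hybrids.  Marker sets are intersected (with
    a warning if they differ).  Returns the per-marker |effect| differences
    and a sign-test summary of whether the full scan yields larger
    magnitudes.
    """
    a = scan_subset.table.set_index("marker_id")
    b = scan_full.table.set_index("marker_id")
    common = a.index.intersection(b.index)
    if len(common) != len(a) or len(common) != len(b):
        import warnings

        warnings.warn("marker sets differ; intersecting")
    ea = a.loc[common, "effect"].to_numpy()
    eb = b.loc[common, "effect"].to_numpy()
    ok = np.isfinite(ea) & np.isfinite(eb)
    diff = np.abs(eb[ok]) - np.abs(ea[ok])
    nz = diff != 0
    n_larger = int((diff[nz] > 0).sum())
    n_tot = int(nz.sum())
    test = stats.binomtest(n_larger, n_tot, 0.5, alternative="greater") \
        if n_tot else None
    return {
        "markers": pd.DataFrame({"marker_id": common[ok],
                                 "abs_effect_diff": diff}),
        "n_full_larger": n_larger,
        "n_compared": n_tot,
        "sign_test_p": float(test.pvalue) if test else np.nan,
        "median_diff": float(np.median(diff)) if len(diff) else np.nan,
    }
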