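"""REML analysis of the multi-year clonal trial.

The across-year model for one trait is

    y = genotype + block + year + genotype x year + residual,

with genotype fixed when the goal is estimated marginal means (EMMs) and
random when the goal is the among-genotype variance and clone-mean
broad-sense heritability

    H^2 = sigma2_G / (sigma2_G + sigma2_GxY / y + sigma2_E / (r y)),

where y is the number of years and r the harmonic-mean realized replication
per genotype.  Narrow-sense heritability and additive genetic correlations
come from genomic-kernel mixed models fitted to the EMMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import RelationshipMatrix
from .reml import MixedModel, MixedModelResults, RandomTerm, design_matrix, factor_kernel

REQUIRED_COLUMNS = ("individual", "block", "year", "trait", "value")


def prepare_plot_data(records: pd.DataFrame, trait: str,
                      aggregate: str = "mean") -> pd.DataFrame:
    """Plot-level data for one trait.

    Harvest-level rows (a ``harvest`` column) are aggregated to one value per
    individual x year x block: season totals ("sum", for yield-like traits)
    or season means ("mean", for quality-like traits).
    """
    for c in REQUIRED_COLUMNS:
        if c not in records.columns:
            raise ValueError(f"phenotype records missing column {c!r}")
    df = records[records["trait"] == trait].copy()
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    if "harvest" in df.columns:
        agg = "sum" if aggregate == "sum" else "mean"
        df = (df.groupby(["individual", "year", "block"], as_index=False)
                .agg(value=("value", agg)))
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    return df


@dataclass
class EMMTable:
    """Estimated marginal means with their sampling covariance."""

    trait: str
    frame: pd.DataFrame  # index: individual; columns: estimate, se
    cov: np.ndarray = field(repr=False)
    df_resid: float = np.inf

    @property
    def individuals(self) -> list[str]:
        return list(self.frame.index)

    def contrast(self, coefs: dict[str, float]):
        """Estimate and SE of a linear combination of EMMs."""
        c = np.zeros(len(self.frame))
        idx = {s: i for i, s in enumerate(self.frame.index)}
        for s, w in coefs.items():
            c[idx[s]] = w
        est = float(c @ self.frame["estimate"].to_numpy())
        se = float(np.sqrt(c @ self.cov @ c))
        return est, se


class TrialModel:
    """Linear mixed model for one trait of a clonal trial.

    Parameters
    ----------
    records : long-format phenotype table (individual, block, year,
        [harvest,] trait, value).
    trait : trait name to analyze.
    genotype_as : "fixed" (for EMMs and contrasts) or "random" (for the
        among-genotype variance and H^2).
    aggregate : harvest aggregation rule, "sum" or "mean".
    """

    def __init__(self, records: pd.DataFrame, trait: str,
                 genotype_as: str = "fixed", aggregate: str = "mean"):
        if genotype_as not in ("fixed", "random"):
            raise ValueError("genotype_as must be 'fixed' or 'random'")
        self.trait = trait
        self.genotype_as = genotype_as
        self.data = prepare_plot_data(records, trait, aggregate)
        self.n_years = self.data["year"].nunique()
        self.n_blocks = self.data["block"].nunique()
        y = self.data["value"].to_numpy(float)
        terms = []
        if self.n_blocks >= 2:
            Zb, _ = design_matrix(self.data["block"])
            terms.append(RandomTerm("block", Z=Zb))
        if self.n_years >= 2:
            Zy, _ = design_matrix(self.data["year"])
            terms.append(RandomTerm("year", Z=Zy))
        gy = self.data["individual"].astype(str) + ":" + self.data["year"].astype(str)
        if self.n_years >= 2:
            Zgy, _ = design_matrix(gy)
            terms.append(RandomTerm("gxy", Z=Zgy))
        if genotype_as == "fixed":
            Xg, self.genotypes = design_matrix(self.data["individual"])
            X, fe_names = Xg, list(self.genotypes)
        else:
            Zg, self.genotypes = design_matrix(self.data["individual"])
            terms.insert(0, RandomTerm("genotype", Z=Zg))
            X, fe_names = np.ones((len(y), 1)), ["intercept"]
        self._mm = MixedModel(y, X, terms, fe_names=fe_names)

    def fit(self, **kwargs) -> "TrialResults":
        return TrialResults(self, self._mm.fit(**kwargs))


@dataclass
class TrialResults:
    """Fitted trial model: variance components, EMMs, heritability."""

    model: TrialModel
    mixed: MixedModelResults = field(repr=False)

    @property
    def variance_components(self) -> pd.Series:
        return self.mixed.params

    @property
    def converged(self) -> bool:
        return self.mixed.converged

    @property
    def llf(self) -> float:
        return self.mixed.llf

    def harmonic_mean_reps(self) -> float:
        """Harmonic mean over genotypes of plots per genotype per year."""
        d = self.model.data
        per = d.groupby("individual").size() / self.model.n_years
        return float(len(per) / (1.0 / per).sum())

    def emms(self) -> EMMTable:
        """Per-genotype estimated marginal means averaging over years.

        Requires genotype fitted as fixed; the cell-means coding makes each
        fixed-effect coefficient the genotype's marginal mean, and the GLS
        coefficient covariance supplies contrast SEs.
        """
        if self.model.genotype_as != "fixed":
            raise ValueError("EMMs require genotype fitted as a fixed effect")
        est = self.mixed.fe_params
        cov = self.mixed.cov_fe_params
        se = np.sqrt(np.diag(cov))
        frame = pd.DataFrame({"estimate": est, "se": se},
                             index=self.model.genotypes)
        frame.index.name = "individual"
        df_resid = self.model.data.shape[0] - len(est)
        return EMMTable(self.model.trait, frame, cov, df_resid)

    def broad_sense_heritability(self, n_years: int | None = None,
                                 reps: float | None = None) -> float:
        """Clone-mean H^2 from the genotype-random fit."""
        vc = self.variance_components
        if "genotype" not in vc:
            raise ValueError("H^2 requires genotype fitted as random")
        y = n_years if n_years is not None else self.model.n_years
        r = reps if reps is not None else self.harmonic_mean_reps()
        return broad_sense_heritability(
            vc["genotype"], vc.get("gxy", 0.0), vc["residual"], y, r)

    def summary(self) -> str:
        head = (f"Trial LMM: trait={self.model.trait!r}, "
                f"genotype as {self.model.genotype_as}\n")
        return head + self.mixed.summary()


def broad_sense_heritability(var_g: float, var_gxy: float, var_e: float,
                             n_years: int, reps: float) -> float:
    """H^2 = s2_G / (s2_G + s2_GxY/y + s2_E/(r*y)) on a clone-mean basis."""
    if n_years < 1 or reps <= 0:
        raise ValueError("need n_years >= 1 and reps > 0")
    phen = var_g + var_gxy / n_years + var_e / (reps * n_years)
    if phen <= 0:
        raise ValueError("zero phenotypic variance")
    return float(var_g / phen)


def narrow_sense_heritability(emms: EMMTable, K_A: RelationshipMatrix):
    """h^2 = s2_A / (s2_A + s2_resid) from a single-kernel model on EMMs.

    Returns (h2, MixedModelResults).
    """
    ids = emms.individuals
    K = K_A.align(ids)
    y = emms.frame["estimate"].to_numpy(float)
    Z = factor_kernel(K)
    mm = MixedModel(y, np.ones((len(y), 1)), [RandomTerm("additive", Z=Z)],
                    fe_names=["intercept"])
    res = mm.fit()
    s2a = res.params["additive"]
    h2 = float(s2a / (s2a + res.params["residual"]))
    return h2, res


def genetic_correlation(emms1: EMMTable, emms2: EMMTable,
                        K_A: RelationshipMatrix):
    """Additive genetic correlation between two traits' EMMs.

    Both traits are mean-centred and scaled to unit variance, stacked, and
    fitted with an unstructured 2x2 additive covariance (kernel K_A) plus an
    unstructured residual.  After scaling the additive covariance estimate is
    the genetic correlation; its p-value is the upper-tail standard-normal
    probability of the Z-ratio (estimate / asymptotic SE).

    Returns dict with r_G, se, z, p_value, converged, fallback flag.
    """
    common = [s for s in emms1.individuals if s in set(emms2.individuals)]
    if len(common) < 3:
        raise ValueError("need >= 3 common individuals")
    y1 = emms1.frame.loc[common, "estimate"].to_numpy(float)
    y2 = emms2.frame.loc[common, "estimate"].to_numpy(float)
    z1 = (y1 - y1.mean()) / y1.std()
    z2 = (y2 - y2.mean()) / y2.std()
    n = len(common)
    raw = float(np.corrcoef(z1, z2)[0, 1])
    if abs(raw) > 1.0 - 1e-9:
        # affinely identical traits: the bivariate covariance is singular and
        # the genetic correlation is the degenerate +/-1
        return {"r_G": float(np.sign(raw)), "se": 0.0,
                "z": np.inf * np.sign(raw), "p_value": 0.0 if raw > 0 else 1.0,
                "converged": True, "fallback": False, "results": None}
    K = K_A.align(common)
    y = np.concatenate([z1, z2])
    X = np.zeros((2 * n, 2))
    X[:n, 0] = 1.0
    X[n:, 1] = 1.0
    zero = np.zeros((n, n))
    A11 = np.block([[K, zero], [zero, zero]])
    A22 = np.block([[zero, zero], [zero, K]])
    A12 = np.block([[zero, K], [K, zero]])
    D1 = np.diag(np.concatenate([np.ones(n), np.zeros(n)]))
    D2 = np.diag(np.concatenate([np.zeros(n), np.ones(n)]))
    eye = np.eye(n)
    R12 = np.block([[zero, eye], [eye, zero]])
    terms = [
        RandomTerm("A11", cov=A11),
        RandomTerm("A22", cov=A22),
        RandomTerm("A12", cov=A12, nonneg=False),
        RandomTerm("R1", cov=D1),
        RandomTerm("R2", cov=D2),
        RandomTerm("R12", cov=R12, nonneg=False),
    ]
    mm = MixedModel(y, X, terms, fe_names=["mu1", "mu2"])
    try:
        res = mm.fit()
        ok = res.converged
    except Exception:
        res, ok = None, False
    if ok and res.cov_params is not None:
        sa1, sa2, sa12 = (res.params["A11"], res.params["A22"],
                          res.params["A12"])
        denom = np.sqrt(max(sa1, 1e-12) * max(sa2, 1e-12))
        r_g = float(sa12 / denom)
        se = float(np.sqrt(max(res.cov_params.loc["A12", "A12"], 0.0)))
        z = sa12 / se if se > 0 else np.inf * np.sign(sa12)
        return {"r_G": r_g, "se": se, "z": float(z),
                "p_value": float(stats.norm.sf(z)), "converged": True,
                "fallback": False, "results": res}
    # method-of-moments fallback: correlation of per-trait additive BLUPs
    b1 = _additive_blup(z1, K)
    b2 = _additive_blup(z2, K)
    r_g = float(np.corrcoef(b1, b2)[0, 1])
    zr = np.arctanh(np.clip(r_g, -0.999999, 0.999999)) * np.sqrt(max(n - 3, 1))
    return {"r_G": r_g, "se": np.nan, "z": float(zr),
            "p_value": float(stats.norm.sf(zr)), "converged": False,
            "fallback": True, "results": res}


def _additive_blup(z: np.ndarray, K: np.ndarray) -> np.ndarray:
    Zf = factor_kernel(K)
    res = MixedModel(z, np.ones((len(z), 1)),
                     [RandomTerm("additive", Z=Zf)]).fit()
    return res.blup_individual("additive")
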