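"""Per-individual and population genotype summaries.

Observed heterozygosity Ho_i = n_het,i / n_nonmissing,i; inbreeding either as
F = 1 - Ho (the estimate used for headline results on array calls) or as the
excess-homozygosity form F = (O_hom - E_hom) / (m - E_hom); effective
population size from one-generation heterozygosity decay
Ne = -1 / (2 ln(H1/H0)); VanRaden additive and classical dominance
relationship matrices; PCA of centred dosages; QC filters; segregation tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class QCReport:
    """Counts of samples/markers dropped by each filter rule."""

    n_samples_in: int
    n_markers_in: int
    samples_dropped_call_rate: int
    markers_dropped_maf: int
    markers_dropped_missing: int
    n_samples_out: int
    n_markers_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass
class RelationshipMatrix:
    """Symmetric genomic relationship matrix keyed by individual IDs."""

    kind: str  # "additive" | "dominance"
    ids: list[str]
    values: np.ndarray = field(repr=False)
    scaling: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape inconsistent with IDs")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        self.values = 0.5 * (v + v.T)

    def align(self, ids: list[str]) -> np.ndarray:
        idx = [self.ids.index(s) for s in ids]
        return self.values[np.ix_(idx, idx)]


def filter_markers_and_samples(G: GenotypeMatrix, maf_min: float = 0.05,
                               max_missing: float = 0.10,
                               min_call_rate: float = 0.90):
    """QC filter: drop low-call-rate samples first, then markers failing the
    minor-allele-frequency or missing-data thresholds.

    Returns (filtered GenotypeMatrix, QCReport).
    """
    for t in (maf_min, max_missing, min_call_rate):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must be in [0,1]")
    nonmiss = G.calls != MISSING
    call_rate = nonmiss.mean(axis=1)
    keep_s = call_rate > min_call_rate if min_call_rate > 0 else call_rate >= 0
    # spec of the rule: samples with call-rate greater than the threshold retained
    kept_ids = [s for s, k in zip(G.ids, keep_s) if k]
    G1 = G.subset(individuals=kept_ids) if len(kept_ids) < G.n_individuals else G
    if G1.n_individuals == 0:
        raise ValueError("no samples survive the call-rate filter")
    freq = G1.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    miss_frac = (G1.calls == MISSING).mean(axis=0)
    fail_maf = ~(maf >= maf_min)  # nan (all-missing marker) fails too
    fail_miss = miss_frac > max_missing
    keep_m = ~(fail_maf | fail_miss)
    report = QCReport(
        n_samples_in=G.n_individuals,
        n_markers_in=G.n_markers,
        samples_dropped_call_rate=int((~keep_s).sum()),
        markers_dropped_maf=int(fail_maf.sum()),
        markers_dropped_missing=int((fail_miss & ~fail_maf).sum()),
        n_samples_out=G1.n_individuals,
        n_markers_out=int(keep_m.sum()),
    )
    if report.n_markers_out == 0:
        raise ValueError("no markers survive filtering")
    return G1.subset(marker_mask=keep_m), report


def observed_heterozygosity(G: GenotypeMatrix) -> pd.Series:
    """Ho per individual: fraction of nonmissing calls that are heterozygous.

    Individuals with no nonmissing calls get nan (flagged with a warning).
    """
    nonmiss = (G.calls != MISSING).sum(axis=1)
    het = (G.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)
    if (nonmiss == 0).any():
        warnings.warn("individual(s) with all calls missing: Ho undefined")
    return pd.Series(ho, index=G.ids, name="Ho")


def inbreeding_coefficient(G: GenotypeMatrix, method: str = "one_minus_H"
                           ) -> pd.Series:
    """Per-individual inbreeding coefficient.

    method="one_minus_H": F_i = 1 - Ho_i (the array-call headline estimate).
    method="excess_homozygosity": F_i = (O_hom,i - E_hom,i) / (m_i - E_hom,i)
    with E_hom,i = sum over the individual's nonmissing markers of
    (1 - 2 p_j q_j), allele frequencies taken from the analyzed panel.
    """
    if method == "one_minus_H":
        return (1.0 - observed_heterozygosity(G)).rename("F")
    if method != "excess_homozygosity":
        raise ValueError(f"unknown method {method!r}")
    if G.n_individuals < 2:
        raise ValueError("excess-homozygosity F needs >= 2 individuals")
    p = G.allele_frequencies()
    two_pq = 2.0 * p * (1.0 - p)
    nonmiss = G.calls != MISSING
    m_i = nonmiss.sum(axis=1).astype(float)
    o_hom = ((G.calls == 0) | (G.calls == 2)).sum(axis=1).astype(float)
    e_hom = nonmiss @ np.nan_to_num(1.0 - two_pq)
    denom = m_i - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, (o_hom - e_hom) / denom, np.nan)
    if (denom <= 0).any():
        warnings.warn("nonpositive denominator in excess-homozygosity F; flagged nan")
    return pd.Series(f, index=G.ids, name="F")


def expected_heterozygosity(G: GenotypeMatrix) -> float:
    """Population expected heterozygosity: mean of 2 p_j q_j over markers."""
    p = G.allele_frequencies()
    return float(np.nanmean(2.0 * p * (1.0 - p)))


def effective_population_size(H0: float, H1: float) -> float:
    """Ne from one-generation heterozygosity decay: Ne = -1 / (2 ln(H1/H0)).

    H1 >= H0 (no decay) returns +inf with a warning.
    """
    if H0 <= 0 or H1 <= 0:
        raise ValueError("heterozygosities must be positive")
    if H1 >= H0:
        warnings.warn("H1 >= H0: no heterozygosity decay, Ne is not finite")
        return float("inf")
    return -1.0 / (2.0 * np.log(H1 / H0))


def _imputed_dosage(G: GenotypeMatrix):
    """Dosages with per-marker mean imputation of missing calls."""
    d = G.dosage_float()
    p = G.allele_frequencies()
    fill = 2.0 * p
    idx = np.where(np.isnan(d))
    d[idx] = fill[idx[1]]
    return d, p


def additive_grm(G: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden method-1 GRM: K = W W' / (2 sum p_j q_j), W = dosage - 2p."""
    if G.n_individuals < 2:
        raise ValueError("GRM needs >= 2 individuals")
    d, p = _imputed_dosage(G)
    ok = np.isfinite(p) & (p > 0) & (p < 1)
    if not ok.any():
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    w = d[:, ok] - 2.0 * p[ok]
    denom = 2.0 * float(np.sum(p[ok] * (1.0 - p[ok])))
    return RelationshipMatrix("additive", list(G.ids), w @ w.T / denom, denom)


def dominance_grm(G: GenotypeMatrix) -> RelationshipMatrix:
    """Classical (mean-centred) dominance relationship matrix.

    Per-marker covariate -2p^2, 2pq, -2q^2 for counted-allele dosages 0, 1, 2
    (p the counted-allele frequency; equivalently -2q^2, 2pq, -2p^2 with p the
    dosage-0 allele's frequency).  Under HWE the covariate has mean zero, so
    missing calls impute to 0.  K_D = D D' / sum (2 p_j q_j)^2.
    """
    if not (G.calls == 1).any():
        raise ValueError("fully homozygous panel: no dominance information")
    p = G.allele_frequencies()
    ok = np.isfinite(p) & (p > 0) & (p < 1)
    if not ok.any():
        raise ValueError("all markers monomorphic: dominance denominator is zero")
    pj = p[ok]
    qj = 1.0 - pj
    calls = G.calls[:, ok]
    shape = calls.shape
    cov = np.select(
        [calls == 0, calls == 1, calls == 2],
        [np.broadcast_to(-2.0 * pj**2, shape),
         np.broadcast_to(2.0 * pj * qj, shape),
         np.broadcast_to(-2.0 * qj**2, shape)],
        default=0.0,
    )
    denom = float(np.sum((2.0 * pj * qj) ** 2))
    return RelationshipMatrix("dominance", list(G.ids), cov @ cov.T / denom, denom)


def pca_scores(G: GenotypeMatrix, n_components: int = 10):
    """PCA of the centred dosage matrix.

    Scores come from the eigendecomposition of the centred Gram matrix
    (equivalent to the SVD of the centred dosages, cheaper when markers
    greatly outnumber individuals).  Sign convention: within each component
    the largest-magnitude score is made positive, so results are
    deterministic across runs.

    Returns (scores DataFrame indexed by individual, variance-explained array).
    """
    n = G.n_individuals
    if n_components > n:
        raise ValueError("more components requested than individuals")
    d, _ = _imputed_dosage(G)
    w = d - d.mean(axis=0)
    gram = w @ w.T
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:n_components]
    vals_k = np.clip(vals[order], 0.0, None)
    scores = vecs[:, order] * np.sqrt(vals_k)
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(scores[:, k]))
        if scores[j, k] < 0:
            scores[:, k] = -scores[:, k]
    total = np.clip(vals, 0.0, None).sum()
    var_explained = vals_k / total if total > 0 else np.zeros_like(vals_k)
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return pd.DataFrame(scores, index=G.ids, columns=cols), var_explained


def segregation_test(observed_counts, expected_ratio):
    """Pearson chi-square goodness of fit of counts against a ratio (e.g. 3:1).

    Returns (chi2 statistic, p-value).
    """
    obs = np.asarray(observed_counts, float)
    ratio = np.asarray(expected_ratio, float)
    if (obs < 0).any() or (ratio <= 0).any():
        raise ValueError("counts must be >= 0 and ratio positive")
    total = obs.sum()
    if total == 0:
        raise ValueError("zero total count")
    exp = total * ratio / ratio.sum()
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    p = float(stats.chi2.sf(chi2, df=len(obs) - 1))
    return chi2, p


def diversity_summary(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual Ho and F (both estimators) plus panel E(H)."""
    ho = observed_heterozygosity(G)
    f1 = inbreeding_coefficient(G, "one_minus_H")
    f2 = inbreeding_coefficient(G, "excess_homozygosity")
    out = pd.DataFrame({"Ho": ho, "F_one_minus_H": f1, "F_excess_hom": f2})
    out.attrs["expected_heterozygosity"] = expected_heterozygosity(G)
    return out
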