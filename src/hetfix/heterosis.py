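"""Mid-, best-, and worst-parent heterosis from trial EMMs.

For a hybrid with parental EMMs ybar_P1, ybar_P2 and hybrid EMM ybar_F1:

    MPH = ybar_F1 - (ybar_P1 + ybar_P2) / 2        %MPH = 100 MPH / ybar_MP
    BPH = ybar_F1 - ybar_BP                        %BPH = 100 BPH / ybar_BP
    WPC = ybar_F1 - ybar_WP  (worst-parent contrast)

The best parent of an elite x elite hybrid is the parent with the greater
EMM; for an elite x exotic hybrid the elite parent is "best" by definition
(the exotic parent is a donor being screened for dispersed favorable
alleles, not a commercial benchmark).  Contrast SEs are Wald SEs from the
EMM sampling covariance; when only marginal SEs are available parent and
hybrid EMM errors are treated as independent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .reml import MixedModel, RandomTerm, factor_kernel
from .trial import EMMTable

CLASS_NEG = "significantly negative"
CLASS_NS = "not significant"
CLASS_POS = "significantly positive"


def best_parent(emm_p1: float, emm_p2: float, cross_class: str,
                ids: tuple[str, str] | None = None):
    """Best- and worst-parent EMMs under the cross-class rule.

    For "elite_x_exotic" crosses parent 1 must be the elite parent and is
    best regardless of the means.  Ties in elite x elite are broken
    deterministically by ID order and flagged.

    Returns (best, worst, tie_flag).
    """
    if cross_class == "elite_x_exotic":
        return emm_p1, emm_p2, False
    if np.isnan(emm_p1) or np.isnan(emm_p2):
        raise ValueError("elite x elite best parent needs both parent EMMs")
    if emm_p1 == emm_p2:
        if ids is not None and ids[1] < ids[0]:
            return emm_p2, emm_p1, True
        return emm_p1, emm_p2, True
    if emm_p1 > emm_p2:
        return emm_p1, emm_p2, False
    return emm_p2, emm_p1, False


def heterosis_contrasts(emms: EMMTable, pedigree: pd.DataFrame,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-hybrid MPH/BPH/worst-parent contrasts with Wald tests.

    Parameters
    ----------
    emms : EMMTable for one trait.
    pedigree : DataFrame with columns ``child, parent1, parent2, group``
        where group contains the cross class ("elite_x_elite" or
        "elite_x_exotic"); for elite x exotic rows parent1 is the elite
        parent.  Founder rows (missing parents) are skipped.

    MPH requires both parent EMMs; BPH is still computed whenever the rule
    defines a best parent (the elite parent of an elite x exotic hybrid may
    be phenotyped while the exotic one is not).
    """
    have = set(emms.individuals)
    est = emms.frame["estimate"]
    rows = []
    for rec in pedigree.itertuples(index=False):
        child, p1, p2, grp = rec.child, rec.parent1, rec.parent2, rec.group
        if grp not in ("elite_x_elite", "elite_x_exotic"):
            continue
        if child not in have:
            continue
        yf1 = est[child]
        e1 = est[p1] if p1 in have else np.nan
        e2 = est[p2] if p2 in have else np.nan
        out = {"hybrid": child, "parent1": p1, "parent2": p2,
               "cross_class": grp, "f1": yf1}
        # MPH
        if np.isfinite(e1) and np.isfinite(e2):
            mp = 0.5 * (e1 + e2)
            mph, mph_se = emms.contrast({child: 1.0, p1: -0.5, p2: -0.5})
            out.update(mph=mph, pct_mph=100.0 * mph / mp if mp != 0 else np.nan,
                       mph_se=mph_se,
                       mph_p=_wald_p(mph, mph_se, emms.df_resid))
        else:
            out.update(mph=np.nan, pct_mph=np.nan, mph_se=np.nan, mph_p=np.nan)
        # BPH / worst parent
        bp_id = wp_id = None
        tie = False
        if grp == "elite_x_exotic":
            if np.isfinite(e1):
                bp_id = p1
                wp_id = p2 if np.isfinite(e2) else None
        else:
            if np.isfinite(e1) and np.isfinite(e2):
                bp, wp, tie = best_parent(e1, e2, grp, (p1, p2))
                bp_id = p1 if (e1 == bp and not (tie and p2 < p1)) else p2
                wp_id = p2 if bp_id == p1 else p1
        if bp_id is not None:
            ybp = est[bp_id]
            bph, bph_se = emms.contrast({child: 1.0, bp_id: -1.0})
            if ybp == 0:
                warnings.warn("best-parent EMM is zero: %BPH undefined")
            out.update(best_parent=bp_id, bp=ybp, bph=bph,
                       pct_bph=100.0 * bph / ybp if ybp != 0 else np.nan,
                       bph_se=bph_se,
                       bph_p=_wald_p(bph, bph_se, emms.df_resid),
                       bp_tie=tie)
        else:
            out.update(best_parent=None, bp=np.nan, bph=np.nan, pct_bph=np.nan,
                       bph_se=np.nan, bph_p=np.nan, bp_tie=False)
        if wp_id is not None:
            wpc, wpc_se = emms.contrast({child: 1.0, wp_id: -1.0})
            out.update(worst_parent=wp_id, wp=est[wp_id], wpc=wpc,
                       wpc_se=wpc_se,
                       wpc_p=_wald_p(wpc, wpc_se, emms.df_resid))
        else:
            out.update(worst_parent=None, wp=np.nan, wpc=np.nan,
                       wpc_se=np.nan, wpc_p=np.nan)
        rows.append(out)
    recs = pd.DataFrame(rows)
    if not recs.empty:
        for kind in ("mph", "bph", "wpc"):
            recs[f"{kind}_class"] = [
                _classify(v, p, alpha)
                for v, p in zip(recs[kind], recs[f"{kind}_p"])]
    return recs


def _wald_p(est: float, se: float, df: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return np.nan
    t = est / se
    if np.isinf(df):
        return float(2.0 * stats.norm.sf(abs(t)))
    return float(2.0 * stats.t.sf(abs(t), df))


def _classify(value: float, p: float, alpha: float) -> str | float:
    if not np.isfinite(value) or not np.isfinite(p):
        return np.nan
    if p >= alpha or value == 0:
        return CLASS_NS
    return CLASS_NEG if value < 0 else CLASS_POS


def classify_contrasts(records: pd.DataFrame, alpha: float = 0.05):
    """Summary tables of contrast significance by cross class.

    Returns (mph_bph_table, worst_parent_table):

    * mph_bph_table: per cross class and contrast (MPH, BPH), the percentage
      of hybrids significantly negative / not significant / significantly
      positive at level alpha (the Table-2 shape of a heterosis study);
    * worst_parent_table: per cross class, the percentage of hybrids whose
      EMM is below the worst parent and the percentage significantly below.
    """
    rows = []
    for grp, sub in records.groupby("cross_class"):
        for kind in ("mph", "bph"):
            ok = sub[np.isfinite(sub[kind]) & np.isfinite(sub[f"{kind}_p"])]
            n = len(ok)
            if n == 0:
                continue
            sig = ok[f"{kind}_p"] < alpha
            neg = float(100.0 * ((ok[kind] < 0) & sig).sum() / n)
            pos = float(100.0 * ((ok[kind] > 0) & sig).sum() / n)
            rows.append((grp, kind.upper(), n, neg, 100.0 - neg - pos, pos))
    table2 = pd.DataFrame(
        rows, columns=["cross_class", "contrast", "n",
                       "pct_significantly_negative", "pct_not_significant",
                       "pct_significantly_positive"])
    rows = []
    for grp, sub in records.groupby("cross_class"):
        ok = sub[np.isfinite(sub["wpc"]) & np.isfinite(sub["wpc_p"])]
        n = len(ok)
        if n == 0:
            continue
        below = ok["wpc"] < 0
        sig_below = below & (ok["wpc_p"] < alpha)
        rows.append((grp, n, float(100.0 * below.sum() / n),
                     float(100.0 * sig_below.sum() / n)))
    table3 = pd.DataFrame(
        rows, columns=["cross_class", "n", "pct_below_worst_parent",
                       "pct_significantly_below"])
    return table2, table3


def heterozygosity_regression(response: pd.Series, het: pd.Series,
                              degree: int = 2, K_A=None, K_D=None):
    """Regress a per-hybrid response (EMM, MPH, or BPH) on heterozygosity.

    Fits degree-1 and degree-2 polynomials and tests whether the quadratic
    term improves fit.  Without kernels this is OLS with the exact F-test
    for the nested comparison.  With K_A (and optionally K_D) supplied, the
    same fixed-effect comparison is carried out inside a kernel mixed model
    using a maximum-likelihood ratio test (chi-square, 1 df).

    Returns a dict with coefficients of both fits, the test statistic,
    p-value, and the comparison method.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    common = response.index.intersection(het.index)
    yv = response.loc[common].to_numpy(float)
    hv = het.loc[common].to_numpy(float)
    keep = np.isfinite(yv) & np.isfinite(hv)
    yv, hv = yv[keep], hv[keep]
    n = keep.sum()
    if np.unique(hv).size < degree + 2:
        raise ValueError("too few distinct heterozygosity values")
    ids = [c for c, k in zip(common, keep) if k]
    X1 = np.column_stack([np.ones(n), hv])
    X2 = np.column_stack([np.ones(n), hv, hv**2])
    if K_A is None:
        b1, rss1 = _ols(X1, yv)
        b2, rss2 = _ols(X2, yv)
        df2 = n - 3
        if rss2 <= 0:
            fstat, p = 0.0, 1.0
        else:
            fstat = (rss1 - rss2) / (rss2 / df2)
            p = float(stats.f.sf(fstat, 1, df2))
        return {"coef_linear": b1, "coef_quadratic": b2, "statistic": float(fstat),
                "p_value": p, "method": "ols_f_test", "n": int(n)}
    terms = [RandomTerm("additive", Z=factor_kernel(K_A.align(ids)))]
    if K_D is not None:
        terms.append(RandomTerm("dominance", Z=factor_kernel(K_D.align(ids))))
    f1 = MixedModel(yv, X1, terms, fe_names=["mu", "H"]).fit(reml=False)
    f2 = MixedModel(yv, X2, terms, fe_names=["mu", "H", "H2"]).fit(reml=False)
    lrt = max(0.0, 2.0 * (f2.llf - f1.llf))
    return {"coef_linear": f1.fe_params, "coef_quadratic": f2.fe_params,
            "statistic": float(lrt), "p_value": float(stats.chi2.sf(lrt, 1)),
            "method": "ml_lrt_with_kernels", "n": int(n),
            "fit_linear": f1, "fit_quadratic": f2}


def _ols(X, y):
    b, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    return b, float(resid @ resid)
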