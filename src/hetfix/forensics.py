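"""Duo and trio genotypic transgression ratios for parentage forensics.

A parent and its biological offspring can never carry opposite homozygotes
at a biallelic marker, and an offspring cannot be heterozygous when both
parents are the same homozygote.  Counting such Mendelian-impossible
configurations over a SNP panel gives the duo transgression ratio

    DTR = (1/m) sum_i S_i,   S_i = 1 iff offspring and candidate parent are
                                   opposite homozygotes at marker i,

and the trio transgression ratio

    TTR = (1/m) sum_i [T_i + S1_i + S2_i - S1_i * S2_i],

where T_i = 1 iff the offspring is heterozygous while both candidate parents
are the same homozygote, S1_i/S2_i are the duo scores against each parent,
and the product term prevents double counting when both duos transgress at
the same marker.  True relationships give ratios of exactly 0 on error-free
genotypes; unrelated pairs accumulate transgressions in proportion to the
panel's opposite-homozygote probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class DuoScore:
    offspring: str
    parent: str
    m: int
    dtr: float


@dataclass
class TrioScore:
    offspring: str
    parent1: str
    parent2: str
    m: int
    ttr: float
    sum_t: int
    sum_s1: int
    sum_s2: int
    sum_s1s2: int


def duo_score_marker(g_off: int, g_par: int) -> int:
    """S_i: 1 iff offspring and candidate parent carry opposite homozygotes."""
    if g_off == MISSING or g_par == MISSING:
        raise ValueError("missing call: marker must be excluded from m")
    return int((g_off == 0 and g_par == 2) or (g_off == 2 and g_par == 0))


def trio_score_marker(g_off: int, g_p1: int, g_p2: int) -> int:
    """T_i: 1 iff offspring heterozygous while both parents are the same homozygote."""
    if MISSING in (g_off, g_p1, g_p2):
        raise ValueError("missing call: marker must be excluded from m")
    return int(g_off == 1 and g_p1 == g_p2 and g_p1 in (0, 2))


def _duo_vec(off: np.ndarray, par: np.ndarray) -> np.ndarray:
    return (((off == 0) & (par == 2)) | ((off == 2) & (par == 0)))


def dtr(G: GenotypeMatrix, offspring: str, candidate_parent: str) -> DuoScore:
    """Duo transgression ratio over jointly nonmissing markers."""
    o = G.row(offspring)
    p = G.row(candidate_parent)
    ok = (o != MISSING) & (p != MISSING)
    m = int(ok.sum())
    if m == 0:
        raise ValueError("no jointly nonmissing markers for duo")
    s = _duo_vec(o[ok], p[ok])
    return DuoScore(offspring, candidate_parent, m, float(s.mean()))


def ttr(G: GenotypeMatrix, offspring: str, parent1: str, parent2: str) -> TrioScore:
    """Trio transgression ratio; markers missing in any of the three are
    excluded from m (so duo and trio components share one denominator)."""
    o = G.row(offspring)
    p1 = G.row(parent1)
    p2 = G.row(parent2)
    ok = (o != MISSING) & (p1 != MISSING) & (p2 != MISSING)
    m = int(ok.sum())
    if m == 0:
        raise ValueError("no jointly nonmissing markers for trio")
    o, p1, p2 = o[ok], p1[ok], p2[ok]
    t = (o == 1) & (p1 == p2) & ((p1 == 0) | (p1 == 2))
    s1 = _duo_vec(o, p1)
    s2 = _duo_vec(o, p2)
    summand = t.astype(int) + s1 + s2 - (s1 & s2)
    return TrioScore(offspring, parent1, parent2, m,
                     float(summand.sum() / m),
                     int(t.sum()), int(s1.sum()), int(s2.sum()),
                     int((s1 & s2).sum()))


def all_pairs_dtr(G: GenotypeMatrix, offspring_ids=None, candidate_ids=None
                  ) -> pd.DataFrame:
    """DTR for every (offspring, candidate) pair, vectorized over the panel.

    Self-duos are excluded.
    """
    offspring_ids = list(offspring_ids or G.ids)
    candidate_ids = list(candidate_ids or G.ids)
    sub_o = G.subset(individuals=offspring_ids)
    sub_c = G.subset(individuals=candidate_ids)
    o_h0 = (sub_o.calls == 0).astype(np.float32)
    o_h2 = (sub_o.calls == 2).astype(np.float32)
    c_h0 = (sub_c.calls == 0).astype(np.float32)
    c_h2 = (sub_c.calls == 2).astype(np.float32)
    o_nm = (sub_o.calls != MISSING).astype(np.float32)
    c_nm = (sub_c.calls != MISSING).astype(np.float32)
    s = o_h0 @ c_h2.T + o_h2 @ c_h0.T
    m = o_nm @ c_nm.T
    rows = []
    for i, o in enumerate(offspring_ids):
        for j, c in enumerate(candidate_ids):
            if o == c:
                continue
            mm = m[i, j]
            rows.append((o, c, int(mm), float(s[i, j] / mm) if mm > 0 else np.nan))
    return pd.DataFrame(rows, columns=["offspring", "candidate_parent", "m", "dtr"])


def scan_parentage(G: GenotypeMatrix, claims: pd.DataFrame,
                   threshold: float = 0.01) -> pd.DataFrame:
    """Authenticate pedigree claims and rank candidate parents.

    Parameters
    ----------
    claims : DataFrame with columns ``child, parent1, parent2`` (parents may
        be NA for founders; such rows are skipped).
    threshold : DTR/TTR above which a claimed relationship fails.

    Returns a report with one row per evaluated duo/trio: the claimed duo
    DTRs, the claimed trio TTR, each candidate duo's rank among all
    genotyped candidates (ascending DTR), and pass/fail vs the threshold.
    Ungenotyped claimed parents are reported with status "ungenotyped".
    """
    genotyped = set(G.ids)
    rows = []
    for rec in claims.itertuples(index=False):
        child = rec.child
        parents = [rec.parent1, rec.parent2]
        if child not in genotyped or all(pd.isna(p) for p in parents):
            continue
        candidates = [s for s in G.ids if s != child]
        cand_dtr = {c: dtr(G, child, c).dtr for c in candidates}
        ranked = sorted(cand_dtr, key=lambda c: (cand_dtr[c], c))
        duo_info = {}
        for which, p in zip(("parent1", "parent2"), parents):
            if pd.isna(p) or p not in genotyped:
                rows.append((child, which, p if not pd.isna(p) else None,
                             np.nan, np.nan, None, "ungenotyped"))
                duo_info[which] = None
                continue
            d = cand_dtr[p]
            rows.append((child, which, p, d, float(ranked.index(p) + 1),
                         bool(d <= threshold),
                         "pass" if d <= threshold else "fail"))
            duo_info[which] = p
        if duo_info.get("parent1") and duo_info.get("parent2"):
            t = ttr(G, child, duo_info["parent1"], duo_info["parent2"])
            rows.append((child, "trio", f"{t.parent1}|{t.parent2}", t.ttr,
                         np.nan, bool(t.ttr <= threshold),
                         "pass" if t.ttr <= threshold else "fail"))
    return pd.DataFrame(
        rows,
        columns=["child", "relation", "claimed", "ratio", "rank", "passed", "status"],
    )
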