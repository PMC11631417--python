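"""Parentage forensics: transgression scores, ratios, and pedigree scans."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hetfix.forensics import (all_pairs_dtr, dtr, duo_score_marker,
                              scan_parentage, trio_score_marker, ttr)
from hetfix.genotypes import MISSING
from hetfix.sim import inject_errors, simulate_study

from conftest import make_genotypes, small_sim_config


def brute_duo(g_off, g_par):
    """Literal evaluation: S = f(AA_O) f(BB_P) + f(BB_O) f(AA_P)."""
    f = lambda g, k: 1.0 if g == k else 0.0
    return f(g_off, 0) * f(g_par, 2) + f(g_off, 2) * f(g_par, 0)


def brute_trio(g_off, g_p1, g_p2):
    """Literal evaluation of the trio summand T + S1 + S2 - S1*S2."""
    f = lambda g, k: 1.0 if g == k else 0.0
    t = f(g_off, 1) * f(g_p1, 0) * f(g_p2, 0) + f(g_off, 1) * f(g_p1, 2) * f(g_p2, 2)
    s1 = brute_duo(g_off, g_p1)
    s2 = brute_duo(g_off, g_p2)
    return t + s1 + s2 - s1 * s2


class TestMarkerScores:
    @pytest.mark.parametrize("o,p,expected", [
        (0, 0, 0),   # identical homozygotes
        (0, 2, 1),   # opposite homozygotes
        (2, 0, 1),
        (1, 2, 0),   # heterozygote never transgresses
        (1, 0, 0),
        (2, 2, 0),
    ])
    def test_duo_score(self, o, p, expected):
        assert duo_score_marker(o, p) == expected

    @pytest.mark.parametrize("o,p1,p2,expected", [
        (1, 0, 0, 1),  # het offspring, both parents same homozygote
        (1, 2, 2, 1),
        (1, 0, 2, 0),
        (0, 0, 0, 0),
    ])
    def test_trio_score(self, o, p1, p2, expected):
        assert trio_score_marker(o, p1, p2) == expected

    def test_missing_calls_rejected(self):
        with pytest.raises(ValueError):
            duo_score_marker(MISSING, 0)
        with pytest.raises(ValueError):
            trio_score_marker(0, MISSING, 1)

    def test_all_27_genotype_triples_match_bruteforce(self):
        """Marker-wise trio summand equals brute-force enumeration of the
        defining frequencies over every genotype triple, confirming the
        double-count correction."""
        for o, p1, p2 in itertools.product((0, 1, 2), repeat=3):
            G = make_genotypes([[o], [p1], [p2]], ids=["O", "P1", "P2"])
            got = ttr(G, "O", "P1", "P2").ttr
            assert got == brute_trio(o, p1, p2), (o, p1, p2)
            assert dtr(G, "O", "P1").dtr == brute_duo(o, p1)


class TestRatios:
    def test_opposite_homozygotes_everywhere(self):
        m = 20
        G = make_genotypes([np.zeros(m), np.full(m, 2)], ids=["O", "P"])
        assert dtr(G, "O", "P").dtr == 1.0

    def test_toy_duo_quarter(self):
        # O = (AA, AA, AB, BB), P = (BB, AA, AA, BB) -> S = (1, 0, 0, 0)
        G = make_genotypes([[0, 0, 1, 2], [2, 0, 0, 2]], ids=["O", "P"])
        score = dtr(G, "O", "P")
        assert score.dtr == 0.25
        assert score.m == 4

    def test_missing_markers_excluded_from_m(self):
        G = make_genotypes([[0, MISSING, 1], [2, 2, 0]], ids=["O", "P"])
        score = dtr(G, "O", "P")
        assert score.m == 2
        assert score.dtr == 0.5

    def test_forced_trio_ttr_one(self):
        m = 10
        G = make_genotypes([np.ones(m), np.zeros(m), np.zeros(m)],
                           ids=["O", "P1", "P2"])
        assert ttr(G, "O", "P1", "P2").ttr == 1.0

    def test_double_count_correction_single_marker(self):
        # O=AA, P1=BB, P2=BB: S1 = S2 = 1, summand = 1 (not 2)
        G = make_genotypes([[0], [2], [2]], ids=["O", "P1", "P2"])
        score = ttr(G, "O", "P1", "P2")
        assert score.ttr == 1.0
        assert score.sum_s1s2 == 1

    def test_ttr_symmetric_in_parents(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(3, 200)).astype(np.int8)
        G = make_genotypes(calls, ids=["O", "P1", "P2"])
        assert ttr(G, "O", "P1", "P2").ttr == ttr(G, "O", "P2", "P1").ttr

    def test_no_overlap_rejected(self):
        G = make_genotypes([[MISSING, 0], [2, MISSING]], ids=["O", "P"])
        with pytest.raises(ValueError):
            dtr(G, "O", "P")


@pytest.fixture(scope="module")
def forensic_study():
    cfg = small_sim_config(
        n_elite_founders=10, n_exotic_founders=2, n_elite_ancestors=0,
        n_markers=2000, divergence=0.1, n_elite_hybrids=30,
        n_exotic_hybrids=5, n_selfed_parents=2, n_s1_offspring=3, seed=17)
    G, truth, _ = simulate_study(cfg)
    return G, truth


class TestSimulatedPedigree:
    def test_true_relations_score_zero(self, forensic_study):
        """Error-free Mendelian transmission admits no transgressions."""
        G, truth = forensic_study
        ped = truth.pedigree.dropna(subset=["parent1"])
        for rec in ped.itertuples(index=False):
            assert dtr(G, rec.child, rec.parent1).dtr == 0.0
            assert dtr(G, rec.child, rec.parent2).dtr == 0.0
            assert ttr(G, rec.child, rec.parent1, rec.parent2).ttr == 0.0

    def test_unrelated_pairs_transgress(self, forensic_study):
        G, truth = forensic_study
        ped = truth.pedigree.set_index("child")
        hybrids = [c for c in ped.index if ped.loc[c, "group"] == "elite_x_elite"]
        founders = [c for c in ped.index if pd.isna(ped.loc[c, "parent1"])]
        checked = 0
        for child in hybrids[:10]:
            p1, p2 = ped.loc[child, ["parent1", "parent2"]]
            for f in founders:
                if f in (p1, p2):
                    continue
                assert dtr(G, child, f).dtr > 0.05
                checked += 1
        assert checked > 50

    def test_swapped_parents_inflate_ttr(self, forensic_study):
        G, truth = forensic_study
        ped = truth.pedigree.dropna(subset=["parent1"])
        hybrids = ped[ped["group"] == "elite_x_elite"].head(6)
        rows = list(hybrids.itertuples(index=False))
        for a, b in zip(rows, rows[1:]):
            if {a.parent1, a.parent2} == {b.parent1, b.parent2}:
                continue
            true_t = ttr(G, a.child, a.parent1, a.parent2).ttr
            wrong_t = ttr(G, a.child, b.parent1, b.parent2).ttr
            assert wrong_t > true_t + 0.01

    def test_error_rate_drives_true_duo_dtr(self, forensic_study):
        """Genotyping error creates a small, predictable transgression rate
        in true duos, far below the unrelated-pair level."""
        G, truth = forensic_study
        noisy = inject_errors(G, error_rate=0.01, missing_rate=0.0, seed=5)
        ped = truth.pedigree.dropna(subset=["parent1"])
        vals = [dtr(noisy, r.child, r.parent1).dtr
                for r in ped.itertuples(index=False)]
        mean_dtr = np.mean(vals)
        assert mean_dtr > 0
        # an error hits one member of the duo w.p. ~2*rate; only a fraction
        # of perturbations create opposite homozygotes
        assert mean_dtr < 0.02
        unrelated = dtr(noisy, ped.iloc[0]["child"],
                        [f for f in G.ids if f.startswith("exotic")][0]).dtr
        assert mean_dtr < unrelated / 5


class TestScan:
    def test_scan_accepts_truth_rejects_none(self, forensic_study):
        G, truth = forensic_study
        claims = truth.pedigree.dropna(subset=["parent1"])
        report = scan_parentage(G, claims, threshold=0.01)
        trio_rows = report[report["relation"] == "trio"]
        duo_rows = report[report["relation"].isin(["parent1", "parent2"])]
        assert (trio_rows["ratio"] == 0).all()
        assert trio_rows["passed"].all()
        assert duo_rows["passed"].all()
        # claimed true parents rank at the top of the candidate list
        assert (duo_rows["rank"] <= 4).all()

    def test_false_trios_fail(self, forensic_study):
        G, truth = forensic_study
        ped = truth.pedigree.dropna(subset=["parent1"]).head(8)
        founders = [s for s in G.ids if s.startswith(("elite_", "exotic_"))]
        wrong = ped.copy()
        wrong["parent1"] = [
            next(f for f in founders if f not in (r.parent1, r.parent2))
            for r in ped.itertuples(index=False)]
        wrong["parent2"] = [
            next(f for f in reversed(founders)
                 if f not in (r.parent1, r.parent2))
            for r in ped.itertuples(index=False)]
        report = scan_parentage(G, wrong, threshold=0.01)
        trio_rows = report[report["relation"] == "trio"]
        assert not trio_rows.empty
        assert not trio_rows["passed"].any()

    def test_ungenotyped_parent_reported_not_fatal(self, forensic_study):
        G, truth = forensic_study
        ped = truth.pedigree.dropna(subset=["parent1"]).head(1).copy()
        ped["parent2"] = "ghost"
        report = scan_parentage(G, ped, threshold=0.01)
        assert (report["status"] == "ungenotyped").any()

    def test_all_pairs_matches_pairwise(self, forensic_study):
        G, _ = forensic_study
        ids = G.ids[:6]
        table = all_pairs_dtr(G, ids, ids).set_index(
            ["offspring", "candidate_parent"])
        for o in ids:
            for c in ids:
                if o == c:
                    continue
                assert table.loc[(o, c), "dtr"] == pytest.approx(
                    dtr(G, o, c).dtr)
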