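"""Genotype metrics: QC filters, Ho/F, Ne, relationship matrices, PCA,
segregation tests."""

import numpy as np
import pytest
from scipy import stats

from hetfix.genotypes import MISSING
from hetfix.metrics import (additive_grm, dominance_grm,
                            effective_population_size,
                            expected_heterozygosity,
                            filter_markers_and_samples,
                            inbreeding_coefficient, observed_heterozygosity,
                            pca_scores, segregation_test)
from hetfix.sim import simulate_founders

from conftest import make_genotypes, small_sim_config


class TestFilters:
    def test_monomorphic_marker_dropped(self):
        G = make_genotypes([[0, 1], [0, 1], [0, 0]])
        Gf, rep = filter_markers_and_samples(G, maf_min=0.05, max_missing=1.0,
                                             min_call_rate=0.0)
        assert list(Gf.markers["marker_id"]) == ["m1"]
        assert rep.markers_dropped_maf == 1

    def test_high_missingness_marker_dropped(self):
        calls = np.ones((20, 2), np.int8)
        calls[:3, 0] = MISSING  # 15% missing in marker 0
        calls[::2, 1] = 0       # keep marker 1 polymorphic
        G = make_genotypes(calls)
        Gf, rep = filter_markers_and_samples(G, maf_min=0.0, max_missing=0.10,
                                             min_call_rate=0.0)
        assert "m0" not in list(Gf.markers["marker_id"])
        assert rep.markers_dropped_missing == 1

    def test_planted_failures_match_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        n, m = 40, 1000
        calls = rng.binomial(2, rng.uniform(0.05, 0.95, m), size=(n, m))
        calls = calls.astype(np.int8)
        miss = rng.random((n, m)) < 0.05
        calls[miss] = MISSING
        calls[0, : m // 2] = MISSING  # low call-rate sample
        G = make_genotypes(calls)
        maf_min, max_missing, min_cr = 0.05, 0.10, 0.90
        # brute-force oracle
        keep_s = [(row != MISSING).mean() > min_cr for row in calls]
        kept = calls[np.array(keep_s)]
        surv = 0
        for j in range(m):
            col = kept[:, j]
            ok = col != MISSING
            p = col[ok].mean() / 2.0
            if min(p, 1 - p) >= maf_min and (~ok).mean() <= max_missing:
                surv += 1
        Gf, rep = filter_markers_and_samples(G, maf_min, max_missing, min_cr)
        assert Gf.n_markers == surv
        assert rep.n_samples_out == sum(keep_s)

    def test_everything_filtered_raises(self):
        G = make_genotypes([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            filter_markers_and_samples(G, maf_min=0.05, max_missing=1.0,
                                       min_call_rate=0.0)


class TestHeterozygosityAndF:
    @pytest.mark.parametrize("calls,expected", [
        ([1, 1, 1, 1], 1.0),
        ([0, 2, 0, 2], 0.0),
        ([0, 1, 2, MISSING], 1.0 / 3.0),
    ])
    def test_observed_heterozygosity(self, calls, expected):
        G = make_genotypes([calls, [0, 1, 2, 1]])
        assert observed_heterozygosity(G)["ind0"] == pytest.approx(expected)

    def test_all_missing_flagged(self):
        G = make_genotypes([[MISSING, MISSING], [0, 1]])
        with pytest.warns(UserWarning):
            ho = observed_heterozygosity(G)
        assert np.isnan(ho["ind0"])

    def test_one_minus_h_reproduces_study_value(self):
        """An individual with Ho = 0.38 has F = 1 - H = 0.62."""
        calls = np.zeros((2, 100), np.int8)
        calls[0, :38] = 1
        calls[1, :50] = 1
        G = make_genotypes(calls)
        f = inbreeding_coefficient(G, "one_minus_H")
        assert f["ind0"] == pytest.approx(0.62)

    def test_fully_homozygous_f_is_one(self):
        G = make_genotypes([[0, 2, 0, 2], [0, 1, 1, 2]])
        assert inbreeding_coefficient(G, "one_minus_H")["ind0"] == 1.0

    def test_excess_homozygosity_matches_hand_oracle(self):
        # 3 individuals x 4 markers, hand-computed per-marker 2pq sums
        calls = np.array([[0, 1, 2, 1],
                          [1, 1, 0, 0],
                          [2, 0, 0, MISSING]], np.int8)
        G = make_genotypes(calls)
        p = np.array([3 / 6, 2 / 6, 2 / 6, 1 / 4])
        e_hom = 1 - 2 * p * (1 - p)
        f_hand = []
        for i, row in enumerate(calls):
            ok = row != MISSING
            m_i = ok.sum()
            o_hom = np.isin(row[ok], (0, 2)).sum()
            e_i = e_hom[ok].sum()
            f_hand.append((o_hom - e_i) / (m_i - e_i))
        f = inbreeding_coefficient(G, "excess_homozygosity")
        assert np.allclose(f.to_numpy(), f_hand)

    def test_estimators_agree_in_rank_order(self):
        cfg = small_sim_config(n_elite_founders=60, n_exotic_founders=2,
                               n_elite_ancestors=0, n_markers=1000, seed=8)
        G, _, _ = simulate_founders(cfg)
        f1 = inbreeding_coefficient(G, "one_minus_H")
        f2 = inbreeding_coefficient(G, "excess_homozygosity")
        rho = stats.spearmanr(f1, f2).statistic
        assert rho > 0.95


class TestNe:
    def test_no_decay_is_nonfinite(self):
        with pytest.warns(UserWarning):
            assert not np.isfinite(effective_population_size(0.3, 0.3))

    def test_inversion_identity(self):
        h0 = 0.4
        assert effective_population_size(h0, h0 * np.exp(-0.5)) == \
            pytest.approx(1.0)

    def test_printed_inputs_give_direct_evaluation(self):
        """Direct evaluation at (0.355, 0.313) gives 3.97 (published analyses
        print 3.91 from unrounded inputs; the formula is not forced to it)."""
        assert effective_population_size(0.355, 0.313) == \
            pytest.approx(3.97, abs=0.005)

    def test_selfing_closed_form(self):
        # halving H per generation: Ne = -1/(2 ln 0.5) ~ 0.721
        assert effective_population_size(0.4, 0.2) == \
            pytest.approx(-1 / (2 * np.log(0.5)))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            effective_population_size(0.0, 0.1)


class TestGRM:
    def test_vanraden_single_marker_hand_value(self):
        G = make_genotypes([[0], [2]])
        K = additive_grm(G).values
        assert np.allclose(K, [[2, -2], [-2, 2]])

    def test_duplicate_individuals(self):
        G = make_genotypes([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]])
        K = additive_grm(G).values
        assert np.allclose(K[0], K[1])
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_diagonal_mean_near_one_on_hwe_panel(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.1, 0.9, 2000)
        calls = rng.binomial(2, p, size=(200, 2000)).astype(np.int8)
        K = additive_grm(make_genotypes(calls)).values
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.05)

    def test_permutation_conjugation(self):
        rng = np.random.default_rng(13)
        calls = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        G = make_genotypes(calls)
        perm = rng.permutation(10)
        Gp = make_genotypes(calls[perm], ids=[f"ind{i}" for i in perm])
        K = additive_grm(G).values
        Kp = additive_grm(Gp).values
        assert np.allclose(Kp, K[np.ix_(perm, perm)])

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError):
            additive_grm(make_genotypes([[2, 2], [2, 2]]))


class TestDominanceGRM:
    def test_fully_homozygous_panel_rejected(self):
        with pytest.raises(ValueError):
            dominance_grm(make_genotypes([[0, 2], [2, 0]]))

    def test_single_marker_hand_value(self):
        # p = 0.5, both heterozygous: covariate 2pq = 0.5, denom (2pq)^2
        G = make_genotypes([[1], [1]])
        K = dominance_grm(G).values
        assert np.allclose(K, [[1, 1], [1, 1]])

    def test_symmetric_psd_on_random_panels(self):
        rng = np.random.default_rng(14)
        calls = rng.integers(0, 3, size=(30, 300)).astype(np.int8)
        K = dominance_grm(make_genotypes(calls)).values
        assert np.allclose(K, K.T)
        vals = np.linalg.eigvalsh(K)
        assert vals.min() > -1e-8 * np.trace(K)


class TestPCA:
    def test_identical_individuals_identical_scores(self):
        rng = np.random.default_rng(15)
        calls = rng.integers(0, 3, size=(6, 80)).astype(np.int8)
        calls[1] = calls[0]
        scores, _ = pca_scores(make_genotypes(calls), 3)
        assert np.allclose(scores.iloc[0], scores.iloc[1], atol=1e-8)

    def test_pc1_separates_diverged_groups(self):
        cfg = small_sim_config(n_elite_founders=50, n_exotic_founders=50,
                               n_elite_ancestors=0, n_markers=5000,
                               divergence=0.2, seed=16)
        G, groups, _ = simulate_founders(cfg)
        scores, varexp = pca_scores(G, 2)
        pc1 = scores["PC1"]
        elite = pc1[[s for s in G.ids if groups[s] == "elite"]]
        exotic = pc1[[s for s in G.ids if groups[s] == "exotic"]]
        # perfect linear separation
        assert max(elite.max(), exotic.max()) == \
            pytest.approx(pc1.max())
        assert elite.max() < exotic.min() or exotic.max() < elite.min()
        assert varexp.sum() <= 1.0 + 1e-12

    def test_too_many_components_rejected(self):
        G = make_genotypes([[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            pca_scores(G, 5)


class TestSegregation:
    @pytest.mark.parametrize("obs,ratio", [
        ([75, 25], [3, 1]),
        ([50, 50], [1, 1]),
    ])
    def test_perfect_fit(self, obs, ratio):
        chi2, p = segregation_test(obs, ratio)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_chi_square(self):
        chi2, p = segregation_test([60, 40], [1, 1])
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(0.0455, abs=2e-4)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            segregation_test([0, 0], [3, 1])
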