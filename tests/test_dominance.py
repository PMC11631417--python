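"""Directional-dominance models and the kinship-corrected marker scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hetfix.config import TraitConfig
from hetfix.dominance import (HodModel, compare_degree, effect_comparison,
                              marker_scan)
from hetfix.metrics import additive_grm, dominance_grm, observed_heterozygosity
from hetfix.sim import simulate_study
from hetfix.trial import narrow_sense_heritability, EMMTable

from conftest import small_sim_config


def dominance_study(delta_mean, seed, **kw):
    base = dict(n_elite_founders=16, n_exotic_founders=3, n_elite_ancestors=4,
                n_elite_hybrids=120, n_exotic_hybrids=40, n_selfed_parents=6,
                n_s1_offspring=40, n_markers=800, seed=seed,
                traits=[TraitConfig("t", 60, 1.0, delta_mean, 0.15 if delta_mean else 0.0,
                                    0.3 if delta_mean else 0.0,
                                    20.0, 0, 0, 0, 1.0, "mean")])
    base.update(kw)
    cfg = small_sim_config(**base)
    G, truth, _ = simulate_study(cfg)
    rng = np.random.default_rng(seed + 1000)
    g = truth.genetic_values["t"]
    y = pd.Series(g.to_numpy() + rng.normal(0, 1.0, len(g)), index=g.index)
    return G, truth, y


@pytest.fixture(scope="module")
def hod_fixture():
    G, truth, y = dominance_study(delta_mean=0.8, seed=41)
    ho = 1.0 - observed_heterozygosity(G)
    KA = additive_grm(G)
    KD = dominance_grm(G)
    return G, truth, y, ho, KA, KD


class TestHodModel:
    def test_directional_dominance_gives_negative_beta(self, hod_fixture):
        _, _, y, ho, KA, KD = hod_fixture
        fit = HodModel(y, ho, KA, KD, degree=1).fit()
        assert fit.beta_ho < 0
        assert fit.wald_p("Ho") < 0.05

    def test_constant_ho_dropped_with_warning(self, hod_fixture):
        G, _, y, _, KA, KD = hod_fixture
        const = pd.Series(0.5, index=y.index)
        with pytest.warns(UserWarning):
            fit = HodModel(y, const, KA, KD, degree=1).fit()
        assert "Ho" not in fit.model._mm.fe_names

    def test_reduces_to_narrow_sense_model(self, hod_fixture):
        """With the dominance kernel omitted and a constant Ho covariate
        dropped, the fit reproduces the single-kernel additive model."""
        G, _, y, _, KA, _ = hod_fixture
        const = pd.Series(0.5, index=y.index)
        with pytest.warns(UserWarning):
            fit = HodModel(y, const, KA, K_D=None, degree=1).fit()
        emm = EMMTable("t", pd.DataFrame({"estimate": y, "se": 0.0}),
                       np.zeros((len(y), len(y))))
        h2, ref = narrow_sense_heritability(emm, KA)
        assert fit.params["additive"] == pytest.approx(
            ref.params["additive"], rel=1e-4)

    def test_degree2_loglik_never_below_degree1(self, hod_fixture):
        _, _, y, ho, KA, KD = hod_fixture
        f1 = HodModel(y, ho, KA, KD, 1).fit(reml=False)
        f2 = HodModel(y, ho, KA, KD, 2).fit(reml=False)
        assert f2.llf >= f1.llf - 1e-6


class TestCompareDegree:
    def test_null_quadratic_not_rejected(self, hod_fixture):
        _, _, y, ho, KA, KD = hod_fixture
        f1 = HodModel(y, ho, KA, KD, 1).fit(reml=False)
        f2 = HodModel(y, ho, KA, KD, 2).fit(reml=False)
        out = compare_degree(f1, f2)
        assert out["statistic"] >= 0
        assert out["ml_llf_degree2"] >= out["ml_llf_degree1"] - 1e-6

    def test_wrong_order_rejected(self, hod_fixture):
        _, _, y, ho, KA, KD = hod_fixture
        f1 = HodModel(y, ho, KA, KD, 1).fit()
        with pytest.raises(ValueError):
            compare_degree(f1, f1)

    def test_planted_quadratic_detected(self):
        rng = np.random.default_rng(5)
        G, truth, y0 = dominance_study(delta_mean=0.0, seed=47)
        ho = 1.0 - observed_heterozygosity(G)
        KA = additive_grm(G)
        KD = dominance_grm(G)
        hc = ho - ho.mean()
        # curvature sized to contribute ~half the trait's spread
        y = y0 + 500.0 * hc**2 + rng.normal(0, 0.2, len(y0))
        f1 = HodModel(y, ho, KA, KD, 1).fit(reml=False)
        f2 = HodModel(y, ho, KA, KD, 2).fit(reml=False)
        assert compare_degree(f1, f2)["p_value"] < 0.01


@pytest.fixture(scope="module")
def le_panel():
    """Hardy-Weinberg panel in linkage equilibrium (no bottleneck LD), the
    setting in which single-marker attribution is well defined."""
    from conftest import make_genotypes

    rng = np.random.default_rng(61)
    p = rng.uniform(0.2, 0.8, 800)
    calls = rng.binomial(2, p, size=(400, 800)).astype(np.int8)
    G = make_genotypes(calls)
    return G, additive_grm(G)


class TestMarkerScan:
    def test_planted_qtl_is_top_hit(self, le_panel):
        G, KA = le_panel
        rng = np.random.default_rng(6)
        j = 123
        x = G.dosage_float()[:, j]
        beta = np.sqrt(0.2 / (0.8 * x.var()))  # marker h2 ~ 0.2
        y = pd.Series(beta * x + rng.normal(0, 1.0, G.n_individuals),
                      index=G.ids)
        res = marker_scan(y, G, KA)
        top = res.table.sort_values("p_value").iloc[0]
        assert top["marker_id"] == G.markers["marker_id"][j]

    def test_null_pvalues_uniform(self, le_panel):
        G, KA = le_panel
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=G.n_individuals), index=G.ids)
        res = marker_scan(y, G, KA)
        pv = res.table["p_value"].dropna()
        assert stats.kstest(pv, "uniform").pvalue > 0.05

    def test_effect_orthogonal_response_near_zero(self, hod_fixture):
        G, _, _, _, KA, _ = hod_fixture
        y = pd.Series(np.zeros(G.n_individuals), index=G.ids)
        y.iloc[0] = 1e-12
        res = marker_scan(y, G, KA)
        assert np.nanmax(np.abs(res.table["effect"])) < 1e-6

    def test_scan_invariant_to_marker_relabeling(self, hod_fixture):
        G, _, y, _, KA, _ = hod_fixture
        res1 = marker_scan(y, G, KA)
        relabeled = G.subset()
        relabeled.markers["marker_id"] = [
            f"renamed_{j}" for j in range(G.n_markers)]
        res2 = marker_scan(y, relabeled, KA)
        assert np.allclose(res1.table["effect"], res2.table["effect"],
                           equal_nan=True)

    def test_exact_mode_agrees_with_p3d_on_effects(self, hod_fixture):
        G, _, y, _, KA, _ = hod_fixture
        sub = G.subset(marker_mask=np.arange(G.n_markers) < 30)
        fast = marker_scan(y, sub, KA, exact=False)
        slow = marker_scan(y, sub, KA, exact=True)
        ok = np.isfinite(fast.table["effect"]).to_numpy()
        f = fast.table["effect"].to_numpy()[ok]
        s = slow.table["effect"].to_numpy()[ok]
        # the null-model variance approximation perturbs effects only mildly
        assert np.max(np.abs(f - s) / (np.abs(s) + 0.1)) < 0.10
        assert np.corrcoef(f, s)[0, 1] > 0.999


class TestEffectComparison:
    def test_identical_scans_give_zero_differences(self, hod_fixture):
        G, _, y, _, KA, _ = hod_fixture
        res = marker_scan(y, G, KA)
        out = effect_comparison(res, res)
        assert out["n_full_larger"] == 0
        assert np.allclose(out["markers"]["abs_effect_diff"], 0.0)

    def test_exotic_inclusion_inflates_effects_for_selected_trait(self):
        """Including wide hybrids restores allele-frequency differences at
        selected loci, so estimated additive effects grow nearly genome-wide;
        for a trait whose QTLs segregate equally in both groups they do not."""
        cfg = small_sim_config(
            n_elite_founders=16, n_exotic_founders=3, n_elite_ancestors=0,
            n_elite_hybrids=150, n_exotic_hybrids=60, n_selfed_parents=2,
            n_s1_offspring=2, n_markers=1500, divergence=0.5, seed=53,
            traits=[
                TraitConfig("sel", 80, 1.0, 0.9, 0.15, 0.0, 10.0,
                            0, 0, 0, 0.5, "mean", qtl_elite_fixed=True),
                TraitConfig("neu", 80, 1.0, 0.0, 0.15, 0.0, 10.0,
                            0, 0, 0, 0.5, "mean", qtl_balanced=True),
            ])
        G, truth, _ = simulate_study(cfg)
        KA = additive_grm(G)
        ped = truth.pedigree.set_index("child")
        hybrids = [s for s in G.ids if ped.loc[s, "group"] in
                   ("elite_x_elite", "elite_x_exotic")]
        elite = [s for s in hybrids if ped.loc[s, "group"] == "elite_x_elite"]
        rng = np.random.default_rng(1)
        outcomes = {}
        for trait in ("sel", "neu"):
            g = truth.genetic_values[trait]
            y = pd.Series(g.to_numpy() + rng.normal(0, 0.5, len(g)),
                          index=g.index)
            full = marker_scan(y[hybrids], G, KA)
            part = marker_scan(y[elite], G, KA)
            outcomes[trait] = effect_comparison(part, full)
        assert outcomes["sel"]["sign_test_p"] < 0.01
        assert outcomes["neu"]["sign_test_p"] > 0.05
        frac_neu = outcomes["neu"]["n_full_larger"] / outcomes["neu"]["n_compared"]
        frac_sel = outcomes["sel"]["n_full_larger"] / outcomes["sel"]["n_compared"]
        assert frac_neu < frac_sel
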