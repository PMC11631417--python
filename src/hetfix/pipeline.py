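"""End-to-end orchestration of the heterosis/inbreeding analysis.

Stage order mirrors the analysis a breeding-genetics study would run on a
SNP-genotyped, clonally replicated trial population:

    QC -> diversity / relationship matrices / PCA -> parentage forensics ->
    trial LMM + EMMs -> heterosis contrasts + classification tables ->
    trait-on-heterozygosity regressions -> directional-dominance fits ->
    kinship-corrected marker scan -> single-locus theory decay curves.

Every stage writes CSV outputs plus a machine-readable run manifest
(package version, seed, thresholds, per-stage wall-clock).  Outputs are
pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, SimConfig
from .dominance import HodModel, compare_degree, effect_comparison, marker_scan
from .forensics import scan_parentage
from .genotypes import GenotypeMatrix
from .heterosis import classify_contrasts, heterosis_contrasts, heterozygosity_regression
from .metrics import (additive_grm, diversity_summary, dominance_grm,
                      effective_population_size, filter_markers_and_samples,
                      pca_scores)
from .sim import simulate_study, write_study
from .theory import heterosis_decay_curve
from .trial import TrialModel, narrow_sense_heritability

log = logging.getLogger("hetfix")


# ---------------------------------------------------------------------------
# report arithmetic (kept as small pure functions so printed study tables can
# be re-derived from their published inputs)

def inbreeding_contrast(s0_mean: float, s1_mean: float) -> float:
    """S0-vs-S1 contrast as printed in inbreeding-depression tables."""
    return s0_mean - s1_mean


def percent_change(s0_mean: float, s1_mean: float) -> float:
    """Percent change from S0 to S1: 100 (S1 - S0) / S0.

    Negative for traits depressed by inbreeding.  (Some published table
    captions print the formula with the opposite orientation while the
    tabulated signs follow this one; this convention reproduces the signs.)
    """
    return 100.0 * (s1_mean - s0_mean) / s0_mean


def heterozygous_gene_bounds(f_range: tuple[float, float],
                             gene_range: tuple[float, float]
                             ) -> tuple[float, float]:
    """(1-F) x gene-count bounds on the number of heterozygous genes."""
    f_lo, f_hi = sorted(f_range)
    g_lo, g_hi = sorted(gene_range)
    return (1.0 - f_hi) * g_lo, (1.0 - f_lo) * g_hi


def s0_s1_table(emms_by_trait: dict[str, pd.Series], s0_ids: list[str],
                s1_ids: list[str], het: pd.Series | None = None
                ) -> pd.DataFrame:
    """Table-1-shaped inbreeding-depression summary.

    Rows: heterozygosity (if supplied) then each trait; columns: S0 mean,
    S1 mean, contrast (S0 - S1), percent change 100 (S1 - S0)/S0.
    """
    rows = []
    if het is not None:
        h0 = float(het.reindex(s0_ids).mean())
        h1 = float(het.reindex(s1_ids).mean())
        rows.append(("heterozygosity", h0, h1, inbreeding_contrast(h0, h1),
                     percent_change(h0, h1)))
    for trait, emm in emms_by_trait.items():
        m0 = float(emm.reindex(s0_ids).mean())
        m1 = float(emm.reindex(s1_ids).mean())
        rows.append((trait, m0, m1, inbreeding_contrast(m0, m1),
                     percent_change(m0, m1)))
    return pd.DataFrame(
        rows, columns=["trait", "s0_mean", "s1_mean", "contrast",
                       "percent_change"])


# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to config.out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": str(out)}
    manifest = {
        "package": "hetfix",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "maf_min": config.maf_min,
            "max_missing": config.max_missing,
            "min_call_rate": config.min_call_rate,
            "alpha": config.alpha,
            "forensics_threshold": config.forensics_threshold,
            "scan_threshold": config.scan_threshold,
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:  # halt with stage label, keep partials
                _write_manifest(out, manifest)
                raise StageError(name, exc) from exc
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {"seconds": round(dt, 3)}
            log.info("stage %s: done in %.2fs", name, dt)
        return deco

    # -- inputs --------------------------------------------------------------
    sim_cfg = config.sim
    if config.genotypes is None and sim_cfg is None:
        warnings.warn("no input paths given: falling back to simulation")
        sim_cfg = SimConfig(seed=config.seed)

    @stage("inputs")
    def _():
        if sim_cfg is not None:
            G, truth, records = simulate_study(sim_cfg)
            write_study(out / "simulated", G, truth, records)
            bundle["genotypes"] = G
            bundle["records"] = records
            bundle["pedigree"] = truth.pedigree
            bundle["truth"] = truth
            bundle["trait_configs"] = {t.name: t for t in sim_cfg.traits}
        else:
            path = Path(config.genotypes)
            bundle["genotypes"] = (GenotypeMatrix.from_vcf(path)
                                   if path.suffix.lower() == ".vcf"
                                   else GenotypeMatrix.from_csv(path))
            bundle["records"] = pd.read_csv(config.phenotypes)
            bundle["pedigree"] = pd.read_csv(config.pedigree)
            bundle["trait_configs"] = {}

    # -- QC ------------------------------------------------------------------
    @stage("qc")
    def _():
        Gf, report = filter_markers_and_samples(
            bundle["genotypes"], config.maf_min, config.max_missing,
            config.min_call_rate)
        bundle["genotypes_qc"] = Gf
        report.to_frame().to_csv(out / "qc_report.csv", index=False)

    # -- diversity / kernels / PCA -------------------------------------------
    @stage("diversity")
    def _():
        Gf = bundle["genotypes_qc"]
        div = diversity_summary(Gf)
        div.to_csv(out / "diversity.csv", index_label="individual")
        bundle["diversity"] = div
        ped = bundle["pedigree"]
        parents = ped.loc[ped["parent1"].isna(), "child"].tolist()
        hybrids = ped.loc[ped["group"].isin(
            ["elite_x_elite", "elite_x_exotic"]), "child"].tolist()
        ho = div["Ho"]
        ne_rows = []
        par_all = [s for s in parents if s in ho.index]
        hyb_all = [s for s in hybrids if s in ho.index]
        if par_all and hyb_all:
            h0 = float(ho[par_all].mean())
            h1 = float(ho[hyb_all].mean())
            ne_rows.append(("all", h0, h1, effective_population_size(h0, h1)))
            elite_par = [s for s in par_all
                         if bundle["pedigree"].set_index("child")
                         .loc[s, "group"] == "elite"]
            exe = ped[ped["group"] == "elite_x_elite"]["child"]
            exe = [s for s in exe if s in ho.index]
            if elite_par and exe:
                h0e = float(ho[elite_par].mean())
                h1e = float(ho[exe].mean())
                ne_rows.append(("elite", h0e, h1e,
                                effective_population_size(h0e, h1e)))
        bundle["ne"] = pd.DataFrame(
            ne_rows, columns=["population", "H0", "H1", "Ne"])
        bundle["ne"].to_csv(out / "ne.csv", index=False)
        bundle["K_A"] = additive_grm(Gf)
        bundle["K_D"] = dominance_grm(Gf)
        pd.DataFrame(bundle["K_A"].values, index=Gf.ids, columns=Gf.ids
                     ).to_csv(out / "grm_additive.csv")
        pd.DataFrame(bundle["K_D"].values, index=Gf.ids, columns=Gf.ids
                     ).to_csv(out / "grm_dominance.csv")
        scores, varexp = pca_scores(Gf, n_components=min(10, Gf.n_individuals))
        scores.to_csv(out / "pca_scores.csv", index_label="individual")
        bundle["pca"] = scores

    # -- forensics -------------------------------------------------------------
    @stage("forensics")
    def _():
        claims = bundle["pedigree"].dropna(subset=["parent1", "parent2"])
        rep = scan_parentage(bundle["genotypes_qc"], claims,
                             config.forensics_threshold)
        rep.to_csv(out / "forensics_report.csv", index=False)
        bundle["forensics"] = rep

    # -- trial LMM + EMMs ------------------------------------------------------
    @stage("emm")
    def _():
        records = bundle["records"]
        traits = config.traits or sorted(records["trait"].unique())
        emms = {}
        vcs = []
        for trait in traits:
            tc = bundle["trait_configs"].get(trait)
            agg = tc.aggregate if tc is not None else "mean"
            emm_res = TrialModel(records, trait, "fixed", agg).fit()
            emms[trait] = emm_res.emms()
            rnd = TrialModel(records, trait, "random", agg).fit()
            vc = rnd.variance_components
            h2 = rnd.broad_sense_heritability()
            row = {"trait": trait, "H2_clone_mean": h2,
                   "harmonic_mean_reps": rnd.harmonic_mean_reps()}
            row.update({f"var_{k}": v for k, v in vc.items()})
            try:
                nh2, _ = narrow_sense_heritability(emms[trait], bundle["K_A"])
                row["h2_narrow"] = nh2
            except Exception as exc:
                row["h2_narrow"] = np.nan
                log.warning("narrow-sense h2 failed for %s: %s", trait, exc)
            vcs.append(row)
            emms[trait].frame.to_csv(out / f"emm_{trait}.csv")
        bundle["emms"] = emms
        bundle["heritability"] = pd.DataFrame(vcs)
        bundle["heritability"].to_csv(out / "heritability.csv", index=False)

    # -- additive genetic correlations between traits ---------------------------
    @stage("genetic_correlation")
    def _():
        from itertools import combinations

        from .trial import genetic_correlation

        rows = []
        for t1, t2 in combinations(bundle["emms"], 2):
            try:
                r = genetic_correlation(bundle["emms"][t1],
                                        bundle["emms"][t2], bundle["K_A"])
                rows.append({"trait1": t1, "trait2": t2, "r_G": r["r_G"],
                             "se": r["se"], "z": r["z"],
                             "p_value": r["p_value"],
                             "fallback": r["fallback"]})
            except Exception as exc:
                log.warning("genetic correlation %s-%s failed: %s",
                            t1, t2, exc)
        bundle["genetic_correlations"] = pd.DataFrame(rows)
        bundle["genetic_correlations"].to_csv(
            out / "genetic_correlations.csv", index=False)

    # -- heterosis -------------------------------------------------------------
    @stage("heterosis")
    def _():
        ped = bundle["pedigree"]
        all_rec = []
        for trait, emm in bundle["emms"].items():
            rec = heterosis_contrasts(emm, ped, config.alpha)
            rec.insert(0, "trait", trait)
            all_rec.append(rec)
        records = pd.concat(all_rec, ignore_index=True)
        records.to_csv(out / "heterosis_records.csv", index=False)
        bundle["heterosis"] = records
        t2_all, t3_all = [], []
        for trait, sub in records.groupby("trait"):
            t2, t3 = classify_contrasts(sub, config.alpha)
            t2.insert(0, "trait", trait)
            t3.insert(0, "trait", trait)
            t2_all.append(t2)
            t3_all.append(t3)
        bundle["table2"] = pd.concat(t2_all, ignore_index=True)
        bundle["table3"] = pd.concat(t3_all, ignore_index=True)
        bundle["table2"].to_csv(out / "heterosis_classification.csv", index=False)
        bundle["table3"].to_csv(out / "worst_parent_table.csv", index=False)

    # -- H regressions ---------------------------------------------------------
    @stage("h_regression")
    def _():
        het = bundle["diversity"]["Ho"]
        rows = []
        hz = bundle["heterosis"]
        for trait, emm in bundle["emms"].items():
            sub = hz[hz["trait"] == trait].set_index("hybrid")
            for resp_name, resp in (
                    ("emm", emm.frame["estimate"]),
                    ("mph", sub["mph"]), ("bph", sub["bph"])):
                resp = resp.dropna()
                if resp.empty or het.reindex(resp.index).nunique() < 4:
                    continue
                r = heterozygosity_regression(resp, het, degree=2)
                rg = heterozygosity_regression(resp, het, degree=2,
                                               K_A=bundle["K_A"],
                                               K_D=bundle["K_D"])
                rows.append({
                    "trait": trait, "response": resp_name, "n": r["n"],
                    "slope": r["coef_linear"][1],
                    "quad_coef": r["coef_quadratic"][2],
                    "quad_F": r["statistic"], "quad_p": r["p_value"],
                    "quad_p_with_kernels": rg["p_value"],
                })
        bundle["h_regression"] = pd.DataFrame(rows)
        bundle["h_regression"].to_csv(out / "h_regressions.csv", index=False)

    # -- directional dominance ---------------------------------------------------
    @stage("dominance")
    def _():
        het = bundle["diversity"]["Ho"]
        ho = (1.0 - het).rename("Ho")
        rows = []
        for trait, emm in bundle["emms"].items():
            y = emm.frame["estimate"]
            f1 = HodModel(y, ho, bundle["K_A"], bundle["K_D"], degree=1).fit()
            f2 = HodModel(y, ho, bundle["K_A"], bundle["K_D"], degree=2).fit()
            cmpres = compare_degree(f1, f2)
            est, se = f1.coef("Ho")
            rows.append({
                "trait": trait, "beta_ho": est, "beta_ho_se": se,
                "beta_ho_p": f1.wald_p("Ho"),
                "var_additive": f1.params["additive"],
                "var_dominance": f1.params.get("dominance", np.nan),
                "var_residual": f1.params["residual"],
                "loglik_reml": f1.llf,
                "degree2_stat": cmpres["statistic"],
                "degree2_p": cmpres["p_value"],
            })
        bundle["hod"] = pd.DataFrame(rows)
        bundle["hod"].to_csv(out / "directional_dominance.csv", index=False)

    # -- marker scan ------------------------------------------------------------
    @stage("scan")
    def _():
        ped = bundle["pedigree"].set_index("child")
        Gf = bundle["genotypes_qc"]
        hybrids = [s for s in Gf.ids
                   if s in ped.index and ped.loc[s, "group"] in
                   ("elite_x_elite", "elite_x_exotic")]
        elite_only = [s for s in hybrids
                      if ped.loc[s, "group"] == "elite_x_elite"]
        comps = []
        for trait, emm in bundle["emms"].items():
            y = emm.frame["estimate"]
            full = marker_scan(y.reindex(hybrids).dropna(), Gf, bundle["K_A"],
                               config.scan_threshold)
            subset = marker_scan(y.reindex(elite_only).dropna(), Gf,
                                 bundle["K_A"], config.scan_threshold)
            full.table.to_csv(out / f"scan_{trait}_all.csv", index=False)
            subset.table.to_csv(out / f"scan_{trait}_elite.csv", index=False)
            comp = effect_comparison(subset, full)
            comps.append({"trait": trait,
                          "n_full_larger": comp["n_full_larger"],
                          "n_compared": comp["n_compared"],
                          "sign_test_p": comp["sign_test_p"],
                          "median_abs_effect_diff": comp["median_diff"]})
            bundle.setdefault("scans", {})[trait] = (subset, full)
        bundle["scan_comparison"] = pd.DataFrame(comps)
        bundle["scan_comparison"].to_csv(out / "scan_effect_comparison.csv",
                                         index=False)

    # -- theory -------------------------------------------------------------------
    @stage("theory")
    def _():
        p1 = np.linspace(0.5, 1.0, 26)
        rows = []
        for d in (0.5, 1.0, 2.0):
            mph = heterosis_decay_curve(p1, np.ones_like(p1), d)
            for pa, v in zip(p1, mph):
                rows.append((d, pa, 1.0, v))
        curve = pd.DataFrame(rows, columns=["d", "p1", "p2", "mph"])
        curve.to_csv(out / "theory_decay_curves.csv", index=False)
        bundle["theory"] = curve

    # -- report -------------------------------------------------------------------
    @stage("report")
    def _():
        bundle["report"] = make_report(bundle)
        bundle["report"].to_csv(out / "s0_s1_table.csv", index=False)

    _write_manifest(out, manifest)
    bundle["manifest"] = manifest
    return bundle


def make_report(bundle: dict) -> pd.DataFrame:
    """Table-1-shaped S0-vs-S1 summary from the pipeline bundle."""
    ped = bundle["pedigree"]
    s1 = ped[ped["group"] == "s1"]
    s0_ids = sorted(s1["parent1"].unique())
    s1_ids = s1["child"].tolist()
    if not s1_ids:
        warnings.warn("no S1 individuals: S0-vs-S1 section omitted")
        return pd.DataFrame(
            columns=["trait", "s0_mean", "s1_mean", "contrast",
                     "percent_change"])
    emms = {t: e.frame["estimate"] for t, e in bundle["emms"].items()}
    het = bundle["diversity"]["Ho"] if "diversity" in bundle else None
    return s0_s1_table(emms, s0_ids, s1_ids, het)


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
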