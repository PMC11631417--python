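"""Breeding-population simulator with known truth.

Generates genotypes, pedigrees, and clonal-trial phenotypes with the
statistical structure the downstream analyses assume:

* two founder groups (elite vs exotic) whose allele frequencies diverge by a
  Balding-Nichols draw around shared ancestral frequencies, so the expected
  between-group FST equals the configured divergence;
* biparental F1 hybrids and S1 selfs with Mendelian pseudo-diploid
  transmission (unlinked markers by default, optional Haldane linkage);
* trait genetic values from QTLs whose dominance deviations have a
  configurable directional bias (delta = d/|a| with mean > 0 for heterotic
  traits), plus a deleterious partially recessive "load" component;
* plot-level trial observations with block, year, genotype-by-year, and
  residual Gaussian effects in a randomized complete blocks design repeated
  over years.

Every function is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig, TraitConfig
from .genotypes import MISSING, GenotypeMatrix, default_marker_table


@dataclass
class TruthRecord:
    """Ground truth of a simulated study, for recovery tests.

    qtl : per trait, the QTL marker indices with additive effect a and
        dominance deviation d (genotype values -a, d, +a for dosages 0,1,2).
    genetic_values : individuals x traits true total genetic values.
    groups : individual -> group label (elite / exotic / hybrid classes).
    pedigree : child, parent1, parent2, group; founders have parent NA.
    """

    qtl: pd.DataFrame
    genetic_values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    pedigree: pd.DataFrame | None = None
    group_frequencies: dict[str, np.ndarray] = field(default_factory=dict)


def _balding_nichols(rng, ancestral: np.ndarray, divergence: float) -> np.ndarray:
    """Group allele frequencies around shared ancestral ones, E[FST] ~ divergence."""
    if divergence == 0.0:
        return ancestral.copy()
    a = ancestral * (1.0 - divergence) / divergence
    b = (1.0 - ancestral) * (1.0 - divergence) / divergence
    return rng.beta(a, b)


def simulate_founders(config: SimConfig, rng=None):
    """Draw elite and exotic founder genotypes.

    Within each group, genotypes are Hardy-Weinberg binomial draws per marker
    from that group's allele frequency vector.  When n_elite_ancestors > 0
    the elite founders are offspring of crosses among that small ancestor
    pool, so they are consanguineous: their own hybrids lose heterozygosity
    (the closed-population bottleneck the effective-population-size
    estimator measures).

    Returns
    -------
    (GenotypeMatrix, dict id->group, dict group->frequency vector)
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.n_markers
    ancestral = rng.uniform(0.1, 0.9, size=m)
    freqs = {
        "elite": _balding_nichols(rng, ancestral, config.divergence),
        "exotic": _balding_nichols(rng, ancestral, config.divergence),
    }
    ancestors = None
    if config.n_elite_ancestors >= 2:
        ancestors = rng.binomial(
            2, freqs["elite"], size=(config.n_elite_ancestors, m)
        ).astype(np.int8)
    ids, rows, groups = [], [], {}
    for g, n in (("elite", config.n_elite_founders), ("exotic", config.n_exotic_founders)):
        for k in range(n):
            ident = f"{g}_{k:03d}"
            ids.append(ident)
            groups[ident] = g
            if g == "elite" and ancestors is not None:
                i, j = rng.choice(config.n_elite_ancestors, size=2, replace=False)
                rows.append(cross(ancestors[i], ancestors[j], 1, config, rng)[0])
            else:
                rows.append(rng.binomial(2, freqs[g]).astype(np.int8))
    markers = default_marker_table(
        [f"mk{j:06d}" for j in range(m)], config.n_chromosomes
    )
    return GenotypeMatrix(ids, markers, np.array(rows)), groups, freqs


def _gametes(parent: np.ndarray, n: int, rng, config: SimConfig) -> np.ndarray:
    """n gametes (allele counts 0/1 per marker) from one parent's dosages.

    Unlinked: a heterozygous marker transmits either allele w.p. 1/2.
    With linkage, heterozygous sites are phased uniformly at random once per
    call (founders are simulated in linkage equilibrium, and only
    single-generation crosses are supported) and gametes follow a Haldane
    recombination chain along each chromosome.
    """
    m = parent.size
    het = parent == 1
    if not config.linkage:
        alleles = np.tile((parent // 2).astype(np.int8), (n, 1))
        alleles[:, het] = rng.integers(0, 2, size=(n, int(het.sum())), dtype=np.int8)
        return alleles
    # random phase: hap1/hap2 per site
    hap1 = (parent // 2).astype(np.int8)
    hap2 = hap1.copy()
    phase = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    hap1[het] = phase
    hap2[het] = 1 - phase
    per = int(np.ceil(m / config.n_chromosomes))
    d = config.morgans_per_chromosome / max(per - 1, 1)
    r = 0.5 * (1.0 - np.exp(-2.0 * d))  # Haldane map function
    alleles = np.empty((n, m), dtype=np.int8)
    for start in range(0, m, per):
        stop = min(start + per, m)
        L = stop - start
        state = np.empty((n, L), dtype=bool)
        state[:, 0] = rng.random(n) < 0.5
        flips = rng.random((n, L - 1)) < r
        state[:, 1:] = flips
        np.logical_xor.accumulate(state, axis=1, out=state)
        block = np.where(state, hap2[start:stop], hap1[start:stop])
        alleles[:, start:stop] = block
    return alleles


def cross(p1: np.ndarray, p2: np.ndarray, n_offspring: int, config: SimConfig, rng=None
          ) -> np.ndarray:
    """Offspring dosages from two parents' dosage vectors at shared markers."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("parents genotyped at different marker sets")
    if (p1 == MISSING).any() or (p2 == MISSING).any():
        raise ValueError("parents must have nonmissing calls for crossing")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return (_gametes(p1, n_offspring, rng, config)
            + _gametes(p2, n_offspring, rng, config)).astype(np.int8)


def self_(parent: np.ndarray, n_offspring: int, config: SimConfig, rng=None
          ) -> np.ndarray:
    """S1 offspring of one parent (self-pollination); same as cross(p, p)."""
    return cross(parent, parent, n_offspring, config, rng)


def inject_errors(G: GenotypeMatrix, error_rate: float, missing_rate: float,
                  seed: int) -> GenotypeMatrix:
    """Independently set calls missing w.p. missing_rate, then perturb the
    surviving calls to a different genotype state w.p. error_rate."""
    for r in (error_rate, missing_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0,1]")
    rng = np.random.default_rng(seed)
    calls = G.calls.copy()
    nonmiss = calls != MISSING
    if missing_rate > 0:
        drop = nonmiss & (rng.random(calls.shape) < missing_rate)
        calls[drop] = MISSING
        nonmiss = calls != MISSING
    if error_rate > 0:
        err = nonmiss & (rng.random(calls.shape) < error_rate)
        # shift to one of the two other states uniformly
        shift = rng.integers(1, 3, size=calls.shape, dtype=np.int8)
        calls[err] = (calls[err] + shift[err]) % 3
    return GenotypeMatrix(list(G.ids), G.markers.copy(), calls)


def _draw_qtl_effects(config: SimConfig, trait: TraitConfig, rng,
                      group_freqs: dict[str, np.ndarray] | None = None
                      ) -> pd.DataFrame:
    pool = np.arange(config.n_markers)
    if trait.qtl_balanced and group_freqs is not None:
        gap = np.abs(group_freqs["elite"] - group_freqs["exotic"])
        cut = np.quantile(gap, 0.3)
        balanced = pool[gap <= cut]
        if balanced.size >= trait.n_qtl:
            pool = balanced
        idx = rng.choice(pool, size=min(trait.n_qtl, pool.size), replace=False)
    elif trait.qtl_elite_fixed and group_freqs is not None:
        # favorable allele near fixation among elites, much rarer in exotics
        gap = group_freqs["elite"] - group_freqs["exotic"]
        eligible = pool[group_freqs["elite"] >= 0.7]
        order = eligible[np.argsort(gap[eligible])[::-1]]
        if order.size < trait.n_qtl:
            rest = pool[group_freqs["elite"] < 0.7]
            order = np.concatenate(
                [order, rest[np.argsort(group_freqs["elite"][rest])[::-1]]])
        idx = np.sort(order[: trait.n_qtl])
    else:
        idx = rng.choice(pool, size=min(trait.n_qtl, pool.size), replace=False)
    a = rng.exponential(trait.additive_effect_scale, size=idx.size)
    delta = rng.normal(trait.delta_mean, trait.delta_sd, size=idx.size)
    n_load = int(round(trait.load_fraction * idx.size))
    is_load = np.zeros(idx.size, dtype=bool)
    if n_load:
        is_load[rng.choice(idx.size, size=n_load, replace=False)] = True
        # deleterious alleles are partially recessive: heterozygote sits close
        # to the favorable homozygote
        delta[is_load] = np.abs(rng.normal(max(trait.delta_mean, 0.8),
                                           trait.delta_sd, size=n_load))
    return pd.DataFrame({
        "trait": trait.name,
        "marker_index": idx,
        "a": a,
        "d": delta * a,
        "is_load": is_load,
    })


def genetic_values(calls: np.ndarray, qtl: pd.DataFrame) -> np.ndarray:
    """Total genetic value per individual: dosage 0 -> -a, 1 -> d, 2 -> +a."""
    idx = qtl["marker_index"].to_numpy()
    a = qtl["a"].to_numpy()
    d = qtl["d"].to_numpy()
    dos = calls[:, idx].astype(float)
    val = np.where(dos == 1, d, (dos - 1.0) * a)
    return val.sum(axis=1)


def simulate_phenotypes(G: GenotypeMatrix, truth: TruthRecord, config: SimConfig,
                        rng=None, individuals: list[str] | None = None
                        ) -> pd.DataFrame:
    """Long-format trial records: individual, block, year, harvest, trait, value.

    plot value = mu + g(QTLs) + block + year + GxY + residual, each random
    term Gaussian with the configured (plot-level) variance.  Harvest-level
    records are constructed so that the plot aggregation (season total for
    "sum" traits, season mean for "mean" traits) reproduces the configured
    variance components exactly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ids = individuals if individuals is not None else list(G.ids)
    rows_idx = [G.ids.index(s) for s in ids]
    n, ny, nb, nh = len(ids), config.n_years, config.n_blocks, config.n_harvests
    recs = []
    for trait in config.traits:
        q = truth.qtl[truth.qtl["trait"] == trait.name]
        g = genetic_values(G.calls[rows_idx], q) if len(q) else np.zeros(n)
        be = rng.normal(0, np.sqrt(trait.var_block), size=nb)
        ye = rng.normal(0, np.sqrt(trait.var_year), size=ny)
        gye = rng.normal(0, np.sqrt(trait.var_gxy), size=(n, ny))
        plot_mean = (trait.mu + g[:, None, None] + be[None, None, :]
                     + ye[None, :, None] + gye[:, :, None])  # (n, ny, nb)
        if trait.aggregate == "sum":
            hmean = plot_mean / nh
            hsd = np.sqrt(trait.var_resid / nh)
        else:
            hmean = plot_mean
            hsd = np.sqrt(trait.var_resid * nh)
        vals = hmean[..., None] + rng.normal(0, hsd, size=(n, ny, nb, nh))
        ii, yy, bb, hh = np.unravel_index(np.arange(vals.size), vals.shape)
        recs.append(pd.DataFrame({
            "individual": np.asarray(ids, dtype=object)[ii],
            "block": bb + 1,
            "year": yy + 1,
            "harvest": hh + 1,
            "trait": trait.name,
            "value": vals.ravel(),
        }))
    return pd.concat(recs, ignore_index=True)


def aggregate_plots(records: pd.DataFrame, traits: list[TraitConfig] | None = None
                    ) -> pd.DataFrame:
    """Aggregate harvest-level records to plot-level season values.

    Yield-like traits are summed across harvests, quality-like traits
    averaged; the rule comes from the trait config ("sum"/"mean"), defaulting
    to mean for unknown traits.
    """
    how = {}
    if traits:
        how = {t.name: t.aggregate for t in traits}
    out = []
    for (trait, ind, yr, bl), grp in records.groupby(
            ["trait", "individual", "year", "block"], sort=False):
        f = how.get(trait, "mean")
        v = grp["value"].sum() if f == "sum" else grp["value"].mean()
        out.append((ind, bl, yr, trait, v))
    return pd.DataFrame(out, columns=["individual", "block", "year", "trait", "value"])


def simulate_study(config: SimConfig):
    """Full study bundle: genotypes, truth, phenotype records, pedigree.

    Mating design mirrors the target study: elite x elite F1s, elite x exotic
    F1s, and S1 selfs of a subset of elite parents.  One exotic founder is
    left unphenotyped (a donor that cannot be clonally propagated), so its
    hybrids have best-parent but no mid-parent contrasts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    founders, groups, freqs = simulate_founders(config, rng)
    m = config.n_markers
    elite_ids = [s for s, g in groups.items() if g == "elite"]
    exotic_ids = [s for s, g in groups.items() if g == "exotic"]

    ids = list(founders.ids)
    calls = [founders.calls]
    ped = [(s, None, None, groups[s]) for s in ids]

    def add(child, p1, p2, grp, dosage):
        ids.append(child)
        groups[child] = grp
        ped.append((child, p1, p2, grp))
        calls.append(dosage[None, :])

    for k in range(config.n_elite_hybrids):
        p1, p2 = rng.choice(len(elite_ids), size=2, replace=False)
        p1, p2 = elite_ids[p1], elite_ids[p2]
        off = cross(founders.row(p1), founders.row(p2), 1, config, rng)[0]
        add(f"exe_{k:04d}", p1, p2, "elite_x_elite", off)
    for k in range(config.n_exotic_hybrids):
        p1 = elite_ids[int(rng.integers(len(elite_ids)))]
        p2 = exotic_ids[int(rng.integers(len(exotic_ids)))]
        off = cross(founders.row(p1), founders.row(p2), 1, config, rng)[0]
        add(f"exo_{k:04d}", p1, p2, "elite_x_exotic", off)
    selfed = elite_ids[: config.n_selfed_parents]
    for k in range(config.n_s1_offspring):
        p = selfed[k % len(selfed)]
        off = self_(founders.row(p), 1, config, rng)[0]
        add(f"s1_{k:04d}", p, p, "s1", off)

    G = GenotypeMatrix(ids, founders.markers.copy(), np.vstack(calls))
    qtl = pd.concat([_draw_qtl_effects(config, t, rng, freqs)
                     for t in config.traits], ignore_index=True)
    gv = pd.DataFrame(index=ids)
    for t in config.traits:
        q = qtl[qtl["trait"] == t.name]
        gv[t.name] = genetic_values(G.calls, q)
    pedigree = pd.DataFrame(ped, columns=["child", "parent1", "parent2", "group"])
    truth = TruthRecord(qtl, gv, groups, pedigree, freqs)

    phenotyped = [s for s in ids if s not in exotic_ids[-1:]] if exotic_ids else ids
    records = simulate_phenotypes(G, truth, config, rng, individuals=phenotyped)

    if config.genotype_error_rate > 0 or config.missing_rate > 0:
        G_obs = inject_errors(G, config.genotype_error_rate, config.missing_rate,
                              config.seed + 2)
    else:
        G_obs = G
    return G_obs, truth, records


def write_study(out_dir, G: GenotypeMatrix, truth: TruthRecord,
                records: pd.DataFrame) -> dict:
    """Write genotypes (VCF + CSV dosage), pedigree truth, and phenotypes."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "dosage": out / "genotypes.csv",
        "pedigree": out / "pedigree.csv",
        "phenotypes": out / "phenotypes.csv",
        "qtl": out / "qtl_truth.csv",
    }
    G.to_vcf(paths["vcf"])
    G.to_csv(paths["dosage"])
    truth.pedigree.to_csv(paths["pedigree"], index=False)
    records.to_csv(paths["phenotypes"], index=False)
    truth.qtl.to_csv(paths["qtl"], index=False)
    return {k: str(v) for k, v in paths.items()}
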