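"""Configuration objects for the simulator and the pipeline.

The simulator's defaults emulate the study design this package targets: a
small elite breeding population (27 founders) plus a handful of exotic
donors (3), biparental F1 families and S1 selfs, a randomized complete
blocks clonal trial with three blocks repeated over two years, and traits
whose QTLs carry directional dominance (heterotic, inbreeding-depressed
traits) or none (neutral quality traits).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class TraitConfig:
    """Genetic architecture and trial noise for one simulated trait.

    delta_mean / delta_sd parameterize the dominance ratio delta = d/|a|;
    a positive mean encodes directional dominance (the prerequisite for
    heterosis under the dominance hypothesis), mean 0 encodes a neutral
    trait.  load_fraction of the QTLs carry deleterious partially recessive
    alleles: the unfavorable allele is made common in both groups so that
    its depression surfaces mainly under selfing.
    """

    name: str = "yield"
    n_qtl: int = 100
    additive_effect_scale: float = 1.0
    delta_mean: float = 0.8
    delta_sd: float = 0.2
    load_fraction: float = 0.3
    mu: float = 0.0
    var_block: float = 0.05
    var_year: float = 0.10
    var_gxy: float = 0.50
    var_resid: float = 2.00
    aggregate: str = "sum"  # harvest records -> plot value: "sum" or "mean"
    # restrict QTLs to markers with similar frequencies in both founder
    # groups (an unselected trait whose loci still segregate everywhere)
    qtl_balanced: bool = False
    # place QTLs at markers where the favorable (counted) allele is near
    # fixation in the elite group but not in the exotic group — the footprint
    # of long-term selection that makes heterosis reappear in wide hybrids
    qtl_elite_fixed: bool = False

    def validate(self) -> None:
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")
        if not 0.0 <= self.load_fraction <= 1.0:
            raise ValueError("load_fraction must be in [0,1]")
        for v in (self.var_block, self.var_year, self.var_gxy, self.var_resid):
            if v < 0:
                raise ValueError("variance components must be >= 0")
        if self.aggregate not in ("sum", "mean"):
            raise ValueError("aggregate must be 'sum' or 'mean'")


def default_traits() -> list[TraitConfig]:
    """Trait set emulating the study: three heterotic yield-component traits
    with directional dominance and one unselected quality trait without."""
    return [
        TraitConfig("yield", 100, 1.0, 0.8, 0.2, 0.3, 50.0, 0.5, 1.0, 4.0, 16.0, "sum"),
        TraitConfig("count", 80, 0.5, 0.7, 0.2, 0.3, 25.0, 0.2, 0.4, 1.0, 4.0, "sum"),
        TraitConfig("weight", 80, 0.5, 0.5, 0.2, 0.2, 25.0, 0.1, 0.2, 0.5, 2.0, "mean"),
        TraitConfig("anc", 60, 1.0, 0.0, 0.2, 0.0, 100.0, 0.5, 1.0, 4.0, 16.0,
                    "mean", qtl_balanced=True),
    ]


@dataclass
class SimConfig:
    """Breeding-population simulator configuration.

    divergence is a Balding-Nichols-style between-group allele-frequency
    divergence in [0,1]: group frequencies are Beta draws around a shared
    ancestral frequency with E[FST] ~ divergence.

    n_elite_ancestors models the breeding bottleneck of a closed elite
    population: elite founders descend from crosses among this small
    ancestor pool, so they are consanguineous and their hybrids lose
    heterozygosity at a rate of roughly 1/(2 * n_elite_ancestors) per
    generation (a one-generation effective population size of about
    n_elite_ancestors).  Set to 0 to draw elite founders straight from the
    group frequencies (unrelated founders, no decay).
    """

    n_elite_founders: int = 27
    n_exotic_founders: int = 3
    n_elite_ancestors: int = 4
    n_markers: int = 28523
    n_chromosomes: int = 28
    divergence: float = 0.2
    n_elite_hybrids: int = 356
    n_exotic_hybrids: int = 113
    n_selfed_parents: int = 9
    n_s1_offspring: int = 31
    traits: list[TraitConfig] = field(default_factory=default_traits)
    n_years: int = 2
    n_blocks: int = 3
    n_harvests: int = 12
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    linkage: bool = False
    morgans_per_chromosome: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_elite_founders,
            self.n_exotic_founders,
            self.n_markers,
            self.n_chromosomes,
            self.n_years,
            self.n_blocks,
            self.n_harvests,
        )
        if any(c < 1 for c in counts):
            raise ValueError("counts must be >= 1")
        if self.n_elite_ancestors == 1:
            raise ValueError("n_elite_ancestors must be 0 (off) or >= 2")
        for p in (self.divergence, self.genotype_error_rate, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/divergence must be in [0,1]")
        for t in self.traits:
            t.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "traits" in d:
            d["traits"] = [
                t if isinstance(t, TraitConfig) else TraitConfig(**t)
                for t in d["traits"]
            ]
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Exactly one of (genotypes/phenotypes/pedigree paths | sim) drives a run;
    when input paths are absent the pipeline falls back to simulation.
    """

    genotypes: str | None = None
    phenotypes: str | None = None
    pedigree: str | None = None
    sim: SimConfig | None = None
    maf_min: float = 0.05
    max_missing: float = 0.10
    min_call_rate: float = 0.90
    alpha: float = 0.05
    forensics_threshold: float = 0.01
    scan_threshold: float = 5e-8
    traits: list[str] | None = None
    out_dir: str = "hetfix_out"
    seed: int = 0

    def validate(self) -> None:
        paths = [self.genotypes, self.phenotypes, self.pedigree]
        have_paths = any(p is not None for p in paths)
        if have_paths and self.sim is not None:
            raise ValueError("provide either input paths or a sim config, not both")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig.from_dict(raw["sim"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
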