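"""Single-locus generation-means theory of heterosis.

Genotype values follow the standard generation-means parameterization:
dosages 0, 1, 2 of the favorable allele take values -a, d, +a, where a is
half the homozygote difference and d the dominance deviation.  For a locus
with favorable-allele frequencies p1 and p2 in two random-mating parent
populations:

    population mean    M(p)   = a (2p - 1) + 2 p (1-p) d
    panmictic MPH      MPH    = d (p1 - p2)^2
    baseline heterosis B(p,F) = 2 p (1-p) d F     (mean loss at inbreeding F)
    inbred MPH                = MPH + d (p1 q1 + p2 q2)  (parents fully inbred)

All of these vanish as the favorable allele approaches fixation (p -> 1),
which is how heterosis "disappears" in a population where selection has
driven favorable dominant alleles to homozygosity.  Quantities are additive
across independent loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LocusModel:
    """Single biallelic locus: frequencies in two populations plus (a, d)."""

    p1: float
    p2: float
    a: float
    d: float

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2):
            if not 0.0 <= p <= 1.0:
                raise ValueError("allele frequencies must be in [0,1]")

    @property
    def q1(self) -> float:
        return 1.0 - self.p1

    @property
    def q2(self) -> float:
        return 1.0 - self.p2


def population_mean(p: float, a: float, d: float) -> float:
    """HWE population mean: a(2p-1) + 2p(1-p)d."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0,1]")
    return a * (2.0 * p - 1.0) + 2.0 * p * (1.0 - p) * d


def f1_mean(model: LocusModel) -> float:
    """Mean of the F1 between the two populations (random union of gametes)."""
    p1, p2, a, d = model.p1, model.p2, model.a, model.d
    q1, q2 = model.q1, model.q2
    return a * (p1 * p2 - q1 * q2) + d * (p1 * q2 + q1 * p2)


def panmictic_mph(model: LocusModel) -> float:
    """Mid-parent heterosis of the population cross: d (p1 - p2)^2."""
    return model.d * (model.p1 - model.p2) ** 2


def inbred_mph(model: LocusModel) -> float:
    """MPH against fully inbred (F=1) parent-population means.

    Inbreeding removes each parent population's heterozygote contribution
    2 p q d, so inbred-MPH = panmictic MPH + d (p1 q1 + p2 q2).
    """
    return panmictic_mph(model) + model.d * (
        model.p1 * model.q1 + model.p2 * model.q2)


def baseline_heterosis(p: float, d: float, F: float) -> float:
    """Mean loss from inbreeding a population to coefficient F: 2 p q d F."""
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must be in [0,1]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0,1]")
    return 2.0 * p * (1.0 - p) * d * F


def heterosis_decay_curve(p1_path, p2_path, d: float, a: float = 1.0):
    """Panmictic-MPH trajectory along paired frequency paths.

    As |p1 - p2| shrinks to zero (e.g. both frequencies sweeping to
    fixation), MPH decays to zero — the fixation-of-heterosis signature.

    Returns an array of MPH values, one per step.
    """
    p1_path = np.asarray(p1_path, float)
    p2_path = np.asarray(p2_path, float)
    if p1_path.shape != p2_path.shape:
        raise ValueError("frequency paths must have equal length")
    return np.array([
        panmictic_mph(LocusModel(pa, pb, a, d))
        for pa, pb in zip(p1_path, p2_path)])


def multilocus_mph(models: list[LocusModel]) -> float:
    """Total panmictic MPH over independent loci (sum of per-locus MPH)."""
    return float(sum(panmictic_mph(m) for m in models))
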