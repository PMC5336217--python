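"""Single-dataset coalescent + GSM simulation under a demographic scenario."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..coalescent import ROOT_UNITS, StepModel, simulate_scenario_genealogy
from ..datamodel import GenotypeDataset, Locus
from .scenario import PriorSpec, ScenarioSpec


@dataclass(frozen=True)
class LocusModel:
    """Mutational model shared by all loci of a simulated dataset.

    One mutation rate ``mu`` (per locus per generation) and one GSM
    geometric parameter ``P`` are drawn per dataset from their priors and
    shared across loci.  ``clamp`` optionally bounds allele sizes to a
    window of repeat units around the root (DIYABC-style 40-state window);
    by default sizes are unbounded.
    """

    n_loci: int = 14
    motif: int = 2
    mu_prior: PriorSpec = field(
        default_factory=lambda: PriorSpec("uniform", 1e-4, 1e-3)
    )
    p_prior: PriorSpec = field(
        default_factory=lambda: PriorSpec("uniform", 0.1, 0.3)
    )
    clamp: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not (0.0 <= self.p_prior.low and self.p_prior.high < 1.0):
            raise ValueError("GSM parameter prior must lie in [0, 1)")
        if self.mu_prior.low <= 0:
            raise ValueError("mutation rate must be positive")


def simulate_dataset(
    spec: ScenarioSpec,
    params: dict[str, float],
    plan: dict[str, int],
    locus_model: LocusModel,
    rng: np.random.Generator | int,
) -> GenotypeDataset:
    """Simulate one diploid SSR dataset under *spec* at *params*.

    ``plan`` maps sampled pool ID -> number of diploid individuals drawn
    at time 0.  ``params`` must satisfy the scenario constraints and may
    carry per-dataset ``mu`` and ``P``; absent, they are drawn from the
    locus model priors.  Populations of the returned dataset are the
    sampled pools, in plan order; diploid genotypes pair consecutive gene
    copies within a pool (lineages are exchangeable, so this equals
    random pairing in distribution).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if not spec.satisfies_constraints(params):
        bad = [f"{a} > {b}" for a, b in spec.constraints
               if not params[a] > params[b]]
        raise ValueError(
            f"scenario {spec.id}: parameters violate constraint(s) {bad}"
        )
    unknown = set(plan) - set(spec.sampled_pools)
    if unknown:
        raise ValueError(f"plan names unsampled pools: {sorted(unknown)}")
    mu = params.get("mu")
    P = params.get("P")
    if mu is None:
        mu = locus_model.mu_prior.sample(rng)
    if P is None:
        P = locus_model.p_prior.sample(rng)
    step = StepModel.gsm(P)
    sizes, events = spec.concretize(params)
    copies = {p: 2 * n for p, n in plan.items()}

    pops = [p for p in plan if plan[p] > 0]
    n_ind = sum(plan[p] for p in pops)
    calls = np.zeros((n_ind, locus_model.n_loci, 2), dtype=np.int64)
    for l in range(locus_model.n_loci):
        gen = simulate_scenario_genealogy(copies, dict(sizes), events, rng)
        units = gen.drop_mutations(mu, step, rng, root_units=ROOT_UNITS)
        if locus_model.clamp is not None:
            units = np.clip(units, *locus_model.clamp)
        if units.min() < 1:
            # affine shift keeps the locus on its ladder and leaves allele
            # counts, heterozygosities and size variances unchanged
            units = units + (1 - units.min())
        calls[:, l, 0] = units[0::2] * locus_model.motif
        calls[:, l, 1] = units[1::2] * locus_model.motif

    individuals = []
    pop_index = []
    for pi, p in enumerate(pops):
        for i in range(plan[p]):
            individuals.append(f"{p}_{i + 1:04d}")
            pop_index.append(pi)
    loci = [Locus(f"L{l + 1:02d}", locus_model.motif)
            for l in range(locus_model.n_loci)]
    return GenotypeDataset(
        loci=loci,
        populations=pops,
        individuals=individuals,
        pop_index=np.array(pop_index),
        calls=calls,
    )
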