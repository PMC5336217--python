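"""Synthetic SSR genotype datasets with the statistical structure the
analysis pipeline assumes.

Three generators cover the testing needs: a finite-island coalescent
model (per-locus scaled mutation rate theta and scaled migration rate),
single datasets simulated under any demographic scenario (delegating to
the ABC engine's simulator), and a study-shaped fixture: 91 populations,
2,008 diploid individuals, 14 loci, placed on a Eurasian-like coordinate
span with a built-in west-to-east gradient of allelic richness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalescent import ROOT_UNITS, StepModel, simulate_island_genealogy, simulate_locus_alleles
from .datamodel import MISSING, GenotypeDataset, Locus, PopulationMetadata

_INTERNAL_N = 1000.0  # diploid size used to de-scale theta and migration


@dataclass(frozen=True)
class IslandModelConfig:
    """Configuration of the symmetric island-model generator.

    ``theta`` is the per-locus scaled mutation rate 4*N*mu; ``migration``
    the scaled rate 4*N*m (m = per-lineage backward migration probability
    per generation); ``gsm_p`` the GSM geometric parameter.  An optional
    ``divergence_time`` (units of 4N generations) merges all demes into
    one ancestral pool backward in time, enabling the isolation model
    (``migration = 0`` requires it).
    """

    n_populations: int
    n_diploid: int
    n_loci: int
    theta: float
    migration: float
    gsm_p: float = 0.0
    motif: int = 2
    divergence_time: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not 0.0 <= self.gsm_p < 1.0:
            raise ValueError("gsm_p outside [0, 1)")
        if min(self.n_populations, self.n_diploid, self.n_loci) < 1:
            raise ValueError("sizes must be >= 1")
        if self.migration < 0:
            raise ValueError("migration must be >= 0")


def _dataset_from_units(units_by_locus, pops, pop_sizes, motif, raw=False):
    n_ind = sum(pop_sizes)
    n_loci = len(units_by_locus)
    calls = np.zeros((n_ind, n_loci, 2), dtype=np.int64)
    for l, units in enumerate(units_by_locus):
        if units.min() < 1:
            units = units + (1 - units.min())
        calls[:, l, 0] = units[0::2] * motif
        calls[:, l, 1] = units[1::2] * motif
    individuals = []
    pop_index = []
    for pi, (p, size) in enumerate(zip(pops, pop_sizes)):
        for i in range(size):
            individuals.append(f"{p}_{i + 1:04d}")
            pop_index.append(pi)
    return GenotypeDataset(
        loci=[Locus(f"L{l + 1:02d}", motif) for l in range(n_loci)],
        populations=list(pops),
        individuals=individuals,
        pop_index=np.array(pop_index),
        calls=calls,
        raw=raw,
    )


def generate_island_dataset(config: IslandModelConfig) -> GenotypeDataset:
    """Simulate a dataset under the island model (one coalescent kernel
    shared with the scenario simulator)."""
    rng = np.random.default_rng(config.seed)
    mu = config.theta / (4.0 * _INTERNAL_N)
    m = config.migration / (4.0 * _INTERNAL_N)
    t_div = (
        None if config.divergence_time is None
        else config.divergence_time * 4.0 * _INTERNAL_N
    )
    step = StepModel.gsm(config.gsm_p)
    units_by_locus = []
    for _ in range(config.n_loci):
        gen = simulate_island_genealogy(
            config.n_populations,
            2 * config.n_diploid,
            _INTERNAL_N,
            m,
            rng,
            divergence_time=t_div,
        )
        units_by_locus.append(gen.drop_mutations(mu, step, rng))
    pops = [f"POP{p + 1:02d}" for p in range(config.n_populations)]
    return _dataset_from_units(
        units_by_locus, pops, [config.n_diploid] * config.n_populations,
        config.motif,
    )


def generate_from_scenario(scenario, params, plan, locus_model, seed: int):
    """Single-dataset entry point into the scenario simulator."""
    from .abc.simulate import simulate_dataset

    return simulate_dataset(scenario, params, plan, locus_model,
                            np.random.default_rng(seed))


def inject_null_alleles(
    ds: GenotypeDataset,
    locus: str,
    null_freq: float,
    seed: int = 0,
) -> GenotypeDataset:
    """Relabel gene copies at one locus as a non-amplifying (null) allele.

    Each copy independently becomes null with probability *null_freq*;
    under HWE a visible/null heterozygote scores as a homozygote of the
    visible allele, and a null/null pair scores as missing.
    """
    if not 0.0 <= null_freq <= 0.5:
        raise ValueError("null_freq outside [0, 0.5]")
    out = ds.copy()
    if null_freq == 0.0:
        return out
    l = ds.locus_index(locus)
    rng = np.random.default_rng(seed)
    g = out.calls[:, l, :]
    typed = g[:, 0] != MISSING
    nulls = rng.random(g.shape) < null_freq
    both = typed & nulls.all(axis=1)
    first = typed & nulls[:, 0] & ~nulls[:, 1]
    second = typed & ~nulls[:, 0] & nulls[:, 1]
    g[both] = MISSING
    g[first, 0] = g[first, 1]
    g[second, 1] = g[second, 0]
    out.calls[:, l, :] = g
    return out


# ---------------------------------------------------------------------------
# Single-population fixtures for the bottleneck tests
# ---------------------------------------------------------------------------

def equilibrium_population(
    n_diploid: int,
    n_loci: int,
    theta: float,
    step: StepModel | None = None,
    seed: int = 0,
    name: str = "EQ",
) -> GenotypeDataset:
    """A single population at mutation-drift equilibrium (theta = 4*N*mu)."""
    rng = np.random.default_rng(seed)
    step = step or StepModel.gsm(0.0)
    units = [
        simulate_locus_alleles(2 * n_diploid, theta, step, rng)
        for _ in range(n_loci)
    ]
    return _dataset_from_units(units, [name], [n_diploid], motif=2)


def bottlenecked_population(
    n_diploid: int,
    n_loci: int,
    theta: float,
    crash_factor: float = 0.01,
    t_crash: float = 10.0,
    step: StepModel | None = None,
    seed: int = 0,
    name: str = "BN",
) -> GenotypeDataset:
    """A population that crashed to ``crash_factor`` of its long-term size
    *t_crash* generations ago (theta refers to the pre-crash size)."""
    from .coalescent import ConcreteEvent, simulate_scenario_genealogy

    if not 0.0 < crash_factor <= 1.0:
        raise ValueError("crash_factor outside (0, 1]")
    rng = np.random.default_rng(seed)
    step = step or StepModel.gsm(0.0)
    mu = theta / (4.0 * _INTERNAL_N)
    events = [ConcreteEvent(time=t_crash, kind="size", pool="pop",
                            size=_INTERNAL_N)]
    units = []
    for _ in range(n_loci):
        gen = simulate_scenario_genealogy(
            {"pop": 2 * n_diploid},
            {"pop": crash_factor * _INTERNAL_N},
            events, rng,
        )
        units.append(gen.drop_mutations(mu, step, rng))
    return _dataset_from_units(units, [name], [n_diploid], motif=2)


# ---------------------------------------------------------------------------
# Study-shaped fixture
# ---------------------------------------------------------------------------

STUDY_N_POPULATIONS = 91
STUDY_N_INDIVIDUALS = 2008
STUDY_N_LOCI = 14
_FIXTURE_THETA = 14.0         # per-locus theta of the shared ancestral pool;
                              # chosen so the total allele count across the 14
                              # loci lands near the study's ~199
_FIXTURE_GSM_P = 0.2
_FOUNDER_MIN, _FOUNDER_MAX = 8, 44   # gene copies; west -> east


def study_shape_fixture(
    seed: int = 0,
) -> tuple[GenotypeDataset, list[PopulationMetadata]]:
    """A dataset shaped like the walnut study: 91 populations, 2,008
    diploids, 14 dinucleotide loci, with a longitudinal diversity gradient.

    Each locus draws a large ancestral allele pool from a stationary
    coalescent; every population then samples its gene copies through a
    founder subset whose size grows from west (8 copies) to east (44
    copies), emulating serial founder effects of a westward expansion.
    Deterministic under *seed*.
    """
    rng = np.random.default_rng(seed)
    sizes = [23] * (STUDY_N_INDIVIDUALS - 22 * STUDY_N_POPULATIONS)
    sizes += [22] * (STUDY_N_POPULATIONS - len(sizes))
    rng.shuffle(sizes)
    lons = np.linspace(-9.0, 90.0, STUDY_N_POPULATIONS)
    lats = 35.0 + 13.0 * rng.random(STUDY_N_POPULATIONS)
    elevs = np.round(2500.0 * rng.random(STUDY_N_POPULATIONS), 0)
    founder = np.round(
        _FOUNDER_MIN
        + (_FOUNDER_MAX - _FOUNDER_MIN)
        * (lons - lons.min()) / (lons.max() - lons.min())
    ).astype(int)
    step = StepModel.gsm(_FIXTURE_GSM_P)
    pool_copies = 1000
    units_by_locus = []
    for _ in range(STUDY_N_LOCI):
        pool = simulate_locus_alleles(pool_copies, _FIXTURE_THETA, step, rng)
        units = np.empty(2 * STUDY_N_INDIVIDUALS, dtype=np.int64)
        at = 0
        for p in range(STUDY_N_POPULATIONS):
            founders = rng.choice(pool, size=founder[p], replace=False)
            draw = rng.choice(founders, size=2 * sizes[p], replace=True)
            units[at:at + 2 * sizes[p]] = draw
            at += 2 * sizes[p]
        units_by_locus.append(units)
    pops = [f"POP{p + 1:02d}" for p in range(STUDY_N_POPULATIONS)]
    ds = _dataset_from_units(units_by_locus, pops, sizes, motif=2)
    meta = [
        PopulationMetadata(
            population=pops[p],
            latitude=float(lats[p]),
            longitude=float(lons[p]),
            elevation=float(elevs[p]),
            n_samples=sizes[p],
        )
        for p in range(STUDY_N_POPULATIONS)
    ]
    return ds, meta
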