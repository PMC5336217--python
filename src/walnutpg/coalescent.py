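"""Coalescent genealogy simulation with stepwise microsatellite mutation.

One kernel serves every simulation need in the package: the island-model
synthetic-data generator, the equilibrium distributions behind the
bottleneck heterozygosity-excess test, and the demographic-scenario
simulator of the ABC engine.

Time runs backward in generations.  Within a pool of diploid effective
size N, k lineages coalesce pairwise at total rate k(k-1)/(4N) per
generation (continuous-time Kingman coalescent).  Demographic events
(merges, admixtures, size changes) are piecewise-constant changes to the
pool structure.  Mutations are dropped on the finished genealogy as a
Poisson process of rate mu per generation per lineage; each mutation
moves the allele size by a signed integer number of repeat units drawn
from a stepwise model:

* GSM (generalized stepwise model): |step| ~ Geometric(1 - P) on
  {1, 2, ...}, so P = 0 is the strict SMM and the mean step is 1/(1-P);
* TPM (two-phase model): |step| = 1 with probability p_single, otherwise
  geometric with a variance-parameterised success probability.

Signs are fair coin flips.  The root allele is a fixed origin (100 repeat
units by default) so simulated ladders are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ROOT_UNITS = 100


# ---------------------------------------------------------------------------
# Mutation step models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepModel:
    """Distribution of the absolute mutation step size, in repeat units.

    ``p_single`` is the probability of a one-step mutation; with the
    complementary probability the step is Geometric(``geom_q``) on
    {1, 2, ...}.  ``StepModel.gsm(P)`` gives the pure geometric GSM;
    ``StepModel.tpm(p_single, variance)`` the two-phase mixture used by
    bottleneck tests.
    """

    p_single: float
    geom_q: float

    @classmethod
    def gsm(cls, P: float) -> "StepModel":
        if not 0.0 <= P < 1.0:
            raise ValueError(f"GSM parameter P={P} outside [0, 1)")
        return cls(p_single=0.0, geom_q=1.0 - P)

    @classmethod
    def tpm(cls, p_single: float = 0.70, variance: float = 30.0) -> "StepModel":
        if not 0.0 <= p_single <= 1.0:
            raise ValueError("p_single outside [0, 1]")
        if variance <= 0:
            raise ValueError("multistep variance must be > 0")
        # geometric on {1,2,...} with Var = (1-q)/q^2 = variance
        q = (-1.0 + math.sqrt(1.0 + 4.0 * variance)) / (2.0 * variance)
        return cls(p_single=p_single, geom_q=q)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw *n* signed steps."""
        if n == 0:
            return np.zeros(0, dtype=np.int64)
        mag = rng.geometric(self.geom_q, size=n)
        if self.p_single > 0.0:
            single = rng.random(n) < self.p_single
            mag = np.where(single, 1, mag)
        signs = rng.integers(0, 2, size=n) * 2 - 1
        return mag * signs

    @property
    def mean_sq_step(self) -> float:
        """E[step^2]: (1+P)/(1-P)^2 for the pure GSM."""
        q = self.geom_q
        e2_geom = (2.0 - q) / q**2
        return self.p_single * 1.0 + (1.0 - self.p_single) * e2_geom


# ---------------------------------------------------------------------------
# Genealogies
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """A coalescent tree: parent pointers and node times (generations).

    Leaves are nodes ``0 .. n_leaves-1`` at time 0; the root's parent
    is -1.  ``leaf_pool[i]`` is the pool index the leaf was sampled from.
    """

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int
    leaf_pool: np.ndarray

    @property
    def total_length(self) -> float:
        child = np.flatnonzero(self.parent >= 0)
        return float((self.time[self.parent[child]] - self.time[child]).sum())

    def drop_mutations(
        self,
        mu: float,
        step_model: StepModel,
        rng: np.random.Generator,
        root_units: int = ROOT_UNITS,
    ) -> np.ndarray:
        """Mutate along branches; return leaf allele sizes in repeat units."""
        n_nodes = self.parent.size
        alleles = np.empty(n_nodes, dtype=np.int64)
        has_parent = self.parent >= 0
        bl = np.zeros(n_nodes)
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        n_mut = rng.poisson(bl * mu)
        total = int(n_mut.sum())
        steps = step_model.sample(rng, total)
        offsets = np.zeros(n_nodes, dtype=np.int64)
        if total:
            ends = np.cumsum(n_mut)
            starts = ends - n_mut
            sums = np.add.reduceat(steps, starts[n_mut > 0])
            offsets[n_mut > 0] = sums
        # parents always strictly older: process oldest first
        order = np.argsort(-self.time, kind="stable")
        for node in order:
            p = self.parent[node]
            alleles[node] = root_units if p < 0 else alleles[p] + offsets[node]
        return alleles[: self.n_leaves]


class _TreeBuilder:
    """Mutable state while a genealogy is assembled."""

    def __init__(self, n_leaves: int, leaf_pool: np.ndarray):
        n_nodes = 2 * n_leaves - 1
        self.parent = np.full(n_nodes, -1, dtype=np.int64)
        self.time = np.zeros(n_nodes)
        self.next_id = n_leaves
        self.n_leaves = n_leaves
        self.leaf_pool = leaf_pool

    def join(self, a: int, b: int, t: float) -> int:
        node = self.next_id
        self.next_id += 1
        self.parent[a] = node
        self.parent[b] = node
        self.time[node] = t
        return node

    def finish(self) -> Genealogy:
        if self.next_id != self.parent.size:
            raise RuntimeError("genealogy incomplete: lineages did not all coalesce")
        return Genealogy(self.parent, self.time, self.n_leaves, self.leaf_pool)


def _coalesce_within(
    nodes: list[int],
    n_diploid: float,
    t: float,
    deadline: float,
    tb: _TreeBuilder,
    rng: np.random.Generator,
) -> tuple[list[int], float]:
    """Coalesce *nodes* in a pool of diploid size N until *deadline*."""
    k = len(nodes)
    while k >= 2:
        rate = k * (k - 1) / (4.0 * n_diploid)
        t_next = t + rng.exponential(1.0 / rate)
        if t_next > deadline:
            return nodes, deadline
        t = t_next
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        node = tb.join(nodes[i], nodes[j], t)
        # replace i with the new node, drop j
        nodes[i] = node
        nodes[j] = nodes[-1]
        nodes.pop()
        k -= 1
    return nodes, deadline if math.isfinite(deadline) else t


# ---------------------------------------------------------------------------
# Scenario (event-driven) genealogies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcreteEvent:
    """A demographic event with numeric time and parameters (backward time)."""

    time: float
    kind: str          # "merge" | "admix" | "size"
    pool: str          # source (merge), derived (admix), target (size)
    sink: str | None = None      # merge sink / admix parent A
    sink_b: str | None = None    # admix parent B
    rate: float | None = None    # admix: P(lineage -> parent A)
    size: float | None = None    # size change: new diploid N


def simulate_scenario_genealogy(
    sample_sizes: dict[str, int],
    pool_sizes: dict[str, float],
    events: list[ConcreteEvent],
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one gene genealogy under an event timeline.

    ``sample_sizes`` maps pool ID -> number of gene copies sampled at time
    0 (2 x diploids).  ``pool_sizes`` gives each pool's diploid effective
    size at time 0.  Events must be sorted by time (ascending, backward);
    after the last event exactly one pool must remain active.
    """
    leaf_pool = []
    pools_order = list(sample_sizes)
    lineages: dict[str, list[int]] = {p: [] for p in pool_sizes}
    nid = 0
    for pi, p in enumerate(pools_order):
        for _ in range(sample_sizes[p]):
            lineages.setdefault(p, []).append(nid)
            leaf_pool.append(pi)
            nid += 1
    n_leaves = nid
    tb = _TreeBuilder(n_leaves, np.array(leaf_pool, dtype=np.int64))
    sizes = dict(pool_sizes)
    t = 0.0
    for ev in events:
        if ev.time < t - 1e-12:
            raise ValueError("events not sorted by time")
        # coalesce every occupied pool up to the event time
        for p, nodes in lineages.items():
            if len(nodes) >= 2:
                lineages[p], _ = _coalesce_within(nodes, sizes[p], t, ev.time, tb, rng)
        t = ev.time
        if ev.kind == "merge":
            lineages.setdefault(ev.sink, []).extend(lineages.pop(ev.pool, []))
        elif ev.kind == "admix":
            moved = lineages.pop(ev.pool, [])
            go_a = rng.random(len(moved)) < ev.rate
            lineages.setdefault(ev.sink, []).extend(
                n for n, a in zip(moved, go_a) if a
            )
            lineages.setdefault(ev.sink_b, []).extend(
                n for n, a in zip(moved, go_a) if not a
            )
        elif ev.kind == "size":
            sizes[ev.pool] = ev.size
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    occupied = [p for p, nodes in lineages.items() if nodes]
    if len(occupied) != 1:
        raise ValueError(
            f"after the last event {len(occupied)} pools still hold lineages: {occupied}"
        )
    final = occupied[0]
    _coalesce_within(lineages[final], sizes[final], t, math.inf, tb, rng)
    return tb.finish()


# ---------------------------------------------------------------------------
# Island model (structured coalescent with migration)
# ---------------------------------------------------------------------------

def simulate_island_genealogy(
    n_pools: int,
    copies_per_pool: int,
    n_diploid: float,
    migration: float,
    rng: np.random.Generator,
    divergence_time: float | None = None,
    ancestral_size: float | None = None,
) -> Genealogy:
    """Structured coalescent for a symmetric island model.

    ``migration`` is the per-lineage per-generation backward migration
    probability m (destination uniform among the other demes).  If
    ``divergence_time`` is given, all demes merge into one ancestral pool
    of size ``ancestral_size`` (default ``n_diploid``) at that time; with
    ``migration == 0`` a finite divergence time is required.
    """
    if n_pools > 1 and migration <= 0.0 and divergence_time is None:
        raise ValueError("migration = 0 with no divergence time never coalesces")
    n_leaves = n_pools * copies_per_pool
    leaf_pool = np.repeat(np.arange(n_pools), copies_per_pool)
    tb = _TreeBuilder(n_leaves, leaf_pool)
    pools = [list(range(p * copies_per_pool, (p + 1) * copies_per_pool))
             for p in range(n_pools)]
    t = 0.0
    deadline = math.inf if divergence_time is None else divergence_time
    total = n_leaves
    while total > 1:
        ks = np.array([len(nodes) for nodes in pools], dtype=np.int64)
        coal_rates = ks * (ks - 1) / (4.0 * n_diploid)
        mig_rate = migration * total if n_pools > 1 else 0.0
        rate = coal_rates.sum() + mig_rate
        if rate == 0.0:
            break  # isolated singletons: wait for the divergence merge
        t_next = t + rng.exponential(1.0 / rate)
        if t_next > deadline:
            break
        t = t_next
        if rng.random() * rate < mig_rate:
            # migration: uniform lineage, uniform other deme
            li = int(rng.integers(total))
            for p, nodes in enumerate(pools):
                if li < len(nodes):
                    node = nodes[li]
                    nodes[li] = nodes[-1]
                    nodes.pop()
                    dest = int(rng.integers(n_pools - 1))
                    if dest >= p:
                        dest += 1
                    pools[dest].append(node)
                    break
                li -= len(nodes)
        else:
            probs = coal_rates / coal_rates.sum()
            p = int(rng.choice(n_pools, p=probs))
            nodes = pools[p]
            k = len(nodes)
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            node = tb.join(nodes[i], nodes[j], t)
            nodes[i] = node
            nodes[j] = nodes[-1]
            nodes.pop()
            total -= 1
    if total > 1:
        merged = [n for nodes in pools for n in nodes]
        _coalesce_within(
            merged, ancestral_size or n_diploid, deadline, math.inf, tb, rng
        )
    return tb.finish()


# ---------------------------------------------------------------------------
# Single-pool convenience (coalescent units)
# ---------------------------------------------------------------------------

def simulate_locus_alleles(
    n_copies: int,
    theta: float,
    step_model: StepModel,
    rng: np.random.Generator,
    root_units: int = ROOT_UNITS,
) -> np.ndarray:
    """Alleles (repeat units) of *n_copies* gene copies from one pool at
    equilibrium with scaled mutation rate theta = 4*N*mu.

    Time is simulated in generations with N = 1000 and mu = theta/(4N);
    only the product matters for the law of the sample.
    """
    n_diploid = 1000.0
    mu = theta / (4.0 * n_diploid)
    gen = simulate_scenario_genealogy(
        {"pool": n_copies}, {"pool": n_diploid}, [], rng
    )
    return gen.drop_mutations(mu, step_model, rng, root_units=root_units)
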