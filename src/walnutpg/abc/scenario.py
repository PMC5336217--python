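"""Demographic scenarios as backward-time event timelines with priors.

A scenario declares gene pools, a list of events (merge, admixture, size
change) whose times and magnitudes are named parameters, a prior for each
parameter, and strict-inequality ordering constraints among time
parameters.  Scenario files are YAML; the ten walnut scenarios (stage 1:
1a-5a, stage 2: 1b-6b) ship with the package.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from ..coalescent import ConcreteEvent


class ScenarioValidationError(ValueError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """A univariate prior: uniform or log-uniform on (low, high)."""

    dist: str  # "uniform" | "loguniform"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior distribution {self.dist!r}")
        if not self.low < self.high:
            raise ValueError(f"prior bounds {self.low} >= {self.high}")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError("log-uniform prior needs low > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(math.exp(rng.uniform(math.log(self.low), math.log(self.high))))


@dataclass(frozen=True)
class EventSpec:
    """One backward-time event; fields hold parameter *names*."""

    kind: str                  # "merge" | "admix" | "size"
    time: str                  # time parameter name
    pool: str                  # merge source / admix derived / size target
    sink: str | None = None    # merge sink / admix parent A
    sink_b: str | None = None  # admix parent B
    rate: str | None = None    # admix rate parameter (proportion from parent A)
    size: str | None = None    # size parameter (size change)


@dataclass
class ScenarioSpec:
    """A demographic model: pools, events, priors, ordering constraints."""

    id: str
    pools: dict[str, str]              # pool ID -> size parameter name
    sampled_pools: list[str]           # pools with present-day samples
    events: list[EventSpec]
    priors: dict[str, PriorSpec]
    constraints: list[tuple[str, str]] = field(default_factory=list)  # (a, b): a > b
    description: str = ""

    # -- parameter plumbing -------------------------------------------
    def parameter_names(self) -> list[str]:
        names = list(self.priors)
        return names

    def satisfies_constraints(self, params: dict[str, float]) -> bool:
        return all(params[a] > params[b] for a, b in self.constraints)

    def concretize(self, params: dict[str, float]) -> tuple[dict[str, float], list[ConcreteEvent]]:
        """Resolve parameters into initial pool sizes and a sorted event list."""
        sizes = {p: float(params[sp]) for p, sp in self.pools.items()}
        events = []
        for idx, ev in enumerate(self.events):
            t = float(params[ev.time])
            if ev.kind == "merge":
                ce = ConcreteEvent(time=t, kind="merge", pool=ev.pool, sink=ev.sink)
            elif ev.kind == "admix":
                ce = ConcreteEvent(
                    time=t, kind="admix", pool=ev.pool, sink=ev.sink,
                    sink_b=ev.sink_b, rate=float(params[ev.rate]),
                )
            elif ev.kind == "size":
                ce = ConcreteEvent(time=t, kind="size", pool=ev.pool,
                                   size=float(params[ev.size]))
            else:
                raise ScenarioValidationError(f"unknown event kind {ev.kind!r}")
            events.append((t, idx, ce))
        events.sort(key=lambda e: (e[0], e[1]))
        return sizes, [ce for _, _, ce in events]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_constraint_acyclicity(spec: ScenarioSpec) -> None:
    # constraints "a > b" form edges b -> a; a cycle makes them unsatisfiable
    adj: dict[str, list[str]] = {}
    for a, b in spec.constraints:
        adj.setdefault(b, []).append(a)
    seen: dict[str, int] = {}

    def visit(u: str) -> None:
        seen[u] = 1
        for v in adj.get(u, []):
            state = seen.get(v, 0)
            if state == 1:
                raise ScenarioValidationError(
                    f"scenario {spec.id}: cyclic ordering constraints through {v!r}"
                )
            if state == 0:
                visit(v)
        seen[u] = 2

    for node in list(adj):
        if seen.get(node, 0) == 0:
            visit(node)


def _bookkeeping_pass(spec: ScenarioSpec, params: dict[str, float]) -> None:
    """Run the lineage bookkeeping over the concrete timeline."""
    sizes, events = spec.concretize(params)
    active = set(spec.sampled_pools)
    for ev in events:
        if ev.kind == "merge":
            if ev.pool not in active:
                # merging an unoccupied pool is a no-op backward in time
                active.discard(ev.pool)
            else:
                active.discard(ev.pool)
            if ev.sink not in sizes:
                raise ScenarioValidationError(
                    f"scenario {spec.id}: merge sink {ev.sink!r} has no declared size"
                )
            active.add(ev.sink)
        elif ev.kind == "admix":
            if ev.pool in active:
                active.discard(ev.pool)
                for parent in (ev.sink, ev.sink_b):
                    if parent not in sizes:
                        raise ScenarioValidationError(
                            f"scenario {spec.id}: admixture parent {parent!r} undeclared"
                        )
                    active.add(parent)
            if not 0.0 < ev.rate < 1.0:
                raise ScenarioValidationError(
                    f"scenario {spec.id}: admixture rate {ev.rate} outside (0, 1)"
                )
        elif ev.kind == "size":
            if ev.pool not in sizes:
                raise ScenarioValidationError(
                    f"scenario {spec.id}: size change on undeclared pool {ev.pool!r}"
                )
    if len(active) != 1:
        raise ScenarioValidationError(
            f"scenario {spec.id}: {sorted(active)} pools remain after the last "
            "event (exactly one final ancestor required; orphan pool?)"
        )


def validate_scenario(spec: ScenarioSpec, n_probe_draws: int = 20, seed: int = 0):
    """Validate a scenario and return a canonical (midpoint-draw) timeline.

    Checks: every referenced parameter has a prior, admixture-rate priors
    lie inside (0, 1), constraints are acyclic and satisfiable, and under
    the midpoint draw plus *n_probe_draws* random prior draws every
    sampled lineage reaches a single final ancestor.
    """
    referenced: set[str] = set(spec.pools.values())
    for ev in spec.events:
        referenced.add(ev.time)
        if ev.kind == "admix":
            referenced.add(ev.rate)
        if ev.kind == "size":
            referenced.add(ev.size)
    missing = referenced - set(spec.priors)
    if missing:
        raise ScenarioValidationError(
            f"scenario {spec.id}: parameters without priors: {sorted(missing)}"
        )
    for p in spec.sampled_pools:
        if p not in spec.pools:
            raise ScenarioValidationError(
                f"scenario {spec.id}: sampled pool {p!r} undeclared"
            )
    for ev in spec.events:
        if ev.kind == "admix":
            pr = spec.priors[ev.rate]
            if pr.low < 0.0 or pr.high > 1.0:
                raise ScenarioValidationError(
                    f"scenario {spec.id}: admixture-rate prior for {ev.rate!r} "
                    f"outside (0, 1)"
                )
    _check_constraint_acyclicity(spec)

    midpoint = {
        name: (pr.low + pr.high) / 2.0 if pr.dist == "uniform"
        else math.exp((math.log(pr.low) + math.log(pr.high)) / 2.0)
        for name, pr in spec.priors.items()
    }
    if not spec.satisfies_constraints(midpoint):
        midpoint = draw_parameters(spec, np.random.default_rng(seed))
    _bookkeeping_pass(spec, midpoint)
    rng = np.random.default_rng(seed)
    for _ in range(n_probe_draws):
        _bookkeeping_pass(spec, draw_parameters(spec, rng))
    _, timeline = spec.concretize(midpoint)
    return timeline


# ---------------------------------------------------------------------------
# Prior draws
# ---------------------------------------------------------------------------

def draw_parameters(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    locus_model=None,
    max_tries: int = 10_000,
) -> dict[str, float]:
    """Draw a constraint-satisfying parameter vector from the priors.

    Whole-vector rejection: violating draws are discarded and redrawn.  If
    *locus_model* is given, per-dataset mutation parameters ``mu`` and
    ``P`` are appended to the vector.
    """
    for _ in range(max_tries):
        params = {name: pr.sample(rng) for name, pr in spec.priors.items()}
        if spec.satisfies_constraints(params):
            if locus_model is not None:
                params["mu"] = locus_model.mu_prior.sample(rng)
                params["P"] = locus_model.p_prior.sample(rng)
            return params
    raise ScenarioValidationError(
        f"scenario {spec.id}: prior acceptance rate < {1.0 / max_tries:g}; "
        "ordering constraints are inconsistent with the priors"
    )


# ---------------------------------------------------------------------------
# YAML loading and the shipped walnut scenarios
# ---------------------------------------------------------------------------

def _spec_from_mapping(doc: dict) -> ScenarioSpec:
    priors = {
        name: PriorSpec(
            dist=str(p.get("dist", "uniform")),
            low=float(p["low"]),
            high=float(p["high"]),
        )
        for name, p in doc.get("priors", {}).items()
    }
    events = []
    for ev in doc.get("events", []):
        kind = ev["kind"]
        if kind == "merge":
            events.append(EventSpec(kind="merge", time=ev["time"],
                                    pool=str(ev["source"]), sink=str(ev["sink"])))
        elif kind == "admix":
            events.append(EventSpec(kind="admix", time=ev["time"],
                                    pool=str(ev["derived"]),
                                    sink=str(ev["parent_a"]),
                                    sink_b=str(ev["parent_b"]),
                                    rate=ev["rate"]))
        elif kind == "size":
            events.append(EventSpec(kind="size", time=ev["time"],
                                    pool=str(ev["pool"]), size=ev["size"]))
        else:
            raise ScenarioValidationError(f"unknown event kind {kind!r}")
    constraints = []
    for c in doc.get("constraints", []):
        a, op, b = str(c).split()
        if op != ">":
            raise ScenarioValidationError(f"constraint {c!r}: only '>' supported")
        constraints.append((a, b))
    return ScenarioSpec(
        id=str(doc["id"]),
        pools={str(k): str(v) for k, v in doc["pools"].items()},
        sampled_pools=[str(p) for p in doc["sampled_pools"]],
        events=events,
        priors=priors,
        constraints=constraints,
        description=str(doc.get("description", "")),
    )


def load_scenario_yaml(source) -> ScenarioSpec:
    """Load a scenario from a YAML file path or string."""
    from pathlib import Path

    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    return _spec_from_mapping(yaml.safe_load(text))


_BUILTIN = ["1a", "2a", "3a", "4a", "5a", "1b", "2b", "3b", "4b", "5b", "6b"]


def builtin_scenario_names() -> list[str]:
    """Names of the shipped walnut scenarios (stage 1: 1a-5a; stage 2: 1b-6b)."""
    return list(_BUILTIN)


def builtin_scenario(name: str) -> ScenarioSpec:
    """Load one of the shipped walnut demographic scenarios by name."""
    if name not in _BUILTIN:
        raise KeyError(f"unknown scenario {name!r}; available: {_BUILTIN}")
    ref = importlib.resources.files("walnutpg.scenarios") / f"scenario_{name}.yaml"
    return _spec_from_mapping(yaml.safe_load(ref.read_text()))
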