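"""Self-calibration experiments for the ABC machinery.

The walnut genotype data are not public, so the pipeline's operating
characteristics are established on constructed problems instead:

* a trio of deliberately well-separated two-pool toy scenarios
  (plain isolation, recent admixture, recent bottleneck) on which the
  model-choice machinery should recover the generating scenario;
* a two-pool divergence problem with known truth for parameter-recovery
  experiments;
* the closed-form checks of the coalescent + GSM simulator
  (pairwise E[(dX)^2] = theta (1+P)/(1-P)^2, SMM equilibrium
  homozygosity 1/sqrt(1+2 theta)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..coalescent import StepModel, simulate_locus_alleles
from .inference import (
    build_reference_table,
    estimate_parameters,
    posterior_logistic,
    reject_closest,
)
from .scenario import EventSpec, PriorSpec, ScenarioSpec, draw_parameters
from .simulate import LocusModel, simulate_dataset
from .stats import summary_statistics

TOY_PLAN = {"A": 20, "B": 20}
TOY_LOCUS_MODEL = LocusModel(n_loci=14)


def toy_trio_specs() -> list[ScenarioSpec]:
    """Three well-separated two-pool scenarios for model-choice calibration.

    ``isolation``: A and B split t_s generations ago, no later contact.
    ``admixture``: B is a very recent even-ish mixture of A and a ghost
    pool that split from A long ago (high diversity, low A-B distance).
    ``bottleneck``: as isolation but B sits at a tiny size since the
    split's aftermath (strong diversity loss in B).
    """
    n_prior = PriorSpec("uniform", 1000, 10000)
    deep = PriorSpec("uniform", 2000, 8000)
    recent = PriorSpec("uniform", 5, 50)
    isolation = ScenarioSpec(
        id="isolation",
        pools={"A": "NA_", "B": "NB"},
        sampled_pools=["A", "B"],
        events=[
            EventSpec(kind="merge", time="ts", pool="B", sink="A"),
            EventSpec(kind="size", time="ts", pool="A", size="NANC"),
        ],
        priors={"NA_": n_prior, "NB": n_prior, "NANC": n_prior, "ts": deep},
    )
    admixture = ScenarioSpec(
        id="admixture",
        pools={"A": "NA_", "B": "NB", "G": "NG"},
        sampled_pools=["A", "B"],
        events=[
            EventSpec(kind="admix", time="ta", pool="B",
                      sink="A", sink_b="G", rate="r"),
            EventSpec(kind="merge", time="ts", pool="G", sink="A"),
            EventSpec(kind="size", time="ts", pool="A", size="NANC"),
        ],
        priors={
            "NA_": n_prior, "NB": n_prior, "NG": n_prior, "NANC": n_prior,
            "ta": recent, "ts": deep,
            "r": PriorSpec("uniform", 0.3, 0.7),
        },
        constraints=[("ts", "ta")],
    )
    bottleneck = ScenarioSpec(
        id="bottleneck",
        pools={"A": "NA_", "B": "NBSMALL"},
        sampled_pools=["A", "B"],
        events=[
            EventSpec(kind="size", time="tb", pool="B", size="NB"),
            EventSpec(kind="merge", time="ts", pool="B", sink="A"),
            EventSpec(kind="size", time="ts", pool="A", size="NANC"),
        ],
        priors={
            "NA_": n_prior, "NB": n_prior, "NANC": n_prior,
            "NBSMALL": PriorSpec("uniform", 5, 50),
            "tb": recent, "ts": deep,
        },
        constraints=[("ts", "tb")],
    )
    return [isolation, admixture, bottleneck]


def scenario_recovery_rate(
    n_per_scenario: int = 500,
    n_pods: int = 50,
    fraction: float = 0.02,
    seed: int = 0,
) -> float:
    """Fraction of pseudo-observed datasets whose generating toy scenario
    attains the top logistic posterior probability.

    Pods are spread evenly over the three scenarios.
    """
    specs = toy_trio_specs()
    table = build_reference_table(
        specs, n_per_scenario, TOY_PLAN, TOY_LOCUS_MODEL, seed=seed
    )
    hits = 0
    for p in range(n_pods):
        spec = specs[p % len(specs)]
        rng = np.random.default_rng(np.random.SeedSequence([seed, 40_001, p]))
        params = draw_parameters(spec, rng, locus_model=TOY_LOCUS_MODEL)
        ds = simulate_dataset(spec, params, TOY_PLAN, TOY_LOCUS_MODEL, rng)
        vec, _ = summary_statistics(ds)
        if posterior_logistic(table, vec, fraction).best == spec.id:
            hits += 1
    return hits / n_pods


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

RECOVERY_TRUTH = {"N": 2000.0, "t": 50.0}
RECOVERY_PLAN = {"A": 50, "B": 50}
# mutation rate held (essentially) fixed so the effective size is
# identified by within-pool diversity rather than confounded with mu
RECOVERY_LOCUS_MODEL = LocusModel(
    n_loci=14,
    mu_prior=PriorSpec("uniform", 4.99e-4, 5.01e-4),
    p_prior=PriorSpec("uniform", 0.199, 0.201),
)


def recovery_spec() -> ScenarioSpec:
    """Two pools of shared size N splitting t generations ago."""
    return ScenarioSpec(
        id="split",
        pools={"A": "N", "B": "N"},
        sampled_pools=["A", "B"],
        events=[
            EventSpec(kind="merge", time="t", pool="B", sink="A"),
        ],
        priors={
            "N": PriorSpec("uniform", 100, 10000),
            "t": PriorSpec("uniform", 10, 500),
        },
    )


def parameter_recovery_rate(
    n_table: int = 2000,
    n_replicates: int = 50,
    fraction: float = 0.15,
    factor: float = 2.0,
    seed: int = 0,
) -> float:
    """Fraction of replicates whose adjusted posterior medians of N and t
    both fall within *factor* of the generating truth (N=2000, t=50)."""
    spec = recovery_spec()
    table = build_reference_table(
        [spec], n_table, RECOVERY_PLAN, RECOVERY_LOCUS_MODEL, seed=seed
    )
    truth = dict(RECOVERY_TRUTH)
    hits = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 50_001, r]))
        params = {"N": truth["N"], "t": truth["t"],
                  "mu": 5e-4, "P": 0.2}
        ds = simulate_dataset(spec, params, RECOVERY_PLAN,
                              RECOVERY_LOCUS_MODEL, rng)
        vec, _ = summary_statistics(ds)
        post = estimate_parameters(table, vec, "split", fraction=fraction)
        ok = all(
            truth[name] / factor <= post.summary.loc[name, "median"]
            <= truth[name] * factor
            for name in ("N", "t")
        )
        hits += ok
    return hits / n_replicates


# ---------------------------------------------------------------------------
# Simulator vs closed forms
# ---------------------------------------------------------------------------

def pairwise_sq_difference_check(
    thetas=(1.0, 2.0, 5.0),
    ps=(0.0, 0.2),
    n_reps: int = 6000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean squared allele-size difference of two gene copies from one
    stationary pool, against E[(dX)^2] = theta (1+P)/(1-P)^2.

    Returns one row per (theta, P) with the Monte-Carlo mean, its
    standard error, and the closed-form expectation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for theta in thetas:
        for P in ps:
            step = StepModel.gsm(P)
            d2 = np.empty(n_reps)
            for i in range(n_reps):
                a = simulate_locus_alleles(2, theta, step, rng)
                d2[i] = (a[0] - a[1]) ** 2
            rows.append({
                "theta": theta, "P": P,
                "mean_sq_diff": float(d2.mean()),
                "se": float(d2.std(ddof=1) / np.sqrt(n_reps)),
                "expected": theta * (1.0 + P) / (1.0 - P) ** 2,
            })
    return pd.DataFrame(rows)


def smm_homozygosity_check(
    theta: float = 2.0,
    n_loci: int = 500,
    n_copies: int = 50,
    seed: int = 0,
) -> dict[str, float]:
    """Sample homozygosity under the strict SMM against 1/sqrt(1+2 theta).

    Equivalently, expected heterozygosity against 1 - (1+2 theta)^(-1/2).
    """
    rng = np.random.default_rng(seed)
    step = StepModel.gsm(0.0)
    hom = np.empty(n_loci)
    for l in range(n_loci):
        alleles = simulate_locus_alleles(n_copies, theta, step, rng)
        _, counts = np.unique(alleles, return_counts=True)
        p = counts / n_copies
        # small-sample-unbiased homozygosity
        hom[l] = (n_copies * float(np.sum(p**2)) - 1.0) / (n_copies - 1.0)
    return {
        "mean_homozygosity": float(hom.mean()),
        "se": float(hom.std(ddof=1) / np.sqrt(n_loci)),
        "expected": 1.0 / np.sqrt(1.0 + 2.0 * theta),
    }
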