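"""Bottleneck detection: heterozygosity excess under the TPM, the
shifted-allele-distribution (mode-shift) check, and the Garza-Williamson
M-ratio.

The heterozygosity-excess test compares, locus by locus, the unbiased
expected heterozygosity of a sample with the distribution of equilibrium
heterozygosity Heq among coalescent samples conditioned on the observed
allele count, under a two-phase mutation model (default 70% single-step,
30% multistep with geometric step variance 30).  A recent bottleneck
leaves He above Heq because rare alleles are lost faster than
heterozygosity.  Significance is a one-tailed Wilcoxon signed-rank test
across loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coalescent import StepModel, simulate_locus_alleles
from .datamodel import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

M_RATIO_CRITICAL = 0.68  # conventional critical threshold


@dataclass(frozen=True)
class MutationModelTPM:
    """Two-phase mutation model: a fraction of one-step mutations plus
    multistep mutations with a geometric step of given variance."""

    p_single: float = 0.70
    variance: float = 30.0

    def step_model(self) -> StepModel:
        return StepModel.tpm(self.p_single, self.variance)


# ---------------------------------------------------------------------------
# Conditional equilibrium heterozygosity
# ---------------------------------------------------------------------------

def _sample_het(n: int, theta: float, step: StepModel, rng) -> tuple[int, float]:
    alleles = simulate_locus_alleles(n, theta, step, rng)
    _, counts = np.unique(alleles, return_counts=True)
    p = counts / n
    he = n / (n - 1.0) * (1.0 - float(np.sum(p**2)))
    return counts.size, he


def _calibrate_theta(
    k: int, n: int, step: StepModel, rng, n_probe: int = 120
) -> float:
    """Bisection on log(theta) so the mean simulated allele count is ~k."""
    lo, hi = 1e-3, 1e3

    def mean_k(theta: float) -> float:
        return float(np.mean([
            _sample_het(n, theta, step, rng)[0] for _ in range(n_probe)
        ]))

    if mean_k(hi) < k:
        raise ValueError(f"k={k} unattainable with n={n} gene copies")
    for _ in range(14):
        mid = math.sqrt(lo * hi)
        if mean_k(mid) < k:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def equilibrium_het_distribution(
    k: int,
    n: int,
    model: MutationModelTPM = MutationModelTPM(),
    nreps: int = 10_000,
    seed: int | np.random.Generator = 0,
    max_attempt_factor: int = 200,
) -> np.ndarray:
    """Sample of equilibrium heterozygosities Heq conditioned on k alleles.

    Simulates *n* gene copies from a stationary coalescent with the TPM,
    with theta calibrated by bisection so the mean allele count is about
    *k*, then keeps only runs with exactly *k* alleles until *nreps* are
    collected.
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n (got k={k}, n={n})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    step = model.step_model()
    theta = _calibrate_theta(k, n, step, rng)
    out = np.empty(nreps)
    got = 0
    attempts = 0
    max_attempts = max_attempt_factor * nreps
    while got < nreps:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not collect {nreps} runs with exactly {k} alleles "
                f"after {attempts} attempts (acceptance too low)"
            )
        ka, he = _sample_het(n, theta, step, rng)
        if ka == k:
            out[got] = he
            got += 1
    return out


# ---------------------------------------------------------------------------
# Heterozygosity-excess test
# ---------------------------------------------------------------------------

@dataclass
class HetExcessResult:
    per_locus: pd.DataFrame   # n, k, He, Heq_mean, Heq_sd, std_diff
    p_excess: float           # one-tailed Wilcoxon (heterozygosity excess)
    n_polymorphic: int


def het_excess_test(
    ds: GenotypeDataset,
    population: str,
    model: MutationModelTPM = MutationModelTPM(),
    nreps: int = 10_000,
    seed: int = 0,
    heq_cache: dict | None = None,
) -> HetExcessResult:
    """TPM heterozygosity-excess test for one population.

    ``heq_cache`` optionally memoises the conditional Heq samples by
    (k, n, model, nreps): the null depends only on those, so a cache can
    be shared across populations scored under the same model.
    """
    rows = ds.pop_rows(population)
    records = []
    diffs = []
    for l, locus in enumerate(ds.loci):
        g = ds.calls[rows][:, l, :]
        copies = g[g != MISSING]
        n = copies.size
        if n < 4:
            continue
        alleles, counts = np.unique(copies, return_counts=True)
        k = alleles.size
        if k < 2:
            continue
        p = counts / n
        he = n / (n - 1.0) * (1.0 - float(np.sum(p**2)))
        key = (k, n, model.p_single, model.variance, nreps)
        if heq_cache is not None and key in heq_cache:
            heq = heq_cache[key]
        else:
            heq = equilibrium_het_distribution(
                k, n, model, nreps=nreps,
                seed=np.random.default_rng(
                    np.random.SeedSequence([seed, k, n])
                ),
            )
            if heq_cache is not None:
                heq_cache[key] = heq
        mean, sd = float(heq.mean()), float(heq.std(ddof=1))
        std_diff = (he - mean) / sd if sd > 0 else np.nan
        records.append({
            "locus": locus.name, "n": n, "k": k, "He": he,
            "Heq_mean": mean, "Heq_sd": sd, "std_diff": std_diff,
        })
        if math.isfinite(std_diff):
            diffs.append(std_diff)
    if len(diffs) < 4:
        raise ValueError(
            f"population {population!r}: only {len(diffs)} polymorphic "
            "loci; the Wilcoxon test needs at least four"
        )
    diffs = np.asarray(diffs)
    method = "exact" if len(diffs) <= 25 and np.all(diffs != 0) else "approx"
    p = float(sps.wilcoxon(diffs, alternative="greater", method=method).pvalue)
    return HetExcessResult(
        per_locus=pd.DataFrame(records).set_index("locus"),
        p_excess=p,
        n_polymorphic=len(diffs),
    )


# ---------------------------------------------------------------------------
# Mode shift
# ---------------------------------------------------------------------------

def mode_shift(ds: GenotypeDataset, population: str) -> str:
    """Classify the allele-frequency spectrum of a population.

    Allele frequencies (pooled over loci) are binned into ten classes of
    width 0.1.  "L-shaped" (the equilibrium expectation) iff the lowest
    class (0, 0.1] holds strictly the most alleles; ties count as
    "shifted" (conservative toward signalling disturbance).
    """
    rows = ds.pop_rows(population)
    freqs = []
    for l in range(ds.n_loci):
        g = ds.calls[rows][:, l, :]
        copies = g[g != MISSING]
        if copies.size == 0:
            continue
        _, counts = np.unique(copies, return_counts=True)
        if counts.size < 2:
            continue
        freqs.extend((counts / copies.size).tolist())
    if not freqs:
        raise ValueError(f"population {population!r}: no polymorphic locus")
    bins = np.clip((np.ceil(np.asarray(freqs) * 10.0) - 1).astype(int), 0, 9)
    hist = np.bincount(bins, minlength=10)
    return "L-shaped" if hist[0] > hist[1:].max() else "shifted"


# ---------------------------------------------------------------------------
# M-ratio
# ---------------------------------------------------------------------------

@dataclass
class MRatioResult:
    per_locus: pd.Series
    mean: float
    below_critical: bool


def m_ratio(ds: GenotypeDataset, population: str) -> MRatioResult:
    """Garza-Williamson M = k / (r + 1) per locus and its mean.

    k is the allele count and r the allele-size range in repeat units.
    Only loci with >= 2 alleles in the population define an M.  The mean
    is compared against the conventional 0.68 critical value.
    """
    rows = ds.pop_rows(population)
    per_locus = {}
    for l, locus in enumerate(ds.loci):
        g = ds.calls[rows][:, l, :]
        copies = g[g != MISSING]
        if copies.size == 0:
            continue
        alleles = np.unique(copies)
        if alleles.size < 2:
            continue
        span = int(alleles.max() - alleles.min())
        if span % locus.motif:
            raise ValueError(
                f"locus {locus.name}: size range {span} not a multiple of "
                f"motif {locus.motif}"
            )
        r = span // locus.motif
        per_locus[locus.name] = alleles.size / (r + 1.0)
    if not per_locus:
        raise ValueError(f"population {population!r}: no locus with >= 2 alleles")
    vals = pd.Series(per_locus, name="M")
    mean = float(vals.mean())
    return MRatioResult(per_locus=vals, mean=mean,
                        below_critical=mean < M_RATIO_CRITICAL)
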