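"""Summary statistics of observed and simulated SSR datasets.

The statistic families mirror the ones the model-choice machinery
conditions on: per pool, the mean number of alleles per locus, mean
unbiased expected heterozygosity and mean allele-size variance; per
unordered pool pair, Weir-Cockerham FST and a shared-allele
classification index; per ordered pool pair, the mean individual
assignment log-likelihood.  For P pools the vector has length
3P + C(P,2) + P(P-1) + C(P,2) (36 for four pools).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from ..datamodel import MISSING, GenotypeDataset
from ..diversity import wc_fstats


def stat_names(pools: list[str]) -> list[str]:
    """Column names of the summary-statistic vector, in canonical order."""
    names = [f"A_{p}" for p in pools]
    names += [f"UHE_{p}" for p in pools]
    names += [f"VAR_{p}" for p in pools]
    names += [f"FST_{a}_{b}" for a, b in itertools.combinations(pools, 2)]
    names += [f"AIL_{a}_{b}" for a, b in itertools.permutations(pools, 2)]
    names += [f"DAS_{a}_{b}" for a, b in itertools.combinations(pools, 2)]
    return names


def summary_statistics(
    ds: GenotypeDataset,
    pools: dict[str, list[str]] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Compute the summary-statistic vector of *ds*.

    ``pools`` optionally groups populations into named gene pools (each
    population may appear in one group); by default every population is
    its own pool.  Returns ``(values, names)``.
    """
    if pools is not None:
        ds = ds.merge_populations(pools)
    pool_ids = list(ds.populations)
    if len(pool_ids) < 2:
        raise ValueError("need >= 2 pools for the between-pool statistics")
    rows = {p: ds.pop_rows(p) for p in pool_ids}
    for p, r in rows.items():
        if r.size < 2:
            raise ValueError(f"pool {p!r} has < 2 individuals")

    # ---- per-pool single-sample statistics
    a_mean, uhe_mean, var_mean = {}, {}, {}
    for p in pool_ids:
        a_vals, uhe_vals, var_vals = [], [], []
        for l in range(ds.n_loci):
            sub = ds.calls[rows[p]][:, l, :]
            copies = sub[sub != MISSING].astype(float)
            if copies.size < 2:
                continue
            alleles, counts = np.unique(copies, return_counts=True)
            n2 = copies.size
            freqs = counts / n2
            he = 1.0 - np.sum(freqs**2)
            a_vals.append(alleles.size)
            uhe_vals.append(n2 / (n2 - 1) * he)
            var_vals.append(float(np.var(copies, ddof=1)))
        a_mean[p] = float(np.mean(a_vals))
        uhe_mean[p] = float(np.mean(uhe_vals))
        var_mean[p] = float(np.mean(var_vals))

    # ---- pairwise FST (multilocus Weir-Cockerham theta)
    fst = {}
    for a, b in itertools.combinations(pool_ids, 2):
        sub = ds.subset_populations([a, b])
        res = wc_fstats(sub)
        theta = res.overall["theta"]
        fst[(a, b)] = 0.0 if not math.isfinite(theta) else float(theta)

    # ---- assignment log-likelihoods (add-one smoothed, log10)
    ail = _assignment_loglik(ds, pool_ids, rows)

    # ---- shared-allele classification index
    das = _classification_index(ds, pool_ids, rows)

    values = (
        [a_mean[p] for p in pool_ids]
        + [uhe_mean[p] for p in pool_ids]
        + [var_mean[p] for p in pool_ids]
        + [fst[pair] for pair in itertools.combinations(pool_ids, 2)]
        + [ail[pair] for pair in itertools.permutations(pool_ids, 2)]
        + [das[pair] for pair in itertools.combinations(pool_ids, 2)]
    )
    return np.array(values, dtype=float), stat_names(pool_ids)


def _assignment_loglik(ds, pool_ids, rows):
    """Mean log10 genotype likelihood of pool *a* individuals under pool
    *b* allele frequencies, add-one smoothed over the locus allele set."""
    out = {}
    # per locus: allele list + per-pool smoothed frequencies
    locus_freqs = []
    for l in range(ds.n_loci):
        alleles, mat = ds.counts_by_population(l)
        k = alleles.size
        if k == 0:
            locus_freqs.append(None)
            continue
        totals = mat.sum(axis=1, keepdims=True)
        freqs = (mat + 1.0) / (totals + k)
        locus_freqs.append((alleles, freqs))
    for a, b in itertools.permutations(pool_ids, 2):
        bi = ds.populations.index(b)
        lls = []
        for i in rows[a]:
            ll = 0.0
            for l in range(ds.n_loci):
                if locus_freqs[l] is None:
                    continue
                x, y = ds.calls[i, l]
                if x == MISSING:
                    continue
                alleles, freqs = locus_freqs[l]
                px = freqs[bi, np.searchsorted(alleles, x)]
                if x == y:
                    ll += math.log10(px * px)
                else:
                    py = freqs[bi, np.searchsorted(alleles, y)]
                    ll += math.log10(2.0 * px * py)
            lls.append(ll)
        out[(a, b)] = float(np.mean(lls))
    return out


def shared_allele_distance(ds: GenotypeDataset) -> np.ndarray:
    """Pairwise DAS matrix: DAS(x, y) = 1 - shared alleles / (2 x loci).

    Shared alleles at a locus is the multiset intersection size of the two
    diploid genotypes (0, 1 or 2); loci missing in either individual are
    excluded from both numerator and denominator.
    """
    n = ds.n_individuals
    shared = np.zeros((n, n))
    valid = np.zeros((n, n))
    for l in range(ds.n_loci):
        g = np.sort(ds.calls[:, l, :], axis=1)
        a, b = g[:, 0], g[:, 1]
        present = a != MISSING
        hom = a == b
        ac = a[:, None] == a[None, :]
        ad = a[:, None] == b[None, :]
        bc = b[:, None] == a[None, :]
        bd = b[:, None] == b[None, :]
        both_hom = hom[:, None] & hom[None, :]
        x_hom = hom[:, None] & ~hom[None, :]
        y_hom = ~hom[:, None] & hom[None, :]
        both_het = ~hom[:, None] & ~hom[None, :]
        s = np.zeros((n, n), dtype=np.int64)
        s += np.where(both_hom, 2 * ac.astype(np.int64), 0)
        s += np.where(x_hom, (ac | ad).astype(np.int64), 0)
        s += np.where(y_hom, (ac | bc).astype(np.int64), 0)
        s += np.where(both_het, ac.astype(np.int64) + ad + bc + bd, 0)
        ok = present[:, None] & present[None, :]
        shared += np.where(ok, s, 0)
        valid += ok
    with np.errstate(invalid="ignore"):
        das = 1.0 - shared / (2.0 * valid)
    np.fill_diagonal(das, 0.0)
    return das


def _classification_index(ds, pool_ids, rows):
    """Fraction of individuals closer (mean DAS, self excluded) to their
    own pool than to the other, averaged over the two directions."""
    das = shared_allele_distance(ds)
    out = {}
    mean_to = {}
    for p in pool_ids:
        r = rows[p]
        sums = das[:, r].sum(axis=1)
        counts = np.full(ds.n_individuals, r.size, dtype=float)
        counts[r] -= 1.0  # self excluded for own-pool means
        # the zero diagonal of das already excludes self from own-pool sums
        mean_to[p] = sums / np.maximum(counts, 1.0)
    for a, b in itertools.combinations(pool_ids, 2):
        da, db = mean_to[a][rows[a]], mean_to[b][rows[a]]
        correct_a = np.mean((da < db) + 0.5 * (da == db))
        da, db = mean_to[b][rows[b]], mean_to[a][rows[b]]
        correct_b = np.mean((da < db) + 0.5 * (da == db))
        out[(a, b)] = float((correct_a + correct_b) / 2.0)
    return out
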