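"""Per-locus and per-population SSR diversity and differentiation estimators.

Conventions
-----------
* ``locus_summary`` pools allele frequencies over populations (GenAlEx
  style); ``population_diversity`` works per population.
* Missing data are handled per locus, complete-case: sample sizes are
  per-locus counts of typed individuals.
* Rarefaction standardises on g gene copies (default 16, i.e. eight
  diploid individuals).
* F-statistics are the Weir & Cockerham (1984) variance-component
  estimators; overall values are ratios of summed components, never
  means of ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import MISSING, GenotypeDataset, PopulationMetadata

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_G = 16


# ---------------------------------------------------------------------------
# Pooled per-locus summary
# ---------------------------------------------------------------------------

def locus_summary(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-locus A, Ae, Ho, HE and PIC with frequencies pooled over pops."""
    rows = []
    for l, locus in enumerate(ds.loci):
        flat = ds.calls[:, l, :]
        present = flat[:, 0] != MISSING
        n = int(present.sum())
        if n == 0:
            logger.warning("locus %s: no genotypes; statistics undefined", locus.name)
            rows.append({"locus": locus.name, "n": 0, "A": np.nan, "Ae": np.nan,
                         "Ho": np.nan, "HE": np.nan, "PIC": np.nan})
            continue
        copies = flat[present].ravel()
        _, counts = np.unique(copies, return_counts=True)
        p = counts / counts.sum()
        he = 1.0 - np.sum(p**2)
        het = np.mean(flat[present, 0] != flat[present, 1])
        # PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
        sq = p**2
        cross = (np.sum(sq) ** 2 - np.sum(sq**2))  # 2*sum_{i<j} p_i^2 p_j^2
        rows.append({
            "locus": locus.name, "n": n, "A": int(p.size),
            "Ae": 1.0 / np.sum(sq), "Ho": float(het), "HE": float(he),
            "PIC": float(1.0 - np.sum(sq) - cross),
        })
    return pd.DataFrame(rows).set_index("locus")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def _missing_prob(n_total: int, n_allele: int, g: int) -> float:
    """C(N - Ni, g) / C(N, g) as a stable product of ratios."""
    if n_allele == 0:
        return 1.0
    if n_total - n_allele < g:
        return 0.0
    out = 1.0
    for j in range(g):
        out *= (n_total - n_allele - j) / (n_total - j)
    return out


def rarefied_allelic_richness(counts, g: int) -> float:
    """Expected allele count in a random subsample of *g* gene copies.

    Rs = sum_i [1 - C(N - N_i, g) / C(N, g)] over alleles with gene-copy
    counts N_i, N = sum N_i.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if g > n:
        raise ValueError(f"rarefaction size g={g} exceeds {n} gene copies")
    if g < 1:
        raise ValueError("g must be >= 1")
    return float(sum(1.0 - _missing_prob(n, int(c), g) for c in counts))


def rarefied_private_richness(counts_by_pop, g: int) -> np.ndarray:
    """Expected number of private alleles per population at depth *g*.

    ``counts_by_pop`` is a (pops x alleles) gene-copy count matrix.  An
    allele contributes to population j the probability it appears in j's
    rarefied sample times the probability it appears in no other
    population's rarefied sample.
    """
    mat = np.asarray(counts_by_pop, dtype=np.int64)
    n_pops, n_alleles = mat.shape
    totals = mat.sum(axis=1)
    if np.any(totals < g):
        raise ValueError(
            f"g={g} exceeds gene copies of population(s) "
            f"{np.flatnonzero(totals < g).tolist()}"
        )
    if n_pops == 1:
        logger.warning("single population: private richness equals allelic richness")
        return np.array([rarefied_allelic_richness(mat[0], g)])
    q = np.empty((n_pops, n_alleles))
    for k in range(n_pops):
        for i in range(n_alleles):
            q[k, i] = 1.0 - _missing_prob(int(totals[k]), int(mat[k, i]), g)
    par = np.empty(n_pops)
    for j in range(n_pops):
        absent_elsewhere = np.prod(1.0 - np.delete(q, j, axis=0), axis=0)
        par[j] = float(np.sum(q[j] * absent_elsewhere))
    return par


# ---------------------------------------------------------------------------
# Weir-Cockerham F-statistics
# ---------------------------------------------------------------------------

@dataclass
class FstatsResult:
    """Weir-Cockerham f (FIS), F (FIT), theta (FST) per locus and overall."""

    per_locus: pd.DataFrame
    overall: dict[str, float]
    components: pd.DataFrame  # summed a, b, c per locus


def _locus_wc_components(ds: GenotypeDataset, l: int):
    """Summed WC84 variance components (a, b, c) for locus *l*."""
    alleles, mat = ds.counts_by_population(l)
    if alleles.size == 0:
        return 0.0, 0.0, 0.0
    n_i = mat.sum(axis=1) / 2.0  # typed diploids per pop
    keep = n_i > 0
    mat, n_i = mat[keep], n_i[keep]
    r = int(keep.sum())
    if r < 2 or alleles.size < 2:
        return 0.0, 0.0, 0.0
    p = mat / (2.0 * n_i[:, None])
    # heterozygote counts carrying each allele, per pop
    het_counts = np.zeros_like(mat, dtype=np.int64)
    flat = ds.calls[:, l, :]
    het = (flat[:, 0] != flat[:, 1]) & (flat[:, 0] != MISSING)
    pop_keep_index = np.flatnonzero(keep)
    pop_remap = {int(old): new for new, old in enumerate(pop_keep_index)}
    idx_a = np.searchsorted(alleles, flat[het, 0])
    idx_b = np.searchsorted(alleles, flat[het, 1])
    pops_het = ds.pop_index[het]
    for pi, ia, ib in zip(pops_het, idx_a, idx_b):
        if int(pi) in pop_remap:
            k = pop_remap[int(pi)]
            het_counts[k, ia] += 1
            het_counts[k, ib] += 1
    h = het_counts / n_i[:, None]

    n_bar = n_i.mean()
    if n_bar <= 1.0:
        return 0.0, 0.0, 0.0
    n_c = (r * n_bar - np.sum(n_i**2) / (r * n_bar)) / (r - 1)
    if n_c <= 0:
        return 0.0, 0.0, 0.0
    p_bar = np.sum(n_i[:, None] * p, axis=0) / (r * n_bar)
    s2 = np.sum(n_i[:, None] * (p - p_bar) ** 2, axis=0) / ((r - 1) * n_bar)
    h_bar = np.sum(n_i[:, None] * h, axis=0) / (r * n_bar)
    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (pq - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        pq - (r - 1) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return float(a.sum()), float(b.sum()), float(c.sum())


def wc_fstats(ds: GenotypeDataset) -> FstatsResult:
    """Weir-Cockerham (1984) f, F and theta per locus and over loci.

    Loci monomorphic over the whole dataset contribute zero components and
    are excluded from the ratios.
    """
    if ds.n_populations < 2:
        raise ValueError("need >= 2 populations")
    comp_rows, stat_rows = [], []
    for l, locus in enumerate(ds.loci):
        a, b, c = _locus_wc_components(ds, l)
        comp_rows.append({"locus": locus.name, "a": a, "b": b, "c": c})
        tot = a + b + c
        stat_rows.append({
            "locus": locus.name,
            "theta": a / tot if tot > 0 else np.nan,
            "F": 1.0 - c / tot if tot > 0 else np.nan,
            "f": 1.0 - c / (b + c) if (b + c) > 0 else np.nan,
        })
    comps = pd.DataFrame(comp_rows).set_index("locus")
    sa, sb, sc = comps["a"].sum(), comps["b"].sum(), comps["c"].sum()
    tot = sa + sb + sc
    overall = {
        "theta": sa / tot if tot > 0 else np.nan,
        "F": 1.0 - sc / tot if tot > 0 else np.nan,
        "f": 1.0 - sc / (sb + sc) if (sb + sc) > 0 else np.nan,
    }
    return FstatsResult(
        per_locus=pd.DataFrame(stat_rows).set_index("locus"),
        overall=overall,
        components=comps,
    )


def pairwise_fst(ds: GenotypeDataset) -> pd.DataFrame:
    """Multilocus WC theta for every population pair (symmetric, zero diag)."""
    pops = ds.populations
    mat = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sub = ds.subset_populations([pops[i], pops[j]])
            theta = wc_fstats(sub).overall["theta"]
            if not math.isfinite(theta):
                logger.warning("pair (%s, %s): FST undefined", pops[i], pops[j])
            mat[i, j] = mat[j, i] = theta
    return pd.DataFrame(mat, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def jost_d(ds: GenotypeDataset) -> tuple[pd.Series, dict[str, float]]:
    """Unbiased Jost D_est per locus plus combined values.

    Per locus: D = (n/(n-1)) (Ht_est - Hs_est)/(1 - Hs_est) with the
    Nei-Chesser small-sample estimators (harmonic-mean sample size).
    Combined across loci by harmonic mean (arithmetic mean also reported).
    """
    if ds.n_populations < 2:
        raise ValueError("need >= 2 populations")
    per_locus = {}
    for l, locus in enumerate(ds.loci):
        _, mat = ds.counts_by_population(l)
        n_i = mat.sum(axis=1) / 2.0
        keep = n_i > 0
        mat, n_i = mat[keep], n_i[keep]
        n = int(keep.sum())
        if n < 2 or mat.shape[1] == 0:
            per_locus[locus.name] = np.nan
            continue
        p = mat / (2.0 * n_i[:, None])
        n_harm = n / np.sum(1.0 / n_i)
        hs = 1.0 - float(np.mean(np.sum(p**2, axis=1)))
        ht = 1.0 - float(np.sum(np.mean(p, axis=0) ** 2))
        hs_est = (2.0 * n_harm / (2.0 * n_harm - 1.0)) * hs
        ht_est = ht + hs_est / (2.0 * n_harm * n)
        if hs_est >= 1.0:
            logger.warning("locus %s: Hs = 1; Jost D undefined", locus.name)
            per_locus[locus.name] = np.nan
            continue
        per_locus[locus.name] = (
            (ht_est - hs_est) / (1.0 - hs_est) * n / (n - 1.0)
        )
    vals = pd.Series(per_locus, name="D_est")
    finite = vals.dropna()
    combined = {
        "arithmetic": float(finite.mean()) if len(finite) else np.nan,
        "harmonic": (
            float(len(finite) / np.sum(1.0 / finite))
            if len(finite) and (finite > 0).all()
            else np.nan
        ),
    }
    return vals, combined


# ---------------------------------------------------------------------------
# Null alleles (EM under HWE)
# ---------------------------------------------------------------------------

@dataclass
class NullAlleleResult:
    frequency: float
    converged: bool
    n_iter: int


def null_allele_em(
    ds: GenotypeDataset,
    locus: str,
    population: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> NullAlleleResult:
    """EM estimate of the null-allele frequency at one locus in one pop.

    Under HWE, apparent homozygotes are mixtures of true homozygotes and
    visible/null heterozygotes; missing genotypes are treated as null
    homozygotes.
    """
    l = ds.locus_index(locus)
    rows = ds.pop_rows(population)
    g = ds.calls[rows][:, l, :]
    typed = g[:, 0] != MISSING
    n_total = g.shape[0]
    n_missing = n_total - int(typed.sum())
    if typed.sum() == 0:
        raise ValueError(f"{population}/{locus}: all genotypes missing")
    if typed.sum() < 20:
        logger.warning(
            "%s/%s: only %d genotypes; EM estimate will be noisy",
            population, locus, int(typed.sum()),
        )
    alleles = np.unique(g[typed])
    k = alleles.size
    het = typed & (g[:, 0] != g[:, 1])
    hom = typed & ~het
    hom_allele_idx = np.searchsorted(alleles, g[hom, 0])
    hom_counts = np.bincount(hom_allele_idx, minlength=k).astype(float)
    het_copy_counts = np.bincount(
        np.searchsorted(alleles, g[het].ravel()), minlength=k
    ).astype(float)

    r = 0.05
    p = np.full(k, (1.0 - r) / k)
    n_copies = 2.0 * n_total
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split apparent homozygotes aa into true aa vs a/null
        with np.errstate(invalid="ignore", divide="ignore"):
            w_true = np.where(
                p > 0, p**2 / (p**2 + 2.0 * p * r), 1.0
            )
        visible_copies = het_copy_counts + hom_counts * (1.0 + w_true)
        null_copies = np.sum(hom_counts * (1.0 - w_true)) + 2.0 * n_missing
        r_new = null_copies / n_copies
        p_new = visible_copies / n_copies
        delta = abs(r_new - r)
        r, p = r_new, p_new
        if delta < tol:
            return NullAlleleResult(float(r), True, it)
    logger.warning("%s/%s: EM did not converge in %d iterations", population, locus, max_iter)
    return NullAlleleResult(float(r), False, it)


# ---------------------------------------------------------------------------
# Single-population FIS and its permutation test
# ---------------------------------------------------------------------------

def _single_pop_fis_components(calls: np.ndarray) -> tuple[float, float]:
    """Summed WC within-population components (b+c, c) over loci/alleles."""
    sum_bc = 0.0
    sum_c = 0.0
    for l in range(calls.shape[1]):
        g = calls[:, l, :]
        typed = g[:, 0] != MISSING
        n = float(typed.sum())
        if n < 2:
            continue
        copies = g[typed].ravel()
        alleles, counts = np.unique(copies, return_counts=True)
        if alleles.size < 2:
            continue
        p = counts / (2.0 * n)
        het = typed & (g[:, 0] != g[:, 1])
        het_counts = np.bincount(
            np.searchsorted(alleles, g[het].ravel()), minlength=alleles.size
        )
        h = het_counts / n
        b = (n / (n - 1.0)) * (
            p * (1.0 - p) - (2.0 * n - 1.0) / (4.0 * n) * h
        )
        c = h / 2.0
        sum_bc += float(np.sum(b + c))
        sum_c += float(np.sum(c))
    return sum_bc, sum_c


def single_population_fis(ds: GenotypeDataset, population: str) -> float:
    """WC within-population inbreeding coefficient f for one population."""
    rows = ds.pop_rows(population)
    bc, c = _single_pop_fis_components(ds.calls[rows])
    return 1.0 - c / bc if bc > 0 else np.nan


@dataclass
class FisTestResult:
    fis: float
    p_two_sided: float      # P(|FIS*| >= |FIS|)
    p_excess_hom: float     # P(FIS* >= FIS), one-tailed for homozygote excess
    n_perm: int


def fis_permutation_test(
    ds: GenotypeDataset,
    population: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> FisTestResult:
    """Permutation test of FIS: alleles shuffled among individuals within
    the population, independently per locus, breaking within-individual
    allele association while preserving allele frequencies."""
    rows = ds.pop_rows(population)
    if rows.size < 5:
        raise ValueError(f"population {population!r} has < 5 individuals")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-values will be coarse", n_perm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calls = ds.calls[rows]
    bc, c = _single_pop_fis_components(calls)
    obs = 1.0 - c / bc if bc > 0 else np.nan
    if not math.isfinite(obs):
        raise ValueError(f"population {population!r}: FIS undefined (monomorphic?)")
    count_abs = 0
    count_ge = 0
    perm = calls.copy()
    for _ in range(n_perm):
        for l in range(calls.shape[1]):
            g = calls[:, l, :]
            typed = g[:, 0] != MISSING
            copies = g[typed].ravel()
            shuffled = rng.permutation(copies)
            perm[typed, l, :] = shuffled.reshape(-1, 2)
            perm[~typed, l, :] = MISSING
        bc_p, c_p = _single_pop_fis_components(perm)
        f_p = 1.0 - c_p / bc_p if bc_p > 0 else 0.0
        if abs(f_p) >= abs(obs):
            count_abs += 1
        if f_p >= obs:
            count_ge += 1
    return FisTestResult(
        fis=float(obs),
        p_two_sided=(count_abs + 1.0) / (n_perm + 1.0),
        p_excess_hom=(count_ge + 1.0) / (n_perm + 1.0),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Per-population diversity summary
# ---------------------------------------------------------------------------

def population_diversity(
    ds: GenotypeDataset,
    g: int = DEFAULT_RAREFACTION_G,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population A, Ae, Ho, HE, UHE, rarefied Rs and PAR, and FIS.

    Rs uses the loci where the population has at least *g* gene copies;
    PAR additionally requires every population to reach *g* copies at the
    locus.  With ``n_perm > 0`` a permutation p-value for FIS (homozygote
    excess) is added.
    """
    counts_cache = [ds.counts_by_population(l) for l in range(ds.n_loci)]
    par_loci = [
        l for l in range(ds.n_loci)
        if counts_cache[l][1].sum(axis=1).min() >= g and counts_cache[l][1].size
    ]
    skipped = ds.n_loci - len(par_loci)
    if skipped:
        logger.warning(
            "%d locus/loci below rarefaction depth g=%d in some population; "
            "skipped for PAR", skipped, g,
        )
    par_by_locus = {
        l: rarefied_private_richness(counts_cache[l][1], g) for l in par_loci
    }
    rows_out = []
    for pi, pop in enumerate(ds.populations):
        rows = ds.pop_rows(pop)
        a_v, ae_v, ho_v, he_v, uhe_v, rs_v = [], [], [], [], [], []
        for l in range(ds.n_loci):
            gcalls = ds.calls[rows][:, l, :]
            typed = gcalls[:, 0] != MISSING
            n = int(typed.sum())
            if n == 0:
                continue
            copies = gcalls[typed].ravel()
            alleles, counts = np.unique(copies, return_counts=True)
            p = counts / counts.sum()
            he = 1.0 - float(np.sum(p**2))
            a_v.append(alleles.size)
            ae_v.append(1.0 / float(np.sum(p**2)))
            ho_v.append(float(np.mean(gcalls[typed, 0] != gcalls[typed, 1])))
            he_v.append(he)
            uhe_v.append(2.0 * n / (2.0 * n - 1.0) * he if n > 1 else np.nan)
            if 2 * n >= g:
                rs_v.append(rarefied_allelic_richness(counts, g))
        par_vals = [par_by_locus[l][pi] for l in par_loci]
        row = {
            "population": pop,
            "n": int(rows.size),
            "A": float(np.mean(a_v)) if a_v else np.nan,
            "Ae": float(np.mean(ae_v)) if ae_v else np.nan,
            "Ho": float(np.mean(ho_v)) if ho_v else np.nan,
            "HE": float(np.mean(he_v)) if he_v else np.nan,
            "UHE": (float(np.nanmean(uhe_v))
                    if uhe_v and not np.all(np.isnan(uhe_v)) else np.nan),
            "Rs": float(np.mean(rs_v)) if rs_v else np.nan,
            "PAR": float(np.mean(par_vals)) if par_vals else np.nan,
            "FIS": single_population_fis(ds, pop),
        }
        if not rs_v:
            logger.warning("population %s: below depth g=%d at every locus", pop, g)
        if n_perm > 0:
            try:
                row["FIS_p"] = fis_permutation_test(
                    ds, pop, n_perm=n_perm, seed=seed
                ).p_excess_hom
            except ValueError:
                row["FIS_p"] = np.nan
        rows_out.append(row)
    return pd.DataFrame(rows_out).set_index("population")


# ---------------------------------------------------------------------------
# Regression of diversity on geography
# ---------------------------------------------------------------------------

def geo_regression(
    summary: pd.DataFrame,
    metadata: list[PopulationMetadata],
    responses: tuple[str, ...] = ("Rs", "UHE"),
    predictors: tuple[str, ...] = ("latitude", "longitude", "elevation"),
) -> pd.DataFrame:
    """OLS of diversity responses on geographic predictors, Holm-adjusted.

    The six tests (2 responses x 3 predictors by default) form one family
    for the sequential-Bonferroni (Holm) correction.
    """
    import statsmodels.api as sm

    meta = pd.DataFrame(
        {
            "population": [m.population for m in metadata],
            "latitude": [m.latitude for m in metadata],
            "longitude": [m.longitude for m in metadata],
            "elevation": [m.elevation for m in metadata],
        }
    ).set_index("population")
    df = summary.join(meta, how="inner")
    if len(df) < 10:
        raise ValueError(f"only {len(df)} populations with metadata; need >= 10")
    rows = []
    for resp in responses:
        for pred in predictors:
            sub = df[[resp, pred]].dropna()
            x, y = sub[pred].to_numpy(float), sub[resp].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("%s ~ %s: constant variable; undefined", resp, pred)
                rows.append({"response": resp, "predictor": pred,
                             "slope": np.nan, "r": np.nan, "p_raw": np.nan})
                continue
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({
                "response": resp, "predictor": pred,
                "slope": float(fit.params[1]), "r": r,
                "p_raw": float(fit.pvalues[1]),
            })
    out = pd.DataFrame(rows)
    mask = out["p_raw"].notna()
    adj = np.full(len(out), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = multipletests(
            out.loc[mask, "p_raw"], method="holm"
        )[1]
    out["p_adjusted"] = adj
    return out
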