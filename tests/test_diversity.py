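"""Diversity and differentiation estimators against independent oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from walnutpg.diversity import (
    fis_permutation_test,
    geo_regression,
    jost_d,
    locus_summary,
    null_allele_em,
    pairwise_fst,
    population_diversity,
    rarefied_allelic_richness,
    rarefied_private_richness,
    single_population_fis,
    wc_fstats,
)
from walnutpg.datamodel import PopulationMetadata
from walnutpg.synthetic import (
    equilibrium_population,
    generate_island_dataset,
    inject_null_alleles,
    IslandModelConfig,
)

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------------------
# Pooled locus summary
# ---------------------------------------------------------------------------

class TestLocusSummary:
    def test_biallelic_even_frequencies(self):
        # p = q = 0.5: Ae = 2, HE = 0.5, PIC = 1 - 0.5 - 2*(0.25*0.25) = 0.375
        ds = make_dataset({"P1": [((100, 102),), ((102, 100),)]})
        row = locus_summary(ds).iloc[0]
        assert row["Ae"] == pytest.approx(2.0)
        assert row["HE"] == pytest.approx(0.5)
        assert row["PIC"] == pytest.approx(0.375)

    def test_monomorphic_locus(self):
        ds = make_dataset({"P1": [((100, 100),), ((100, 100),)]})
        row = locus_summary(ds).iloc[0]
        assert (row["A"], row["Ae"], row["HE"], row["PIC"]) == (1, 1.0, 0.0, 0.0)

    def test_all_missing_locus_flagged(self, caplog):
        ds = make_dataset({"P1": [((0, 0), (100, 102)), ((0, 0), (100, 100))]})
        with caplog.at_level("WARNING"):
            out = locus_summary(ds)
        assert math.isnan(out.iloc[0]["A"]) and out.iloc[1]["A"] == 2


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def enumeration_richness(counts, g):
    """Exact expected allele count over all C(N, g) subsets (rational)."""
    copies = [i for i, c in enumerate(counts) for _ in range(c)]
    total = 0
    subsets = list(itertools.combinations(range(len(copies)), g))
    for sub in subsets:
        total += len({copies[i] for i in sub})
    return Fraction(total, len(subsets))


class TestRarefaction:
    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            k = int(rng.integers(1, 4))
            counts = rng.integers(1, 5, size=k)
            n = int(counts.sum())
            if n > 12:
                continue
            g = int(rng.integers(1, n + 1))
            exact = float(enumeration_richness(counts.tolist(), g))
            assert rarefied_allelic_richness(counts, g) == pytest.approx(
                exact, abs=1e-12
            )

    def test_fifteen_one_at_g2(self):
        # 1 + (1 - C(15,2)/C(16,2)) = 1 + (1 - 105/120) = 1.125
        assert rarefied_allelic_richness([15, 1], 2) == pytest.approx(1.125)

    def test_monomorphic_and_full_depth(self):
        assert rarefied_allelic_richness([16], 5) == pytest.approx(1.0)
        counts = [7, 5, 4]
        assert rarefied_allelic_richness(counts, 16) == pytest.approx(3.0)

    def test_g_exceeding_copies_rejected(self):
        with pytest.raises(ValueError):
            rarefied_allelic_richness([3, 2], 6)

    @given(st.lists(st.integers(1, 6), min_size=1, max_size=4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_depth(self, counts):
        n = sum(counts)
        values = [rarefied_allelic_richness(counts, g) for g in range(1, n + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        if n >= 2:
            assert 1.0 - 1e-12 <= values[1] <= 2.0 + 1e-12
        assert values[-1] == pytest.approx(len(counts))


def enumeration_private(mat, g):
    """Exact expected private allele count by enumerating subset pairs."""
    mat = np.asarray(mat)
    pops = []
    for row in mat:
        copies = [i for i, c in enumerate(row) for _ in range(c)]
        pops.append([
            {copies[i] for i in sub}
            for sub in itertools.combinations(range(len(copies)), g)
        ])
    out = []
    for j in range(len(pops)):
        total = Fraction(0)
        count = 0
        for combo in itertools.product(*pops):
            others = set().union(*(s for k, s in enumerate(combo) if k != j))
            total += len(combo[j] - others)
            count += 1
        out.append(total / count)
    return [float(x) for x in out]


class TestPrivateRichness:
    def test_matches_exhaustive_enumeration(self):
        mat = [[3, 1, 0], [1, 0, 2]]
        exact = enumeration_private(mat, 2)
        got = rarefied_private_richness(mat, 2)
        assert np.allclose(got, exact, atol=1e-12)

    def test_fully_private_allele_contributes_one(self):
        # allele only in pop 0 at full count; g = N_0 guarantees presence
        mat = [[4, 0], [0, 6]]
        par = rarefied_private_richness(mat, 4)
        assert par[0] == pytest.approx(1.0)

    def test_par_bounded_by_richness(self, rng):
        for _ in range(50):
            mat = rng.integers(0, 6, size=(3, 4))
            mat[:, 0] += 1  # no empty population
            g = int(min(mat.sum(axis=1)))
            if g < 1:
                continue
            par = rarefied_private_richness(mat, g)
            rs = [rarefied_allelic_richness(row, g) for row in mat]
            assert np.all(par <= np.array(rs) + 1e-12)


# ---------------------------------------------------------------------------
# Weir-Cockerham F-statistics
# ---------------------------------------------------------------------------

def wc84_oracle(genotypes_by_pop):
    """Independent coding of the WC84 per-allele variance components.

    ``genotypes_by_pop``: list (per pop) of lists of (a, b) genotypes.
    Returns summed (a, b, c).
    """
    alleles = sorted({x for pop in genotypes_by_pop for g in pop for x in g})
    r = len(genotypes_by_pop)
    n = [len(pop) for pop in genotypes_by_pop]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for allele in alleles:
        p = [sum((g[0] == allele) + (g[1] == allele) for g in pop) / (2 * ni)
             for pop, ni in zip(genotypes_by_pop, n)]
        h = [sum(1 for g in pop if g[0] != g[1] and allele in g) / ni
             for pop, ni in zip(genotypes_by_pop, n)]
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        A, B, C = A + a, B + b, C + hbar / 2
    return A, B, C


def _random_genotype_instance(rng, n_pops=2):
    pops = {}
    geno_by_pop = []
    for p in range(n_pops):
        n_ind = int(rng.integers(3, 8))
        inds = []
        for _ in range(n_ind):
            a, b = 100 + 2 * rng.integers(0, 4, size=2)
            inds.append(((int(a), int(b)),))
        pops[f"P{p + 1}"] = inds
        geno_by_pop.append([g[0] for g in inds])
    return make_dataset(pops), geno_by_pop


class TestWCFstats:
    def test_complete_differentiation(self):
        ds = make_dataset({
            "P1": [((100, 100),)] * 4,
            "P2": [((102, 102),)] * 4,
        })
        assert wc_fstats(ds).overall["theta"] == pytest.approx(1.0)

    def test_duplicated_population_near_zero(self, rng):
        base = [((100 + 2 * int(rng.integers(0, 3)),
                  100 + 2 * int(rng.integers(0, 3))),) for _ in range(30)]
        ds = make_dataset({"P1": base, "P2": list(base)})
        assert abs(wc_fstats(ds).overall["theta"]) < 0.05

    def test_equals_independent_wc84_coding(self, rng):
        checked = 0
        for _ in range(200):
            ds, geno = _random_genotype_instance(rng)
            a, b, c = wc84_oracle(geno)
            comps = wc_fstats(ds).components
            if abs(a) + abs(b) + abs(c) < 1e-15:
                continue  # monomorphic draw
            assert comps["a"].sum() == pytest.approx(a, abs=1e-12)
            assert comps["b"].sum() == pytest.approx(b, abs=1e-12)
            assert comps["c"].sum() == pytest.approx(c, abs=1e-12)
            checked += 1
        assert checked > 100

    def test_pairwise_consistency_and_symmetry(self, rng):
        ds = random_dataset(rng, n_pops=3, n_loci=2, max_ind=8)
        mat = pairwise_fst(ds)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 0.0)
        sub = ds.subset_populations([ds.populations[0], ds.populations[1]])
        expect = wc_fstats(sub).overall["theta"]
        got = mat.iloc[0, 1]
        if math.isfinite(expect):
            assert got == pytest.approx(expect, abs=1e-12)

    def test_island_model_panmixia_theta_near_zero(self):
        cfg = IslandModelConfig(
            n_populations=4, n_diploid=12, n_loci=8, theta=2.0,
            migration=40.0, seed=11,
        )
        ds = generate_island_dataset(cfg)
        assert abs(wc_fstats(ds).overall["theta"]) < 0.05


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def jost_oracle(p1, p2, n_per_pop):
    """Rational-arithmetic evaluation of the unbiased D estimator."""
    p1 = [Fraction(x) for x in p1]
    p2 = [Fraction(x) for x in p2]
    n = 2
    hs = 1 - Fraction(sum(x**2 for x in p1) + sum(x**2 for x in p2), 2)
    ht = 1 - sum(((a + b) / 2) ** 2 for a, b in zip(p1, p2))
    nh = Fraction(n_per_pop)
    hs_est = Fraction(2 * nh, 2 * nh - 1) * hs
    ht_est = ht + hs_est / (2 * nh * n)
    return float((ht_est - hs_est) / (1 - hs_est) * Fraction(n, n - 1))


class TestJostD:
    def test_fixed_different_alleles(self):
        ds = make_dataset({
            "P1": [((100, 100),)] * 5, "P2": [((102, 102),)] * 5,
        })
        vals, _ = jost_d(ds)
        assert vals.iloc[0] == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        rows = [((100, 102),), ((100, 100),), ((102, 102),), ((100, 102),)] * 12
        ds = make_dataset({"P1": rows, "P2": list(rows)})
        vals, combined = jost_d(ds)
        assert abs(vals.iloc[0]) < 0.05
        assert abs(combined["arithmetic"]) < 0.05

    def test_printed_frequency_instance_matches_oracle(self):
        # pop1 allele counts 70/30, pop2 30/70, 50 diploids each
        p1 = [((100, 100),)] * 20 + [((100, 102),)] * 30
        p2 = [((102, 102),)] * 20 + [((100, 102),)] * 30
        ds = make_dataset({"P1": p1, "P2": p2})
        vals, _ = jost_d(ds)
        expect = jost_oracle(
            [Fraction(7, 10), Fraction(3, 10)],
            [Fraction(3, 10), Fraction(7, 10)], 50,
        )
        assert vals.iloc[0] == pytest.approx(expect, abs=1e-12)


# ---------------------------------------------------------------------------
# Null alleles
# ---------------------------------------------------------------------------

class TestNullAlleleEM:
    def test_hwe_fixture_near_zero(self):
        ds = equilibrium_population(250, 1, 4.0, seed=3)
        res = null_allele_em(ds, "L01", "EQ")
        assert res.converged and abs(res.frequency) < 0.02

    def test_recovers_injected_frequency(self):
        ds = equilibrium_population(500, 1, 4.0, seed=5)
        ds = inject_null_alleles(ds, "L01", 0.2, seed=6)
        res = null_allele_em(ds, "L01", "EQ")
        assert res.frequency == pytest.approx(0.2, abs=0.03)

    def test_half_null_missing_fraction(self):
        ds = equilibrium_population(2000, 1, 4.0, seed=8)
        out = inject_null_alleles(ds, "L01", 0.5, seed=9)
        missing = np.mean(out.calls[:, 0, 0] == 0)
        assert missing == pytest.approx(0.25, abs=0.03)

    def test_all_missing_rejected(self):
        ds = make_dataset({"P1": [((0, 0),), ((0, 0),)]})
        with pytest.raises(ValueError, match="missing"):
            null_allele_em(ds, "L1", "P1")

    def test_zero_injection_is_identity(self):
        ds = equilibrium_population(50, 2, 2.0, seed=1)
        assert inject_null_alleles(ds, "L01", 0.0, seed=2).equals(ds)


# ---------------------------------------------------------------------------
# FIS permutation test
# ---------------------------------------------------------------------------

class TestFisPermutation:
    def test_selfed_population_extreme(self):
        rows = [((100 + 2 * (i % 4),) * 2, (140 + 2 * (i % 3),) * 2)
                for i in range(12)]
        ds = make_dataset({"P1": rows})
        res = fis_permutation_test(ds, "P1", n_perm=200, seed=0)
        assert res.fis == pytest.approx(1.0)
        assert res.p_excess_hom <= 1.0 / 201.0 + 1e-12

    def test_p_uniform_under_hwe(self):
        # calibration: under random-union-of-gametes the permutation p-value
        # is uniform on its grid
        from scipy import stats as sps

        ps = []
        for i in range(120):
            ds = equilibrium_population(30, 6, 3.0, seed=3000 + i)
            try:
                ps.append(fis_permutation_test(
                    ds, "EQ", n_perm=120, seed=i
                ).p_excess_hom)
            except ValueError:
                continue
        stat = sps.kstest(ps, "uniform").pvalue
        assert stat > 0.01

    def test_small_population_rejected(self):
        ds = make_dataset({"P1": [((100, 102),)] * 3})
        with pytest.raises(ValueError, match="< 5"):
            fis_permutation_test(ds, "P1")


# ---------------------------------------------------------------------------
# Population diversity table
# ---------------------------------------------------------------------------

class TestPopulationDiversity:
    def test_unbiased_he_formula(self):
        # N = 10 diploids, two alleles at 0.5: UHE = (20/19) * 0.5
        rows = [((100, 102),)] * 10
        ds = make_dataset({"P1": rows})
        out = population_diversity(ds, g=4)
        assert out.iloc[0]["UHE"] == pytest.approx(20.0 / 19.0 * 0.5)

    def test_rarefaction_at_full_depth_equals_A(self):
        rows = [((100, 102),), ((104, 100),), ((102, 104),)]
        ds = make_dataset({"P1": rows})
        out = population_diversity(ds, g=6)
        assert out.iloc[0]["Rs"] == pytest.approx(out.iloc[0]["A"])

    def test_duplicated_population_identical_rows(self, rng):
        ds = random_dataset(rng, n_pops=1, n_loci=3, max_ind=8)
        dup = make_dataset({
            "A": [tuple(map(tuple, row)) for row in ds.calls],
            "B": [tuple(map(tuple, row)) for row in ds.calls],
        })
        out = population_diversity(dup, g=2)
        a, b = out.loc["A"], out.loc["B"]
        for col in ("A", "Ae", "Ho", "HE", "UHE", "Rs"):
            assert a[col] == pytest.approx(b[col], nan_ok=True)

    def test_invariant_ranges(self, rng):
        ds = random_dataset(rng, n_pops=3, n_loci=3, max_ind=8)
        out = population_diversity(ds, g=2)
        for _, row in out.iterrows():
            for col in ("Ho", "HE", "UHE"):
                assert np.isnan(row[col]) or 0.0 <= row[col] <= 1.0
            if not np.isnan(row["Rs"]):
                assert 1.0 <= row["Rs"] <= row["A"] + 1e-12
            if not (np.isnan(row["PAR"]) or np.isnan(row["Rs"])):
                assert row["PAR"] <= row["Rs"] + 1e-12


# ---------------------------------------------------------------------------
# Geographic regression
# ---------------------------------------------------------------------------

def _meta(n, rng):
    return [
        PopulationMetadata(
            population=f"P{i}", latitude=float(30 + rng.random() * 10),
            longitude=float(rng.random() * 80), elevation=float(rng.random() * 1000),
        )
        for i in range(n)
    ]


class TestGeoRegression:
    def test_perfect_predictor_has_smallest_adjusted_p(self, rng):
        import pandas as pd

        meta = _meta(20, rng)
        lon = np.array([m.longitude for m in meta])
        summary = pd.DataFrame({
            "Rs": lon,  # response equals predictor
            "UHE": rng.random(20),
        }, index=[m.population for m in meta])
        out = geo_regression(summary, meta)
        row = out[(out.response == "Rs") & (out.predictor == "longitude")]
        assert row["p_adjusted"].iloc[0] == out["p_adjusted"].min()
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_familywise_error_controlled_under_null(self, rng):
        import pandas as pd

        meta = _meta(20, rng)
        idx = [m.population for m in meta]
        false_families = 0
        n_rep = 300
        for _ in range(n_rep):
            summary = pd.DataFrame({
                "Rs": rng.random(20), "UHE": rng.random(20),
            }, index=idx)
            out = geo_regression(summary, meta)
            false_families += bool((out["p_adjusted"] < 0.05).any())
        rate = false_families / n_rep
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= 0.05 + 3 * se

    def test_too_few_populations_rejected(self, rng):
        import pandas as pd

        meta = _meta(5, rng)
        summary = pd.DataFrame(
            {"Rs": rng.random(5), "UHE": rng.random(5)},
            index=[m.population for m in meta],
        )
        with pytest.raises(ValueError, match=">= 10"):
            geo_regression(summary, meta)
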