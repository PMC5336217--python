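"""Scenario encoding, prior draws, summary statistics, rejection and the
posterior machinery of the ABC engine."""

import numpy as np
import pandas as pd
import pytest

from walnutpg.abc import (
    LocusModel,
    PriorSpec,
    ReferenceTable,
    ScenarioValidationError,
    builtin_scenario,
    builtin_scenario_names,
    decline_percent,
    draw_parameters,
    generations_to_years,
    posterior_direct,
    posterior_logistic,
    reject_closest,
    simulate_dataset,
    summary_statistics,
    validate_scenario,
)
from walnutpg.abc.inference import RetainedSet, estimate_parameters
from walnutpg.abc.scenario import EventSpec, ScenarioSpec
from walnutpg.abc.calibration import recovery_spec, RECOVERY_LOCUS_MODEL, RECOVERY_PLAN

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Scenario encoding and priors
# ---------------------------------------------------------------------------

class TestScenarios:
    def test_all_shipped_scenarios_validate(self):
        names = builtin_scenario_names()
        assert names == ["1a", "2a", "3a", "4a", "5a",
                         "1b", "2b", "3b", "4b", "5b", "6b"]
        for name in names:
            timeline = validate_scenario(builtin_scenario(name),
                                         n_probe_draws=5)
            assert timeline  # canonical event list is non-empty

    def test_6b_constraint_chain_enforced_on_draws(self):
        spec = builtin_scenario("6b")
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = draw_parameters(spec, rng)
            assert p["t4"] > p["t3"] > p["t2"] > p["t1"] > p["td"]
            assert p["t3"] > p["tm"]

    def test_unmerged_pool_rejected(self):
        spec = ScenarioSpec(
            id="orphan",
            pools={"A": "NA_", "B": "NB"},
            sampled_pools=["A", "B"],
            events=[],  # B never merges
            priors={"NA_": PriorSpec("uniform", 100, 1000),
                    "NB": PriorSpec("uniform", 100, 1000)},
        )
        with pytest.raises(ScenarioValidationError, match="final ancestor|orphan"):
            validate_scenario(spec)

    def test_cyclic_constraints_rejected(self):
        spec = ScenarioSpec(
            id="cycle",
            pools={"A": "NA_", "B": "NB"},
            sampled_pools=["A", "B"],
            events=[EventSpec(kind="merge", time="t1", pool="B", sink="A")],
            priors={"NA_": PriorSpec("uniform", 100, 1000),
                    "NB": PriorSpec("uniform", 100, 1000),
                    "t1": PriorSpec("uniform", 10, 20),
                    "t2": PriorSpec("uniform", 10, 20)},
            constraints=[("t1", "t2"), ("t2", "t1")],
        )
        with pytest.raises(ScenarioValidationError, match="cyclic"):
            validate_scenario(spec)

    def test_prior_sampling_statistics(self):
        spec = builtin_scenario("6b")
        rng = np.random.default_rng(1)
        draws = np.array([draw_parameters(spec, rng)["t4"]
                          for _ in range(10_000)])
        assert draws.min() >= 100 and draws.max() <= 10_000
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        # rejection of t4 <= t3 truncates almost nothing (t3 <= 200)
        assert abs(draws.mean() - 5050.0) < 3 * se + 55.0

    def test_seeded_draw_sequence_reproducible(self):
        spec = builtin_scenario("3b")
        a = [draw_parameters(spec, np.random.default_rng(9)) for _ in range(3)]
        b = [draw_parameters(spec, np.random.default_rng(9)) for _ in range(3)]
        assert a == b


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _clonal_pool_dataset():
    row = ((100, 102), (140, 142), (160, 160))
    return make_dataset({"A": [row] * 8, "B": [row] * 8})


class TestSummaryStatistics:
    def test_vector_length_four_pools(self):
        spec = builtin_scenario("6b")
        lm = LocusModel(n_loci=4)
        rng = np.random.default_rng(2)
        params = draw_parameters(spec, rng, locus_model=lm)
        ds = simulate_dataset(
            spec, params,
            {"pool1": 5, "pool2": 5, "pool3": 5, "pool4": 5}, lm, rng,
        )
        vec, names = summary_statistics(ds)
        assert len(vec) == len(names) == 3 * 4 + 6 + 12 + 6

    def test_identical_clonal_pools(self):
        vec, names = summary_statistics(_clonal_pool_dataset())
        stats = dict(zip(names, vec))
        assert stats["FST_A_B"] == pytest.approx(0.0, abs=1e-9)
        assert stats["DAS_A_B"] == pytest.approx(0.5)

    def test_disjoint_fixed_pools(self):
        ds = make_dataset({
            "A": [((100, 100), (140, 140))] * 6,
            "B": [((102, 102), (146, 146))] * 6,
        })
        vec, names = summary_statistics(ds)
        stats = dict(zip(names, vec))
        assert stats["FST_A_B"] == pytest.approx(1.0)
        assert stats["DAS_A_B"] == pytest.approx(1.0)

    def test_exchangeability_under_individual_permutation(self, rng):
        spec = builtin_scenario("1b")
        lm = LocusModel(n_loci=5)
        g = np.random.default_rng(3)
        params = draw_parameters(spec, g, locus_model=lm)
        ds = simulate_dataset(
            spec, params,
            {"pool1": 6, "pool2": 6, "pool3": 6, "pool4": 6}, lm, g,
        )
        vec1, _ = summary_statistics(ds)
        # permute individuals within the dataset (pop labels travel along)
        perm = rng.permutation(ds.n_individuals)
        ds2 = ds.copy()
        ds2.individuals = [ds.individuals[i] for i in perm]
        ds2.pop_index = ds.pop_index[perm]
        ds2.calls = ds.calls[perm]
        vec2, _ = summary_statistics(ds2)
        assert np.array_equal(vec1, vec2)

    def test_tiny_pool_rejected(self):
        ds = make_dataset({"A": [((100, 102),)] * 3, "B": [((100, 100),)]})
        with pytest.raises(ValueError, match="< 2"):
            summary_statistics(ds)


# ---------------------------------------------------------------------------
# Rejection and posteriors
# ---------------------------------------------------------------------------

def _fake_table(rng, n=1000, s=5, n_scen=2):
    stats = pd.DataFrame(
        rng.normal(size=(n, s)), columns=[f"s{i}" for i in range(s)]
    )
    med = stats.median(axis=0)
    mad = (stats - med).abs().median(axis=0).to_numpy()
    ids = np.array([f"S{i % n_scen}" for i in range(n)])
    return ReferenceTable(
        scenario_ids=ids,
        params=pd.DataFrame({"theta": rng.random(n)}),
        stats=stats, mad=mad,
    )


class TestRejection:
    def test_fraction_one_retains_all(self, rng):
        t = _fake_table(rng, n=100)
        ret = reject_closest(t, np.zeros(5), 1.0)
        assert ret.indices.size == 100

    def test_observed_equal_to_row_is_first(self, rng):
        t = _fake_table(rng, n=200)
        obs = t.stats.iloc[123].to_numpy()
        ret = reject_closest(t, obs, 0.05)
        assert ret.indices[0] == 123
        assert ret.distances[0] == pytest.approx(0.0)

    def test_matches_full_sort_oracle(self, rng):
        t = _fake_table(rng, n=1000)
        obs = rng.normal(size=5)
        ret = reject_closest(t, obs, 0.01)
        z = t.normalised()
        d = np.sqrt(((z - t.normalise_observed(obs)) ** 2).sum(axis=1))
        expect = np.argsort(d, kind="stable")[:10]
        assert np.array_equal(ret.indices, expect)

    def test_bad_fraction_rejected(self, rng):
        t = _fake_table(rng, n=10)
        with pytest.raises(ValueError):
            reject_closest(t, np.zeros(5), 0.0)


class TestPosteriors:
    def test_direct_share_arithmetic(self, rng):
        t = _fake_table(rng, n=1000, n_scen=2)
        # construct a retained set with 181 of S0 and 319 of S1
        i0 = np.flatnonzero(t.scenario_ids == "S0")[:181]
        i1 = np.flatnonzero(t.scenario_ids == "S1")[:319]
        ret = RetainedSet(indices=np.concatenate([i0, i1]),
                          distances=np.zeros(500))
        post = posterior_direct(t, ret, 500)
        assert post.probabilities.loc["S0", "p"] == pytest.approx(0.362)
        assert post.probabilities.loc["S1", "p"] == pytest.approx(0.638)
        assert post.probabilities["p"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_direct_single_scenario_certainty(self, rng):
        t = _fake_table(rng, n=100, n_scen=2)
        idx = np.flatnonzero(t.scenario_ids == "S1")[:30]
        ret = RetainedSet(indices=idx, distances=np.zeros(30))
        post = posterior_direct(t, ret, 30)
        assert post.probabilities.loc["S1", "p"] == 1.0
        assert post.probabilities.loc["S0", "p"] == 0.0

    def test_logistic_uninformative_labels_near_uniform(self, rng):
        # labels independent of the statistics: probabilities ~ class shares
        t = _fake_table(rng, n=1200, n_scen=3)
        post = posterior_logistic(t, np.zeros(5), fraction=0.5)
        assert post.probabilities["p"].sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.abs(post.probabilities["p"] - 1 / 3) < 0.12)

    def test_logistic_separable_labels_confident(self, rng):
        t = _fake_table(rng, n=600, n_scen=2)
        # shift S0 rows toward the origin, S1 away: fully informative
        z = t.stats.to_numpy()
        z[t.scenario_ids == "S1"] += 8.0
        t.stats = pd.DataFrame(z, columns=t.stats.columns)
        post = posterior_logistic(t, np.zeros(5), fraction=1.0)
        assert post.probabilities.loc["S0", "p"] > 0.9


@pytest.fixture(scope="module")
def small_table():
    from walnutpg.abc import build_reference_table

    return build_reference_table(
        [recovery_spec()], 300, RECOVERY_PLAN, RECOVERY_LOCUS_MODEL, seed=2,
    )


class TestEstimateParameters:

    def test_quantile_ordering_and_prior_bounds(self, small_table):
        obs = small_table.stats.iloc[17].to_numpy()
        post = estimate_parameters(small_table, obs, "split",
                                   fraction=0.8, min_retained=100)
        for name, row in post.summary.iterrows():
            assert row["q05"] <= row["median"] <= row["q95"]
        assert (post.sample["N"].between(100, 10_000)).all()
        assert (post.sample["t"].between(10, 500)).all()

    def test_insufficient_retained_rejected(self, small_table):
        obs = small_table.stats.iloc[0].to_numpy()
        with pytest.raises(ValueError, match="retained"):
            estimate_parameters(small_table, obs, "split",
                                fraction=0.01, min_retained=200)


# ---------------------------------------------------------------------------
# Error rates on identical scenarios
# ---------------------------------------------------------------------------

def test_identical_scenarios_are_indistinguishable():
    """Two byte-identical competing scenarios: the focal one should win about
    half the pods (type II ~ 1/2)."""
    from walnutpg.abc import build_reference_table, type2_error

    base = recovery_spec()
    twin = ScenarioSpec(
        id="twin", pools=base.pools, sampled_pools=base.sampled_pools,
        events=base.events, priors=base.priors, constraints=base.constraints,
    )
    lm = RECOVERY_LOCUS_MODEL
    plan = {"A": 10, "B": 10}
    table = build_reference_table([base, twin], 120, plan, lm, seed=3)
    rate = type2_error(table, "split", n_pods=30, fraction=0.2, seed=4)["twin"]
    assert 0.2 <= rate <= 0.8


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

class TestConversions:
    @pytest.mark.parametrize("gens,expect", [
        (579, (46_320, 63_690)),
        (19.7, (1_576, 2_167)),
        (0, (0, 0)),
    ])
    def test_generation_scaling(self, gens, expect):
        assert generations_to_years(gens, 80, 110) == expect

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            generations_to_years(-1, 80, 110)

    def test_decline_percent(self):
        assert decline_percent(8040, 6320) == pytest.approx(21.4, abs=0.05)
        assert decline_percent(100, 100) == 0.0
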