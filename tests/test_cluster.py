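"""Evanno delta-K, run alignment, membership classification, IDW rasters."""

import numpy as np
import pytest

from walnutpg.cluster import (
    QMatrix,
    Raster,
    align_runs,
    classify_membership,
    composite_map,
    evanno,
    idw_surface,
    read_ascii_grid,
    write_ascii_grid,
)


def _runs_from_means(means, sd=1.0, jitter=None):
    """Two runs per K with the requested means and sample sd."""
    runs = []
    for k, m in means.items():
        runs.append((k, m + sd / np.sqrt(2)))
        runs.append((k, m - sd / np.sqrt(2)))
    return runs


class TestEvanno:
    def test_hand_computed_second_differences(self):
        means = {1: -100.0, 2: -50.0, 3: -45.0, 4: -44.0}
        table, best = evanno(_runs_from_means(means))
        assert table.loc[2, "delta_K"] == pytest.approx(45.0)
        # |L(4) - 2 L(3) + L(2)| = |-44 + 90 - 50| = 4
        assert table.loc[3, "delta_K"] == pytest.approx(4.0)
        assert best == 2
        assert np.isnan(table.loc[1, "delta_K"])
        assert np.isnan(table.loc[4, "delta_K"])

    def test_linear_likelihood_zero_delta(self):
        means = {k: -100.0 + 10.0 * k for k in range(1, 5)}
        table, _ = evanno(_runs_from_means(means))
        assert table.loc[2, "delta_K"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_sd_flagged(self, caplog):
        runs = [(1, -10.0), (1, -10.0), (2, -5.0), (2, -5.0),
                (3, -4.0), (3, -4.5), (4, -3.5), (4, -4.0)]
        with caplog.at_level("WARNING"):
            table, best = evanno(runs)
        assert np.isnan(table.loc[2, "delta_K"])
        assert best == 3

    def test_noncontiguous_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            evanno([(1, -1.0), (1, -1.1), (3, -2.0), (3, -2.1),
                    (4, -3.0), (4, -3.1)])


class TestAlignRuns:
    def test_permuted_identical_runs_recovered(self, rng):
        q = rng.dirichlet(np.ones(4), size=10)
        ref = QMatrix(entities=[f"i{n}" for n in range(10)], q=q)
        perm = [2, 0, 3, 1]
        other = QMatrix(entities=ref.entities, q=q[:, perm])
        avg = align_runs([ref, other])
        assert np.allclose(avg.q, q, atol=1e-12)

    def test_noisy_runs_average_close_to_truth(self, rng):
        truth = rng.dirichlet(np.full(3, 5.0), size=30)
        runs = []
        for r in range(4):
            noise = rng.uniform(-0.01, 0.01, size=truth.shape)
            noise -= noise.mean(axis=1, keepdims=True)  # stay on the simplex
            q = np.clip(truth + noise, 0.0, 1.0)
            q = q / q.sum(axis=1, keepdims=True)
            # reference run keeps truth's column order; others are permuted
            perm = np.arange(3) if r == 0 else rng.permutation(3)
            runs.append(QMatrix(
                entities=[f"i{n}" for n in range(30)], q=q[:, perm]
            ))
        avg = align_runs(runs)
        assert np.max(np.abs(avg.q - truth)) < 0.01

    def test_six_runs_k4_supported(self, rng):
        q = rng.dirichlet(np.ones(4), size=8)
        ents = [f"i{n}" for n in range(8)]
        runs = [QMatrix(entities=ents, q=q[:, rng.permutation(4)])
                for _ in range(6)]
        avg = align_runs(runs)
        assert avg.q.shape == (8, 4)
        assert np.allclose(avg.q.sum(axis=1), 1.0)

    def test_k_above_eight_rejected(self, rng):
        q = rng.dirichlet(np.ones(9), size=4)
        runs = [QMatrix(entities=list("abcd"), q=q)] * 2
        with pytest.raises(ValueError, match="K=9"):
            align_runs(runs)


class TestClassifyMembership:
    def test_threshold_rule(self):
        q = QMatrix(entities=["e1", "e2"],
                    q=np.array([[0.80, 0.10, 0.05, 0.05],
                                [0.5, 0.5, 0.0, 0.0]]))
        labels = classify_membership(q, 0.75)
        assert labels["e1"] == 0
        assert labels["e2"] == "admixed"

    def test_threshold_one_requires_certainty(self):
        q = QMatrix(entities=["e1", "e2"],
                    q=np.array([[1.0, 0.0], [0.999, 0.001]]))
        labels = classify_membership(q, 1.0)
        assert labels["e1"] == 0 and labels["e2"] == "admixed"

    def test_invalid_threshold(self):
        q = QMatrix(entities=["e"], q=np.array([[1.0]]))
        with pytest.raises(ValueError):
            classify_membership(q, 0.4)


class TestIDW:
    def test_single_point_constant_surface(self):
        r = idw_surface([(5.0, 5.0, 3.5)], 0, 0, 1.0, 4, 4)
        assert np.allclose(r.values, 3.5)

    def test_midpoint_is_mean_for_any_power(self):
        for p in (1.0, 2.0, 3.7):
            r = idw_surface([(0.0, 0.5, 1.0), (1.0, 0.5, 3.0)],
                            0, 0, 1.0, 1, 1, power=p)
            assert r.values[0, 0] == pytest.approx(2.0)

    def test_three_point_brute_force(self):
        pts = [(0.2, 0.3, 1.0), (3.0, 2.0, 5.0), (1.5, 4.0, -2.0)]
        r = idw_surface(pts, 0, 0, 0.7, 5, 6, power=2.0)
        gx, gy = r.cell_centers()
        probe = [(i, j) for i in range(0, 5, 2) for j in range(0, 6, 2)][:10]
        for i, j in probe:
            x, y = gx[i, j], gy[i, j]
            num = den = 0.0
            for px, py, pz in pts:
                d2 = (x - px) ** 2 + (y - py) ** 2
                num += pz / d2
                den += 1.0 / d2
            assert r.values[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_exact_at_data_point_and_within_range(self, rng):
        pts = [(0.5, 0.5, 1.0), (2.5, 1.5, 7.0), (1.5, 2.5, 4.0)]
        r = idw_surface(pts, 0, 0, 1.0, 3, 3)
        # cell (row for y=0.5 is bottom row) containing (0.5, 0.5)
        assert r.values[2, 0] == pytest.approx(1.0)
        assert r.values.min() >= 1.0 - 1e-12
        assert r.values.max() <= 7.0 + 1e-12

    def test_coincident_conflicting_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            idw_surface([(1, 1, 2.0), (1, 1, 3.0)], 0, 0, 1.0, 2, 2)


class TestComposite:
    def test_single_full_surface_uniform_color(self):
        s = Raster(0, 0, 1.0, np.ones((3, 3)))
        rgb = composite_map([s], colors=[(0.2, 0.4, 0.6)])
        assert np.allclose(rgb.values[0], 0.2)
        assert np.allclose(rgb.values[2], 0.6)

    def test_even_mixture_is_midpoint_color(self):
        a = Raster(0, 0, 1.0, np.full((2, 2), 0.5))
        b = Raster(0, 0, 1.0, np.full((2, 2), 0.5))
        rgb = composite_map([a, b], colors=[(1, 0, 0), (0, 0, 1)])
        assert np.allclose(rgb.values[0], 0.5)
        assert np.allclose(rgb.values[2], 0.5)

    def test_channels_clipped_to_unit_interval(self, rng):
        surfaces = [Raster(0, 0, 1.0, rng.random((4, 4)) / 2) for _ in range(2)]
        rgb = composite_map(surfaces)
        assert rgb.values.min() >= 0.0 and rgb.values.max() <= 1.0

    def test_grid_mismatch_rejected(self):
        a = Raster(0, 0, 1.0, np.ones((2, 2)))
        b = Raster(0, 0, 2.0, np.ones((2, 2)))
        with pytest.raises(ValueError, match="grid"):
            composite_map([a, b])


def test_ascii_grid_round_trip(tmp_path, rng):
    r = Raster(10.5, -3.25, 0.5, rng.random((4, 6)).round(4))
    path = tmp_path / "g.asc"
    write_ascii_grid(r, path)
    back = read_ascii_grid(path)
    assert back.same_grid(r)
    assert np.allclose(back.values, r.values, atol=1e-6)
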