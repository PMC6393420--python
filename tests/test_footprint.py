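"""Thrombogenic footprint construction, bootstrap equalization, comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from dtekit import (
    SAEnsemble,
    bootstrap_equalize,
    build_footprint,
    compare_footprints,
    find_modes,
    silverman_bandwidth,
    tail_mass,
)
from dtekit.errors import ValidationError
from dtekit.footprint import _kde_on_grid


@pytest.fixture(scope="module")
def normal_sample():
    rng = np.random.default_rng(42)
    return np.abs(rng.normal(20.0, 3.0, 10_000))


class TestKDECore:
    def test_matches_scipy_gaussian_kde(self, normal_sample):
        """Independent oracle: scipy's KDE with the bandwidth pinned to ours."""
        x = normal_sample[:500]
        h = silverman_bandwidth(x)
        grid = np.linspace(5, 35, 200)
        ours = _kde_on_grid(x, grid, h)
        kde = stats.gaussian_kde(x, bw_method=h / x.std(ddof=1))
        np.testing.assert_allclose(ours, kde(grid), rtol=1e-10, atol=1e-12)

    def test_weighted_matches_scipy(self, normal_sample):
        x = normal_sample[:200]
        rng = np.random.default_rng(0)
        w = rng.random(200)
        w /= w.sum()
        h = 1.3
        grid = np.linspace(10, 30, 100)
        kde = stats.gaussian_kde(x, bw_method=None, weights=w)
        kde.set_bandwidth(h / math.sqrt(kde.covariance[0, 0]) * kde.factor)
        np.testing.assert_allclose(
            _kde_on_grid(x, grid, h, weights=w), kde(grid), rtol=1e-9
        )


class TestBuildFootprint:
    def test_normal_density_recovered(self, normal_sample):
        """KDE of N(20, 3) samples tracks the closed-form density."""
        fp = build_footprint(normal_sample, grid_spec=(0.0, 40.0, 512))
        target = stats.norm.pdf(fp.grid, 20.0, 3.0)
        sup = np.max(np.abs(fp.density - target))
        assert sup < 0.05 * target.max()

    def test_integral_is_one(self, normal_sample, advected, annulus_cfg):
        from dtekit import sa_ensemble

        for values in (normal_sample, sa_ensemble(advected).values,
                       np.array([3.0, 3.1, 50.0])):
            fp = build_footprint(values)
            assert fp.integral() == pytest.approx(1.0, abs=1e-3)

    def test_single_atom_explicit_bandwidth(self):
        """All-equal SA with explicit h: the kernel itself, renormalized."""
        fp = build_footprint(
            np.full(50, 10.0), grid_spec=(0.0, 20.0, 801), bandwidth_rule=1.0
        )
        kernel = stats.norm.pdf(fp.grid, 10.0, 1.0)
        kernel /= np.trapezoid(kernel, fp.grid)
        np.testing.assert_allclose(fp.density, kernel, rtol=1e-6)

    def test_degenerate_without_bandwidth_errors(self):
        with pytest.raises(ValidationError, match="bandwidth"):
            build_footprint(np.full(10, 5.0))

    def test_zero_boundary_clipped_and_renormalized(self):
        # mass near 0 leaks below the boundary; the footprint renormalizes
        fp = build_footprint(np.array([0.1, 0.2, 0.3, 5.0]),
                             grid_spec=(0.0, 10.0, 400), bandwidth_rule=0.5)
        assert fp.grid[0] == 0.0
        assert fp.integral() == pytest.approx(1.0, abs=1e-3)

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            build_footprint(np.array([]))


class TestBootstrap:
    def test_support_containment(self, rng):
        values = SAEnsemble(rng.uniform(0, 10, 100), label="a")
        other = SAEnsemble(rng.uniform(0, 10, 60), label="b")
        a, b = bootstrap_equalize(values, other, n_target=100, reps=1, seed=0)
        assert a.shape == (1, 100) and b.shape == (1, 100)
        assert set(a.ravel()) <= set(values.values)
        assert set(b.ravel()) <= set(other.values)

    def test_deterministic_given_seed(self, rng):
        va = SAEnsemble(rng.uniform(0, 10, 50))
        vb = SAEnsemble(rng.uniform(0, 10, 80))
        r1 = bootstrap_equalize(va, vb, reps=5, seed=99)
        r2 = bootstrap_equalize(va, vb, reps=5, seed=99)
        np.testing.assert_array_equal(r1[0], r2[0])
        np.testing.assert_array_equal(r1[1], r2[1])

    def test_default_target_is_larger_population(self, rng):
        va = SAEnsemble(rng.uniform(0, 10, 50))
        vb = SAEnsemble(rng.uniform(0, 10, 80))
        a, b = bootstrap_equalize(va, vb, reps=2, seed=0)
        assert a.shape == (2, 80) and b.shape == (2, 80)

    def test_replicate_mean_identity(self, normal_sample):
        """build_footprint's pooled-count weighting equals the explicit
        pointwise mean of per-replicate kernel densities (shared h)."""
        values = normal_sample[:300]
        n_target, reps, seed = 120, 40, 5
        fp = build_footprint(values, grid_spec=(5.0, 35.0, 200),
                             bootstrap=(n_target, reps), seed=seed)
        h = silverman_bandwidth(values)
        idx = np.random.default_rng(seed).integers(
            0, len(values), size=(reps, n_target)
        )
        mean_density = np.mean(
            [_kde_on_grid(values[row], fp.grid, h) for row in idx], axis=0
        )
        mean_density /= np.trapezoid(mean_density, fp.grid)
        np.testing.assert_allclose(fp.density, mean_density, rtol=1e-9)

    def test_reps_converge_to_subsample_density(self, normal_sample):
        """The bootstrap replicate-mean converges (in reps) to the plain KDE
        of the resampled base — bootstrapping equalizes sizes, it does not
        create information beyond the base sample."""
        base = normal_sample[:500]
        h = silverman_bandwidth(base)
        plain = build_footprint(base, grid_spec=(5.0, 35.0, 256))
        fp = build_footprint(base, grid_spec=(5.0, 35.0, 256),
                             bootstrap=(10_000, 400), seed=3)
        assert fp.bandwidth == h
        sup = np.max(np.abs(fp.density - plain.density))
        assert sup < 0.02 * plain.density.max()

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            bootstrap_equalize(np.array([]), np.array([1.0]))


class TestTailMass:
    def test_brute_force_oracle(self, rng):
        values = rng.uniform(0, 100, 333)
        for thr in (-1.0, 0.0, 17.3, 99.9, 100.1):
            assert tail_mass(values, thr) == np.sum(values > thr) / len(values)

    @pytest.mark.parametrize(
        "thr,expect", [(5.0, 1.0), (250.0, 0.0), (50.0, 0.5)]
    )
    def test_examples(self, thr, expect):
        assert tail_mass(np.array([10.0, 40.0, 60.0, 200.0]), thr) == expect


class TestFindModes:
    def test_unimodal(self, normal_sample):
        fp = build_footprint(normal_sample, grid_spec=(0.0, 40.0, 512))
        modes = find_modes(fp)
        assert len(modes) == 1
        assert modes[0][0] == pytest.approx(20.0, abs=1.0)

    def test_bimodal_mixture(self):
        rng = np.random.default_rng(0)
        n = 10_000
        heavy = rng.random(n) < 0.8
        x = np.abs(np.where(heavy, rng.normal(10, 2, n), rng.normal(150, 5, n)))
        fp = build_footprint(x, grid_spec=(0.0, 170.0, 1024))
        modes = find_modes(fp)
        assert len(modes) == 2
        assert modes[0][0] == pytest.approx(10.0, abs=1.5)  # main mode
        assert modes[1][0] == pytest.approx(150.0, abs=3.0)

    def test_prominence_one_keeps_at_most_global_max(self, normal_sample):
        fp = build_footprint(normal_sample)
        assert len(find_modes(fp, min_prominence=1.0)) <= 1


class TestCompareFootprints:
    def test_self_comparison(self, rng):
        values = SAEnsemble(rng.normal(50, 5, 400).clip(min=0), label="x")
        cmp_ = compare_footprints(values, values, threshold=50.0, seed=0)
        assert cmp_.ks_statistic == 0.0
        assert cmp_.main_mode_shift == pytest.approx(0.0, abs=1.0)
        assert cmp_.tail_mass_ratio == pytest.approx(1.0)

    def test_constructed_shift(self, rng):
        a = rng.normal(30, 3, 2000).clip(min=0)
        b = a + 10.0
        cmp_ = compare_footprints(a, b, threshold=35.0, seed=1)
        assert cmp_.main_mode_shift == pytest.approx(10.0, abs=1.5)
        assert cmp_.ks_statistic > 0.5

    def test_disjoint_supports_ks_one(self):
        a = np.linspace(1, 10, 50)
        b = np.linspace(100, 110, 50)
        cmp_ = compare_footprints(a, b, threshold=50.0, seed=0)
        assert cmp_.ks_statistic == 1.0
        assert not cmp_.tail_ratio_defined
        assert math.isinf(cmp_.tail_mass_ratio)

    def test_json_output(self, tmp_path, rng):
        values = rng.uniform(1, 60, 100)
        cmp_ = compare_footprints(values, values, seed=0)
        cmp_.to_json(tmp_path / "cmp.json")
        import json

        loaded = json.loads((tmp_path / "cmp.json").read_text())
        assert loaded["ks_statistic"] == 0.0
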