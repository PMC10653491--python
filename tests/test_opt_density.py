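"""OPT density estimator: Kaplan-Meier initialisation, expected counts under
censoring, the stop/split likelihood recursion, and the censored fixed point."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import betaln

from ctiva.opt_density import (
    PartitionNode,
    Region,
    decide_partition,
    default_domain,
    density_from_json,
    density_to_json,
    expected_counts,
    extract_density,
    fit_joint,
    initial_joint,
    km_fit,
    opt_build,
)

UNIT = Region(0.0, 1.0, 0.0, 1.0)


def point_counts_fn(points):
    pts = list(points)
    return lambda r: float(sum(1 for x, y in pts if r.contains(x, y)))


def phi_direct(pts, lo1, hi1, lo2, hi2, l1, l2, depth):
    """Direct-space (no logarithms) evaluation of the OPT recursion; the
    independent oracle for the log-space implementation."""
    n = sum(1 for x, y in pts if lo1 <= x < hi1 and lo2 <= y < hi2)
    area = (hi1 - lo1) * (hi2 - lo2)
    p0 = area ** (-n)
    if n < 2 or (l1 >= depth and l2 >= depth):
        return p0
    total = 0.0
    if l1 < depth:
        mid = (lo1 + hi1) / 2
        na = sum(1 for x, y in pts if lo1 <= x < mid and lo2 <= y < hi2)
        total += (math.exp(betaln(na + 0.5, n - na + 0.5) - betaln(0.5, 0.5))
                  * phi_direct(pts, lo1, mid, lo2, hi2, l1 + 1, l2, depth)
                  * phi_direct(pts, mid, hi1, lo2, hi2, l1 + 1, l2, depth))
    if l2 < depth:
        mid = (lo2 + hi2) / 2
        na = sum(1 for x, y in pts if lo2 <= y < mid and lo1 <= x < hi1)
        total += (math.exp(betaln(na + 0.5, n - na + 0.5) - betaln(0.5, 0.5))
                  * phi_direct(pts, lo1, hi1, lo2, mid, l1, l2 + 1, depth)
                  * phi_direct(pts, lo1, hi1, mid, hi2, l1, l2 + 1, depth))
    return 0.5 * p0 + 0.25 * total


class TestKaplanMeier:
    def test_all_events(self):
        km = km_fit([1, 2, 3], [1, 1, 1])
        assert np.allclose([km(1), km(2), km(3)], [2 / 3, 1 / 3, 0.0])

    def test_no_events(self):
        km = km_fit([1, 2], [0, 0])
        assert km(0.5) == 1.0 and km(2.0) == 1.0

    def test_one_censor(self):
        km = km_fit([1, 2, 3], [1, 0, 1])
        assert np.isclose(km(1), 2 / 3)
        assert np.isclose(km(3), 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_fit([], [])

    def test_residual_mass_in_last_cell(self):
        km = km_fit([1, 2], [1, 0])  # S stays at 1/2 beyond t=2
        masses = km.cell_masses(np.array([0.0, 1.5, 3.0]))
        assert np.isclose(masses.sum(), 1.0)
        assert np.isclose(masses[1], 0.5)


class TestInitialJoint:
    def test_normalised_product_measure(self, uncensored_obs):
        omega = default_domain(uncensored_obs)
        f = initial_joint(uncensored_obs, omega, depth=5)
        assert np.isclose(f.integral(), 1.0, atol=1e-9)
        # independence: mass(A x B) = mass(A x Omega2) * mass(Omega1 x B)
        a = Region(omega.lo1, (omega.lo1 + omega.hi1) / 2, omega.lo2, omega.hi2)
        b = Region(omega.lo1, omega.hi1, omega.lo2, (omega.lo2 + omega.hi2) / 2)
        ab = Region(a.lo1, a.hi1, b.lo2, b.hi2)
        assert np.isclose(f.mass(ab), f.mass(a) * f.mass(b), atol=1e-6)

    def test_rejects_domain_not_covering_data(self, uncensored_obs):
        with pytest.raises(ValueError):
            initial_joint(uncensored_obs, Region(0, 0.1, 0, 0.1), depth=3)


class TestExpectedCounts:
    def test_uncensored_equals_plain_count(self, uncensored_obs):
        omega = default_domain(uncensored_obs)
        f = initial_joint(uncensored_obs, omega, depth=5)
        region = Region(omega.lo1, omega.hi1 / 2, omega.lo2, omega.hi2)
        plain = np.sum(uncensored_obs["v1"] < omega.hi1 / 2)
        assert np.isclose(expected_counts(f, uncensored_obs, region), plain)

    def test_both_censored_normalises_to_one(self, uniform_unit_density):
        obs = pd.DataFrame({"v1": [0.5], "delta1": [0], "v2": [0.5], "delta2": [0]})
        got = expected_counts(uniform_unit_density, obs, Region(0.5, 1.0, 0.5, 1.0))
        assert np.isclose(got, 1.0)

    def test_uniform_quadrant_fraction(self, uniform_unit_density):
        # (0.25 * 0.25) / (0.5 * 0.5) = 0.25
        obs = pd.DataFrame({"v1": [0.5], "delta1": [0], "v2": [0.5], "delta2": [0]})
        got = expected_counts(uniform_unit_density, obs, Region(0.75, 1.0, 0.75, 1.0))
        assert np.isclose(got, 0.25)

    def test_additive_over_partition(self, default_replicate, default_fit):
        obs = default_replicate.observations
        f = default_fit.density
        omega = f.domain
        m1 = (omega.lo1 + omega.hi1) / 2
        m2 = (omega.lo2 + omega.hi2) / 2
        quadrants = [Region(lo1, hi1, lo2, hi2)
                     for lo1, hi1 in ((omega.lo1, m1), (m1, omega.hi1))
                     for lo2, hi2 in ((omega.lo2, m2), (m2, omega.hi2))]
        total = sum(expected_counts(f, obs, q) for q in quadrants)
        assert np.isclose(total, len(obs), atol=1e-6)


class TestOptBuild:
    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_log_space_matches_direct_space(self, depth):
        pts = [(0.1, 0.2), (0.3, 0.7), (0.8, 0.4), (0.62, 0.9), (0.55, 0.15)]
        tree = opt_build(point_counts_fn(pts), UNIT, max_depth=depth)
        direct = math.log(phi_direct(pts, 0, 1, 0, 1, 0, 0, depth))
        assert abs(tree.phi - direct) <= 1e-9 * abs(direct)

    def test_sparse_node_is_terminal_with_phi0(self):
        tree = opt_build(point_counts_fn([(0.2, 0.2)]), UNIT, max_depth=4)
        assert tree.phi == tree.phi0
        assert tree.is_uniform and tree.children is None

    def test_two_point_depth_one_hand_value(self):
        # depth 1: all four children hold < 2 points, so Phi(child) = Phi0
        pts = [(0.2, 0.3), (0.7, 0.6)]
        tree = opt_build(point_counts_fn(pts), UNIT, max_depth=1)
        direct = math.log(phi_direct(pts, 0, 1, 0, 1, 0, 0, 1))
        assert np.isclose(tree.phi, direct, rtol=1e-12)

    def test_beta_half_is_pi(self):
        assert np.isclose(math.exp(betaln(0.5, 0.5)), math.pi)

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            opt_build(point_counts_fn([]), UNIT, max_depth=0)


class TestDecidePartition:
    def test_sparse_is_uniform(self):
        assert decide_partition(1.0, 0.0, {1: 10.0}) == "uniform"

    def test_symmetric_layout_is_uniform(self):
        pts = [(0.25, 0.25), (0.75, 0.25), (0.25, 0.75), (0.75, 0.75)]
        tree = opt_build(point_counts_fn(pts), UNIT, max_depth=1)
        assert tree.is_uniform

    def test_mass_concentrated_on_axis1_half_splits_axis1(self):
        pts = [(0.1, y) for y in np.linspace(0.05, 0.95, 12)]
        tree = opt_build(point_counts_fn(pts), UNIT, max_depth=3)
        assert tree.split_axis == 1


class TestExtractDensity:
    def test_single_leaf_uniform(self):
        leaf = PartitionNode(UNIT, 10.0, 0.0, 0.0, None, is_uniform=True)
        f = extract_density(leaf, n_total=10.0)
        assert np.isclose(f.mass(UNIT), 1.0)
        assert np.isclose(f.leaves[0][1], 1.0)

    def test_two_leaf_arithmetic(self):
        # masses (0.75n, 0.25n) on areas (0.5, 0.5) -> densities (1.5, 0.5)
        left = PartitionNode(Region(0, 0.5, 0, 1), 75.0, 0.0, 0.0, None, is_uniform=True)
        right = PartitionNode(Region(0.5, 1, 0, 1), 25.0, 0.0, 0.0, None, is_uniform=True)
        root = PartitionNode(UNIT, 100.0, 0.0, 0.0, 1, children=(left, right))
        f = extract_density(root, n_total=100.0)
        dens = dict((r.lo1, d) for r, d in f.leaves)
        assert np.isclose(dens[0.0], 1.5) and np.isclose(dens[0.5], 0.5)
        assert np.isclose(f.integral(), 1.0)

    def test_zero_mass_rejected(self):
        leaf = PartitionNode(UNIT, 0.0, 0.0, 0.0, None, is_uniform=True)
        with pytest.raises(ValueError):
            extract_density(leaf, n_total=10.0)


class TestFitJoint:
    def test_uncensored_matches_point_counts(self, uncensored_obs):
        fit = fit_joint(uncensored_obs, max_depth=4, max_iter=5)
        assert fit.converged and fit.n_iter <= 2
        v1 = uncensored_obs["v1"].to_numpy()
        v2 = uncensored_obs["v2"].to_numpy()
        for region, _ in fit.density.leaves:
            cnt = np.sum((v1 >= region.lo1) & (v1 < region.hi1)
                         & (v2 >= region.lo2) & (v2 < region.hi2))
            assert np.isclose(fit.density.mass(region), cnt / len(uncensored_obs),
                              atol=1e-9)

    def test_density_normalised(self, default_fit):
        assert np.isclose(default_fit.density.integral(), 1.0, atol=1e-6)

    def test_mass_above_diagonal(self, default_fit):
        # T2 > T1 almost surely under the additive model; the piecewise-
        # constant leaves straddling the diagonal cap the recoverable mass
        f = default_fit.density
        total = 0.0
        for region, dens in f.leaves:
            if dens == 0:
                continue
            xs = np.linspace(region.lo1, region.hi1, 41)
            ys = np.clip(region.hi2 - np.maximum(xs, region.lo2), 0,
                         region.hi2 - region.lo2)
            total += dens * np.trapezoid(ys, xs)
        assert total > 0.75

    def test_km_marginal_consistency(self, default_replicate, default_fit):
        # fitted marginal survival of T1 tracks the univariate KM estimate
        obs = default_replicate.observations
        km = km_fit(obs["v1"], obs["delta1"])
        ts = np.quantile(obs["v1"], np.linspace(0.05, 0.95, 19))
        err = [abs(default_fit.density.marginal_survival(1, t) - km(t)) for t in ts]
        assert np.mean(err) < 0.05

    def test_tv_sequence_settles(self):
        # successive TV distances nonincreasing after the second iteration
        # in most seeded runs
        from ctiva.simulate import SimConfig, make_replicate

        good = 0
        for seed in range(5):
            rep = make_replicate(SimConfig(n_samples=200, n_variables=4,
                                           block_sizes=(1, 1, 1, 1), seed=seed))
            fit = fit_joint(rep.observations, max_depth=6, max_iter=8, tol=1e-4)
            diffs = np.diff(fit.tv_history[1:])
            if len(diffs) == 0 or np.all(diffs <= 1e-9):
                good += 1
        assert good >= 4

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_joint(pd.DataFrame({"v1": [1.0], "delta1": [1],
                                    "v2": [2.0], "delta2": [1]}))


class TestDensityJson:
    def test_roundtrip(self, default_fit):
        f = default_fit.density
        g = density_from_json(density_to_json(f))
        assert np.isclose(f.tv_distance(g), 0.0, atol=1e-12)
        region = Region(0.1, 0.9, 0.2, 1.4)
        assert np.isclose(f.mass(region), g.mass(region), atol=1e-12)
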