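import numpy as np
import pytest
from hypothesis import given, strategies as st

from rigiperc import criticality as cr
from rigiperc import lattice as lt
from rigiperc.errors import EstimationError


@pytest.fixture(scope="module")
def small_ensemble():
    """N ~ 95 sweep over a coarse near-critical grid."""
    return cr.sweep_ensemble([95], np.linspace(0.4, 1.0, 13), replicas=20, seed=1)


class TestGcCurve:
    def test_fully_connected_end_is_deterministically_rigid(self, small_ensemble):
        stats = small_ensemble.gc_stats()
        top = stats[np.isclose(stats["k"], 1.0)]
        assert top["mean"].iloc[0] == pytest.approx(1.0)
        assert top["std"].iloc[0] == pytest.approx(0.0)

    def test_low_connectivity_is_floppy(self):
        ens = cr.sweep_ensemble([95], [0.3], replicas=20, seed=2)
        assert ens.records["gc"].mean() < 0.1

    def test_transition_sharpens_with_size(self):
        grid = np.linspace(0.6, 0.75, 4)
        small = cr.sweep_ensemble([46], grid, replicas=25, seed=3)
        large = cr.sweep_ensemble([352], grid, replicas=25, seed=3)
        # spread of gc across the window is larger for larger N (sharper
        # rise) while deep sub/super-critical values pin to 0/1
        rng_small = small.gc_stats()["mean"].max() - small.gc_stats()["mean"].min()
        rng_large = large.gc_stats()["mean"].max() - large.gc_stats()["mean"].min()
        assert rng_large > rng_small

    def test_gc_mean_nondecreasing_in_k(self, small_ensemble):
        means = small_ensemble.gc_stats().sort_values("k")["mean"].to_numpy()
        assert np.all(np.diff(means) > -0.08)  # monotone up to sampling noise

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            cr.sweep_ensemble([95], [0.5, 0.4], replicas=2, seed=0)
        with pytest.raises(ValueError):
            cr.sweep_ensemble([95], [0.5], replicas=0, seed=0)


class TestClusterSizeStats:
    def test_only_spanning_cluster_gives_missing_values(self):
        ens = cr.sweep_ensemble([95], [1.0], replicas=3, seed=0)
        stats = cr.cluster_size_stats(ens)
        assert np.isnan(stats["mean_s"]).all()
        assert np.isnan(stats["var_s"]).all()

    def test_pool_moments_are_finite_near_the_transition(self, small_ensemble):
        stats = cr.cluster_size_stats(small_ensemble)
        mid = stats[(stats["k"] > 0.5) & (stats["k"] < 0.9)]
        assert (mid["n_pool"] > 0).all()
        assert (mid["mean_s"] >= 3).all()
        assert (mid["var_s"] >= 0).all()


class TestFindCriticalK:
    def test_variance_peak_lands_near_the_transition(self, small_ensemble):
        cp = cr.find_critical_k(small_ensemble, "variance-peak")
        assert cp.method == "variance-peak"
        assert 0.6 < cp.k_c < 0.85

    def test_gc_crossing_lands_near_the_transition(self, small_ensemble):
        cp = cr.find_critical_k(small_ensemble, "gc-crossing")
        assert 0.6 < cp.k_c < 0.8

    def test_methods_agree_roughly(self, small_ensemble):
        a = cr.find_critical_k(small_ensemble, "variance-peak").k_c
        b = cr.find_critical_k(small_ensemble, "gc-crossing").k_c
        assert abs(a - b) < 0.1

    def test_unknown_method_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            cr.find_critical_k(small_ensemble, "magic")

    def test_no_interior_peak_is_estimation_failure(self):
        ens = cr.sweep_ensemble([95], [0.85, 0.9, 0.95], replicas=5, seed=4)
        with pytest.raises(EstimationError):
            cr.find_critical_k(ens, "variance-peak")

    def test_never_crossing_is_estimation_failure(self):
        ens = cr.sweep_ensemble([95], [0.3, 0.4, 0.5], replicas=5, seed=4)
        with pytest.raises(EstimationError):
            cr.find_critical_k(ens, "gc-crossing")


class TestPowerlawMLE:
    def test_recovers_planted_exponent(self):
        sizes = cr.sample_discrete_powerlaw(2.5, 3, 10_000, seed=0)
        fit = cr.powerlaw_mle(sizes, s_min=3)
        assert fit.exponent == pytest.approx(2.5, abs=0.1)
        assert fit.n_tail == 10_000

    @pytest.mark.parametrize("gamma", [2.0, 3.0])
    def test_recovery_across_exponents(self, gamma):
        sizes = cr.sample_discrete_powerlaw(gamma, 3, 10_000, seed=1)
        assert cr.powerlaw_mle(sizes, 3).exponent == pytest.approx(gamma, abs=0.1)

    def test_degenerate_sample_is_estimation_failure(self):
        with pytest.raises(EstimationError):
            cr.powerlaw_mle([5] * 100, s_min=3)

    def test_too_few_observations_is_estimation_failure(self):
        with pytest.raises(EstimationError):
            cr.powerlaw_mle([3, 4, 5, 6], s_min=3)


class TestJSDivergence:
    def test_identity(self):
        assert cr.js_divergence([0.2, 0.8], [0.2, 0.8]) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_saturate_at_one(self):
        assert cr.js_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # p = (1/2, 1/2), q = (1, 0): JSD = 3/2 - (1/2) log2 3 = 0.31128
        assert cr.js_divergence([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.3113, abs=2e-4)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            cr.js_divergence([0.5, 0.6], [1.0, 0.0])
        with pytest.raises(ValueError):
            cr.js_divergence([0.5, 0.5], [0.5, 0.5, 0.0])

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_symmetry_and_bounds(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        q = np.roll(p, 1)
        d = cr.js_divergence(p, q)
        assert 0.0 <= d <= 1.0 + 1e-9
        assert d == pytest.approx(cr.js_divergence(q, p), abs=1e-12)


class TestNearCriticalPool:
    @staticmethod
    def _networks(ks, seed=0):
        full = lt.build_full_lattice(10)
        cmax = lt.max_connectivity_bulk(full.n_nodes)
        return [lt.dilute_random(full, k * cmax, seed=seed + i)
                for i, k in enumerate(ks)]

    def test_zero_width_window_selects_exact_matches_only(self):
        nets = self._networks([0.70, 0.72, 0.74])
        k_mid = lt.connectivity_report(nets[1]).normalized_connectivity
        pool, n = cr.near_critical_pool(nets, k_mid, half_width=0.0)
        assert n == 1

    def test_widening_window_grows_selection_monotonically(self):
        nets = self._networks(np.linspace(0.6, 0.85, 12))
        counts = [cr.near_critical_pool(nets, 0.72, half_width=w)[1]
                  for w in (0.01, 0.03, 0.08, 0.2)]
        assert counts == sorted(counts)

    def test_empty_selection_warns(self):
        nets = self._networks([0.4])
        with pytest.warns(UserWarning):
            pool, n = cr.near_critical_pool(nets, 0.9, half_width=0.01)
        assert n == 0 and pool == []


class TestFitLambda:
    def test_single_point_grid_returns_it(self):
        obs = [3] * 30 + [4] * 10 + [5] * 5
        lam, table = cr.fit_lambda(obs, [95] * 5, (2.8, 4.5), [0.3],
                                   replicas=2, seed=0)
        assert lam == 0.3
        assert len(table) == 1

    def test_uncorrelated_observations_prefer_small_lambda(self):
        rng = np.random.default_rng(0)
        full = lt.build_full_lattice(10)
        from rigiperc.rigidity import finite_cluster_sizes, rigid_clusters

        obs = []
        for i in range(40):
            c = rng.uniform(2.8, 4.5)
            dil = lt.dilute_random(full, c, seed=i)
            obs.extend(finite_cluster_sizes(rigid_clusters(dil), dil.coords))
        lam, table = cr.fit_lambda(obs, [95] * 40, (2.8, 4.5),
                                   [0.0, 0.45, 0.9], replicas=4, seed=1)
        assert lam == 0.0

    def test_grid_outside_range_rejected(self):
        with pytest.raises(ValueError):
            cr.fit_lambda([3, 4], [95], (2.8, 4.5), [0.5, 1.0])


class TestSecondCluster:
    def test_fully_connected_has_no_second_cluster(self):
        mean, sd = cr.second_cluster_expectation(95, 5.03, replicas=5, seed=0)
        assert mean == pytest.approx(0.0)

    def test_correlated_dilution_enlarges_second_cluster(self):
        # at matched connectivity, spatially correlated bond loss leaves a
        # larger second rigid cluster than the random expectation
        from rigiperc.rigidity import rigid_clusters

        full = lt.build_full_lattice(10)
        C = 3.8
        exp_mean, _ = cr.second_cluster_expectation(95, C, replicas=60, seed=1)
        params = lt.CorrelationParams(1.0, 0.47)
        vals = []
        for s in range(60):
            dil = lt.dilute_correlated(full, C, params, seed=s)
            vals.append(rigid_clusters(dil).second_gc_fraction)
        assert np.mean(vals) > exp_mean

    def test_replica_floor(self):
        with pytest.raises(ValueError):
            cr.second_cluster_expectation(95, 3.8, replicas=1, seed=0)


class TestVarianceScaling:
    def test_single_size_rejected(self):
        with pytest.raises(ValueError):
            cr.variance_scaling([95], replicas=2, seed=0)
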