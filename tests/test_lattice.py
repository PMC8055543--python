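import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rigiperc import lattice as lt


class TestBuildFullLattice:
    @pytest.mark.parametrize(
        "L,N",
        [(2, 3), (7, 46), (10, 95), (11, 116), (15, 218), (16, 248),
         (18, 315), (19, 352), (25, 613), (35, 1208)],
    )
    def test_printed_size_pairs(self, L, N):
        lat = lt.build_full_lattice(L)
        assert lat.n_nodes == N == lt.lattice_size(L)

    def test_side_12_gives_138(self):
        # the alternating-row rule gives 138 for L = 12; no special-casing
        assert lt.lattice_size(12) == 138

    def test_smallest_patch_is_a_triangle(self):
        lat = lt.build_full_lattice(2)
        assert lat.n_nodes == 3 and lat.n_edges == 3

    def test_all_bonds_unit_length(self):
        lat = lt.build_full_lattice(6)
        ea = lat.edge_array()
        lengths = np.linalg.norm(lat.coords[ea[:, 1]] - lat.coords[ea[:, 0]], axis=1)
        assert np.allclose(lengths, 1.0)

    def test_bonds_are_all_nearest_neighbour_pairs(self):
        lat = lt.build_full_lattice(5)
        d = np.linalg.norm(lat.coords[:, None] - lat.coords[None, :], axis=2)
        expected = {(i, j) for i in range(lat.n_nodes)
                    for j in range(i + 1, lat.n_nodes)
                    if abs(d[i, j] - 1.0) < 1e-9}
        assert set(lat.edges) == expected

    def test_too_small_side_rejected(self):
        with pytest.raises(ValueError):
            lt.build_full_lattice(1)


class TestConnectivityReport:
    def test_triangle_mean_connectivity(self, triangle_lattice):
        rep = lt.connectivity_report(triangle_lattice)
        assert rep.mean_connectivity == 2.0

    def test_printed_formula_at_L7(self):
        # direct evaluation: (8 + 16*5 + 6*25) / 46 = 238/46
        assert lt.max_connectivity(7, 46) == pytest.approx(238 / 46)

    def test_row_convention_reproduces_printed_formula(self):
        lat = lt.build_full_lattice(7)
        rep = lt.connectivity_report(lat, boundary="rows")
        assert rep.max_connectivity == pytest.approx(238 / 46)
        # the full patch's measured connectivity (4.83, close to the
        # reported 4.9 for this patch)
        assert rep.mean_connectivity == pytest.approx(222 / 46)

    def test_limit_approaches_six(self):
        L = 400
        N = lt.lattice_size(L)
        assert lt.max_connectivity(L, N) == pytest.approx(6.0, abs=0.05)
        assert lt.max_connectivity_bulk(N) == pytest.approx(6.0, abs=0.05)

    def test_sqrt_convention_normalizes_full_lattice_to_one(self):
        for L in (7, 11, 35):
            lat = lt.build_full_lattice(L)
            k = lt.connectivity_report(lat).normalized_connectivity
            assert k == pytest.approx(1.0, abs=0.01)

    def test_missing_side_raises(self):
        from rigiperc.errors import InvalidStateError

        lat = lt.Lattice(np.array([[0, 0], [1, 0], [0.5, 0.9]]),
                         [(0, 1)], L=None)
        with pytest.raises(InvalidStateError):
            lt.connectivity_report(lat, boundary="rows")


class TestDiluteRandom:
    def test_partially_connected_patch_edge_count(self):
        # <C> = 3.6 on the N = 46 patch -> round(3.6 * 46 / 2) = 83 bonds
        lat = lt.build_full_lattice(7)
        dil = lt.dilute_random(lat, 3.6, seed=0)
        assert dil.n_edges == 83
        assert abs(dil.mean_connectivity - 3.6) <= 2 / 46

    def test_target_at_current_is_identity(self):
        lat = lt.build_full_lattice(5)
        dil = lt.dilute_random(lat, lat.mean_connectivity, seed=3)
        assert dil.edges == lat.edges

    def test_same_seed_same_edges(self):
        lat = lt.build_full_lattice(8)
        a = lt.dilute_random(lat, 3.0, seed=11)
        b = lt.dilute_random(lat, 3.0, seed=11)
        assert a.edges == b.edges
        c = lt.dilute_random(lat, 3.0, seed=12)
        assert a.edges != c.edges

    def test_target_above_current_rejected(self):
        lat = lt.build_full_lattice(5)
        dil = lt.dilute_random(lat, 3.0, seed=0)
        with pytest.raises(ValueError):
            lt.dilute_random(dil, 5.0, seed=0)

    @given(st.integers(3, 9), st.floats(0.5, 4.5), st.integers(0, 2**31 - 1))
    def test_dilution_invariants(self, L, target, seed):
        lat = lt.build_full_lattice(L)
        target = min(target, lat.mean_connectivity)
        dil = lt.dilute_random(lat, target, seed)
        assert set(dil.edges) <= set(lat.edges)
        assert abs(dil.mean_connectivity - target) <= 2 / lat.n_nodes
        assert dil.n_nodes == lat.n_nodes


class TestDiluteCorrelated:
    def test_invalid_strength_rejected(self):
        with pytest.raises(ValueError):
            lt.CorrelationParams(1.0, 1.5)
        with pytest.raises(ValueError):
            lt.CorrelationParams(0.0, 0.5)

    def test_reaches_target_connectivity(self):
        lat = lt.build_full_lattice(9)
        params = lt.CorrelationParams(1.0, 0.8)
        dil = lt.dilute_correlated(lat, 3.5, params, seed=5)
        assert abs(dil.mean_connectivity - 3.5) <= 2 / lat.n_nodes

    def test_deterministic_given_seed(self):
        lat = lt.build_full_lattice(9)
        params = lt.CorrelationParams(1.0, 0.47)
        a = lt.dilute_correlated(lat, 3.5, params, seed=5)
        b = lt.dilute_correlated(lat, 3.5, params, seed=5)
        assert a.edges == b.edges

    @staticmethod
    def _removal_autocorrelation(lat, dil, vic):
        """Mean fraction of each removed bond's vicinity that is also
        removed (a Moran-style bond-absence autocorrelation at lag <= l)."""
        removed = np.array([e not in set(dil.edges) for e in lat.edges])
        vals = [removed[v].mean() for i, v in enumerate(vic)
                if removed[i] and len(v)]
        return float(np.mean(vals))

    def test_correlated_removal_clusters_in_space(self):
        # lambda = 0.9 leaves holes: the bond-absence autocorrelation at
        # lag <= l clearly exceeds the uncorrelated ensemble's
        lat = lt.build_full_lattice(10)
        vic = lt.edge_vicinities(lat, 1.0)
        target = 0.7 * lt.max_connectivity_bulk(lat.n_nodes)
        strong, none = [], []
        for seed in range(30):
            d1 = lt.dilute_correlated(lat, target,
                                      lt.CorrelationParams(1.0, 0.9), seed)
            d0 = lt.dilute_random(lat, target, seed)
            strong.append(self._removal_autocorrelation(lat, d1, vic))
            none.append(self._removal_autocorrelation(lat, d0, vic))
        assert np.mean(strong) > np.mean(none) + 0.05

    def test_zero_strength_matches_random_statistics(self):
        # with lambda = 0 every removal restarts at a uniform bond, so the
        # autocorrelation statistic is indistinguishable from dilute_random
        lat = lt.build_full_lattice(10)
        vic = lt.edge_vicinities(lat, 1.0)
        target = 0.7 * lt.max_connectivity_bulk(lat.n_nodes)
        a, b = [], []
        for seed in range(30):
            d1 = lt.dilute_correlated(lat, target,
                                      lt.CorrelationParams(1.0, 0.0), seed)
            d0 = lt.dilute_random(lat, target, seed + 1000)
            a.append(self._removal_autocorrelation(lat, d1, vic))
            b.append(self._removal_autocorrelation(lat, d0, vic))
        assert abs(np.mean(a) - np.mean(b)) < 0.02


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        lat = lt.dilute_random(lt.build_full_lattice(6), 3.2, seed=9)
        path = tmp_path / "net.json"
        lt.write_json(lat, path)
        back = lt.read_json(path)
        assert back.edges == lat.edges
        assert np.allclose(back.coords, lat.coords)
        assert back.L == lat.L
        assert back.meta["seed"] == 9

    def test_csv_round_trip(self, tmp_path):
        lat = lt.dilute_random(lt.build_full_lattice(6), 3.2, seed=9)
        lt.write_csv(lat, tmp_path / "e.csv", tmp_path / "c.csv")
        back = lt.read_csv(tmp_path / "e.csv", tmp_path / "c.csv", L=lat.L)
        assert back.edges == lat.edges
        assert np.allclose(back.coords, lat.coords)

    def test_malformed_ids_rejected(self, tmp_path):
        doc = {"nodes": [{"id": 0, "x": 0, "y": 0}, {"id": 2, "x": 1, "y": 0}],
               "edges": [[0, 2]], "meta": {}}
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValueError):
            lt.read_json(p)


class TestLatticeValidation:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            lt.Lattice(np.zeros((3, 2)), [(0, 0)], L=2)

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError):
            lt.Lattice(np.zeros((3, 2)), [(0, 1), (1, 0)], L=2)

    def test_dangling_endpoint_rejected(self):
        with pytest.raises(ValueError):
            lt.Lattice(np.zeros((3, 2)), [(0, 5)], L=2)
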