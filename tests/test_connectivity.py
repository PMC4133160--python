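"""Connectivity generator: local Gaussian sampling, remote patches,
matrix assembly, statistics, microincision."""

import numpy as np
import pytest
import scipy.sparse as sp

from seizuresheet import (
    apply_microincision,
    assemble_weight_matrices,
    build_geometry,
    connection_statistics,
    sample_local_connections,
    sample_remote_patches,
)
from seizuresheet.connectivity import build_connectivity


class TestLocalSampler:
    def test_hard_cutoff_exhaustive(self, torus_geom, conn_params):
        adj = sample_local_connections(torus_geom, conn_params.sigma_um,
                                       conn_params.local_radius_um, seed=3)
        m = adj.tocoo()
        d = torus_geom.distance_um(m.row, m.col)
        assert d.max() <= conn_params.local_radius_um
        assert d.min() >= torus_geom.pitch_um  # no self-connections
        assert np.all(m.row != m.col)

    def test_seed_determinism(self, torus_geom, conn_params):
        a1 = sample_local_connections(torus_geom, conn_params.sigma_um,
                                      conn_params.local_radius_um, seed=3)
        a2 = sample_local_connections(torus_geom, conn_params.sigma_um,
                                      conn_params.local_radius_um, seed=3)
        assert (a1 != a2).nnz == 0
        a3 = sample_local_connections(torus_geom, conn_params.sigma_um,
                                      conn_params.local_radius_um, seed=4)
        assert (a1 != a3).nnz > 0

    def test_distance_law_matches_truncated_gaussian(self, conn_params):
        """Empirical connection frequency per distance bin within three
        binomial standard errors of exp(-d^2 / 2 sigma^2)."""
        geom = build_geometry(40, 40, macro_edge=10, boundary="torus")
        sigma, radius = conn_params.sigma_um, conn_params.local_radius_um
        adj = sample_local_connections(geom, sigma, radius, seed=9)
        m = adj.tocoo()
        d = geom.distance_um(m.row, m.col)
        # enumerate candidate ordered pairs per exact lattice distance
        from collections import Counter

        cand = Counter()
        rad = int(radius // geom.pitch_um) + 1
        for dx in range(-rad, rad + 1):
            for dy in range(-rad, rad + 1):
                if (dx, dy) == (0, 0):
                    continue
                dist = geom.pitch_um * np.hypot(dx, dy)
                if dist <= radius:
                    cand[round(dist, 6)] += geom.n_units
        got = Counter(np.round(d, 6))
        for dist, n_trials in cand.items():
            p = np.exp(-dist**2 / (2 * sigma**2))
            se = np.sqrt(p * (1 - p) / n_trials)
            assert abs(got.get(dist, 0) / n_trials - p) < 3 * se + 1e-12, (
                f"distance {dist}: freq {got.get(dist, 0) / n_trials:.4f} vs p {p:.4f}"
            )


class TestRemotePatches:
    def test_patch_membership_radius_and_cardinality(self, torus_geom, conn_params):
        layout, adj = sample_remote_patches(torus_geom, conn_params, seed=5)
        for center, members in layout.members.items():
            dists = torus_geom.distance_um(np.full(len(members), center), members)
            assert np.all(dists <= conn_params.patch_radius_units * torus_geom.pitch_um)
            assert len(members) == 81  # lattice disc of radius 5, torus

    def test_zero_flux_edge_patches_may_be_smaller(self, zeroflux_geom, conn_params):
        import dataclasses

        cp = dataclasses.replace(conn_params, max_patch_distance_um=700.0)
        layout, _ = sample_remote_patches(zeroflux_geom, cp, seed=5)
        sizes = [len(m) for m in layout.members.values()]
        assert max(sizes) <= 81

    def test_out_degree_capped_at_n_out_remote(self, torus_geom, conn_params):
        _, adj = sample_remote_patches(torus_geom, conn_params, seed=5)
        out_deg = np.asarray(adj.sum(axis=1)).ravel()
        assert out_deg.max() <= conn_params.n_out_remote
        # with a large enough pool the cap is nearly attained on average
        assert out_deg.mean() > 0.9 * conn_params.n_out_remote

    def test_sharing_names_exactly_one_direct_neighbour(self, torus_geom, conn_params):
        layout, _ = sample_remote_patches(torus_geom, conn_params, seed=5)
        g = torus_geom
        for macro, partner in layout.sharing.items():
            mr, mc = divmod(macro, g.macro_cols)
            pr, pc = divmod(partner, g.macro_cols)
            dr = min(abs(mr - pr), g.macro_rows - abs(mr - pr))
            dc = min(abs(mc - pc), g.macro_cols - abs(mc - pc))
            assert sorted((dr, dc)) == [0, 1]
            shared = set(layout.centers[macro]) & set(layout.centers[partner])
            assert len(shared) >= conn_params.n_shared_patches

    def test_too_small_geometry_rejected(self, conn_params):
        import dataclasses

        geom = build_geometry(10, 10, macro_edge=10)
        cp = dataclasses.replace(conn_params, max_patch_distance_um=50.0,
                                 n_patches_per_macro=10)
        with pytest.raises(ValueError):
            sample_remote_patches(geom, cp, seed=1)


class TestAssembly:
    def test_empty_adjacencies_give_diagonal(self, torus_geom, conn_params, standard_unit):
        n = torus_geom.n_units
        empty = sp.csr_matrix((n, n))
        model = assemble_weight_matrices(empty, empty, empty, standard_unit,
                                         conn_params, torus_geom)
        assert (model.w_ee != conn_params.w_self_e * sp.identity(n)).nnz == 0
        assert (model.w_ei != conn_params.w_self_ei * sp.identity(n)).nnz == 0

    def test_ie_ii_strictly_diagonal(self, small_sheet):
        for mat in (small_sheet.model.w_ie, small_sheet.model.w_ii):
            coo = mat.tocoo()
            assert np.all(coo.row == coo.col)

    def test_diagonals_match_unit_constants(self, small_sheet, conn_params):
        m, u = small_sheet.model, small_sheet.unit
        assert np.allclose(m.w_ee.diagonal(), conn_params.w_self_e)
        assert np.allclose(m.w_ei.diagonal(), conn_params.w_self_ei)
        assert np.allclose(m.w_ie.diagonal(), u.c_ie)
        assert np.allclose(m.w_ii.diagonal(), u.c_ii)
        assert conn_params.w_self_e == u.c_ee
        assert conn_params.w_self_ei == u.c_ei

    def test_all_weights_non_negative(self, small_sheet):
        for name in ("w_ee", "w_ei", "w_ie", "w_ii"):
            assert getattr(small_sheet.model, name).min() >= 0

    def test_local_remote_ratio_matches_hand_count(self, torus_geom, conn_params, standard_unit):
        local_ee = sample_local_connections(torus_geom, conn_params.sigma_um,
                                            conn_params.local_radius_um, seed=21)
        local_ei = sample_local_connections(torus_geom, conn_params.sigma_um,
                                            conn_params.local_radius_um, seed=22)
        _, remote = sample_remote_patches(torus_geom, conn_params, seed=23)
        model = assemble_weight_matrices(local_ee, local_ei, remote, standard_unit,
                                         conn_params, torus_geom)
        assert model.provenance["n_local_ee"] == local_ee.nnz
        assert model.provenance["n_remote_ee"] == remote.nnz
        assert model.provenance["local_remote_ratio"] == pytest.approx(
            local_ee.nnz / remote.nnz
        )


class TestStatistics:
    def test_handshake_identity(self, small_sheet):
        stats = connection_statistics(small_sheet.model)
        for name, s in stats.items():
            assert s["in_degree"].sum() == s["out_degree"].sum() == s["n_connections"]

    def test_local_distance_support(self, small_sheet, conn_params):
        stats = connection_statistics(small_sheet.model)
        edges = stats["local_ee"]["distance_edges"]
        hist = stats["local_ee"]["distance_hist"]
        nonzero = edges[:-1][hist > 0]
        assert nonzero.min() >= small_sheet.geometry.pitch_um - 1e-9
        assert nonzero.max() <= conn_params.local_radius_um

    def test_remote_distances_bounded_by_reach_plus_sharing(self, small_sheet, conn_params):
        stats = connection_statistics(small_sheet.model)
        edges = stats["remote_ee"]["distance_edges"]
        hist = stats["remote_ee"]["distance_hist"]
        max_d = edges[:-1][hist > 0].max()
        g = small_sheet.geometry
        macro_um = g.macro_edge * g.pitch_um
        reach = (min(conn_params.max_patch_distance_um,
                     (min(g.n_rows, g.n_cols) // 2) * g.pitch_um)
                 + conn_params.patch_radius_units * g.pitch_um
                 + macro_um * 1.5)
        assert max_d <= reach


class TestMicroincision:
    def test_cut_in_connection_free_corner_changes_nothing(self, small_sheet):
        g = small_sheet.geometry
        # a tiny segment between unit centers' grid, far shorter than a pitch
        cut = [((1.0, 1.0), (2.0, 2.0))]
        out = apply_microincision(small_sheet.model, cut)
        assert (out.w_ee != small_sheet.model.w_ee).nnz == 0

    def test_enclosing_rectangle_cuts_all_crossing_chords(self, small_sheet):
        """Brute-force chord test: after a closed rectangular cut, no
        remaining connection crosses the rectangle boundary."""
        g = small_sheet.geometry
        p = g.pitch_um
        # segments overlap past the corners so diagonal chords cannot
        # slip exactly through a joint (endpoint touches do not cut)
        lo, hi, ov = 9.5, 20.5, 1.0
        box = [(((lo - ov) * p, lo * p), ((hi + ov) * p, lo * p)),
               ((hi * p, (lo - ov) * p), (hi * p, (hi + ov) * p)),
               (((hi + ov) * p, hi * p), ((lo - ov) * p, hi * p)),
               ((lo * p, (hi + ov) * p), (lo * p, (lo - ov) * p))]
        out = apply_microincision(small_sheet.model, box)
        inside = ((g.rows >= 10) & (g.rows <= 20) & (g.cols >= 10) & (g.cols <= 20))
        for mat in (out.w_ee, out.w_ei):
            coo = mat.tocoo()
            off = coo.row != coo.col
            r, c = coo.row[off], coo.col[off]
            # minimal-image chords crossing the box boundary must be gone:
            # any surviving in->out pair must wrap around the torus instead
            crossing = inside[r] != inside[c]
            if crossing.any():
                dr, dc = g.displacement(r[crossing], c[crossing])
                rr, cc = g.unit_coords(r[crossing])
                direct_r = rr + dr
                direct_c = cc + dc
                wraps = ((direct_r < 0) | (direct_r >= g.n_rows)
                         | (direct_c < 0) | (direct_c >= g.n_cols))
                assert wraps.all()

    def test_second_parallel_cut_strictly_reduces(self, small_sheet):
        g = small_sheet.geometry
        p = g.pitch_um
        cut1 = [((5 * p, 0.2 * p), (5 * p, 28 * p))]
        cut2 = cut1 + [((8 * p, 0.2 * p), (8 * p, 28 * p))]
        n0 = small_sheet.model.w_ee.nnz
        n1 = apply_microincision(small_sheet.model, cut1).w_ee.nnz
        n2 = apply_microincision(small_sheet.model, cut2).w_ee.nnz
        assert n2 < n1 < n0

    def test_diagonal_untouched(self, small_sheet):
        g = small_sheet.geometry
        p = g.pitch_um
        out = apply_microincision(small_sheet.model, [((0.5 * p, 0.5 * p), (25 * p, 25 * p))])
        assert np.allclose(out.w_ee.diagonal(), small_sheet.model.w_ee.diagonal())
        assert np.allclose(out.w_ii.diagonal(), small_sheet.model.w_ii.diagonal())

    def test_out_of_bounds_cut_rejected(self, small_sheet):
        with pytest.raises(ValueError):
            apply_microincision(small_sheet.model, [((-5000.0, 0.0), (0.0, 0.0))])


class TestRoundTrip:
    def test_export_import_bitwise(self, small_sheet, tmp_path):
        from seizuresheet.connectivity import export_model, import_model

        export_model(small_sheet.model, tmp_path)
        back = import_model(tmp_path)
        for name in ("w_ee", "w_ei", "w_ie", "w_ii"):
            assert (getattr(back, name) != getattr(small_sheet.model, name)).nnz == 0
        assert back.geometry == small_sheet.geometry

    def test_seeded_rebuild_identical(self, torus_geom, conn_params, standard_unit):
        m1 = build_connectivity(torus_geom, standard_unit, conn_params, seed=77)
        m2 = build_connectivity(torus_geom, standard_unit, conn_params, seed=77)
        assert (m1.w_ee != m2.w_ee).nnz == 0
        assert (m1.w_ei != m2.w_ei).nnz == 0
        m3 = build_connectivity(torus_geom, standard_unit, conn_params, seed=78)
        assert (m1.w_ee != m3.w_ee).nnz > 0
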