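"""Sheet integrator: noise structure, decoupled-limit equivalence,
symmetry, delays, LFP reduction, stimulation."""

import numpy as np
import pytest
import scipy.sparse as sp

from seizuresheet import (
    HeterogeneityMap,
    NoiseSpec,
    RampSpec,
    StimulusSpec,
    build_geometry,
    compute_lfp,
    generate_noise,
    simulate_sheet,
    simulate_unit,
    stimulus_threshold_probe,
)
from seizuresheet.connectivity import assemble_weight_matrices
from seizuresheet.simulator import lfp_excursion_criterion


def diagonal_model(geom, unit, conn_params):
    """Connectivity with empty network terms: every unit decoupled."""
    n = geom.n_units
    empty = sp.csr_matrix((n, n))
    return assemble_weight_matrices(empty, empty, empty, unit, conn_params, geom)


class TestNoise:
    def test_macro_shared_and_moments(self, torus_geom):
        spec = NoiseSpec(coupling=1.0, seed=5)
        arr = generate_noise(torus_geom, spec, 4000)
        macro = torus_geom.macro_of_unit
        # identical within each macrocolumn at every step
        for m in range(torus_geom.n_macros):
            cols = arr[:, macro == m]
            assert np.all(cols == cols[:, :1])
        # per-macro mean 0, std 1 within 3 standard errors
        per_macro = arr[:, [np.argmax(macro == m) for m in range(torus_geom.n_macros)]]
        n = per_macro.shape[0]
        assert np.all(np.abs(per_macro.mean(axis=0)) < 3 / np.sqrt(n))
        assert np.all(np.abs(per_macro.std(axis=0) - 1) < 3 / np.sqrt(2 * n))

    def test_zero_coupling_equals_deterministic(self, small_sheet):
        res_a = simulate_sheet(small_sheet.model, small_sheet.unit,
                               noise=NoiseSpec(0.0, seed=3), duration=200.0)
        res_b = simulate_sheet(small_sheet.model, small_sheet.unit,
                               noise=NoiseSpec(0.0, seed=99), duration=200.0)
        assert np.array_equal(res_a.u, res_b.u)


class TestDecoupledEquivalence:
    def test_sheet_reduces_to_unit_oracle_bitwise(self, standard_unit, conn_params):
        """With all off-diagonal weights zero and a one-macrocolumn
        sheet, every unit's trajectory equals the single-unit
        integrator's with the same seed."""
        geom = build_geometry(10, 10, macro_edge=10)
        model = diagonal_model(geom, standard_unit, conn_params)
        seed = 123
        res = simulate_sheet(model, standard_unit,
                             noise=NoiseSpec(standard_unit.noise_coupling, seed),
                             duration=400.0, dt=2.0)
        t, u, v = simulate_unit(standard_unit, init=(0.0, 0.0), duration=400.0,
                                dt=2.0, noise_seed=seed)
        for j in (0, 37, 99):
            assert np.array_equal(res.u[:, j].astype(float), u.astype(np.float32).astype(float))
            assert np.array_equal(res.v[:, j].astype(float), v.astype(np.float32).astype(float))


class TestInvariants:
    def test_determinism_bit_for_bit(self, small_sheet):
        kw = dict(noise=NoiseSpec(0.5, seed=11), duration=300.0)
        r1 = simulate_sheet(small_sheet.model, small_sheet.unit, **kw)
        r2 = simulate_sheet(small_sheet.model, small_sheet.unit, **kw)
        assert np.array_equal(r1.u, r2.u) and np.array_equal(r1.v, r2.v)

    def test_boundedness(self, small_sheet):
        res = simulate_sheet(small_sheet.model, small_sheet.unit,
                             noise=NoiseSpec(1.0, seed=2), duration=2000.0)
        assert res.u.min() >= 0 and res.u.max() <= 1
        assert res.v.min() >= 0 and res.v.max() <= 1

    def test_homogeneous_torus_stays_homogeneous(self, standard_unit, conn_params):
        """Noiseless, homogeneous parameters, translation-invariant
        (all-to-all-by-offset) coupling: spatial variance stays ~0.

        Random sampled connectivity is not translation invariant, so the
        symmetry check uses deterministic diagonal connectivity."""
        geom = build_geometry(20, 20, macro_edge=10)
        model = diagonal_model(geom, standard_unit, conn_params)
        res = simulate_sheet(model, standard_unit, noise=NoiseSpec(0.0, 0),
                             duration=2000.0,
                             init=(np.full(400, 0.37), np.full(400, 0.11)))
        assert np.all(res.u.var(axis=1) < 1e-12)
        assert np.all(res.v.var(axis=1) < 1e-12)

    def test_step_halving_small_change(self, small_sheet):
        """Deterministic macro LFP changes by < 5% RMS under dt -> dt/2."""
        kw = dict(noise=NoiseSpec(0.0, 0), duration=2000.0,
                  init=(np.full(900, 0.2), np.full(900, 0.05)))
        r1 = simulate_sheet(small_sheet.model, small_sheet.unit, dt=2.0,
                            record_every=1, **kw)
        r2 = simulate_sheet(small_sheet.model, small_sheet.unit, dt=1.0,
                            record_every=2, **kw)
        lfp1, lfp2 = r1.lfp, r2.lfp
        n = min(len(lfp1), len(lfp2))
        rms = np.sqrt(np.mean((lfp1[:n] - lfp2[:n]) ** 2))
        scale = max(np.sqrt(np.mean(lfp1[:n] ** 2)), 1e-9)
        assert rms / scale < 0.05


class TestDelays:
    def test_infinite_speed_reproduces_undelayed(self, small_sheet):
        kw = dict(noise=NoiseSpec(0.5, seed=4), duration=300.0)
        r0 = simulate_sheet(small_sheet.model, small_sheet.unit, **kw)
        r1 = simulate_sheet(small_sheet.model, small_sheet.unit,
                            delay_speed=np.inf, **kw)
        assert np.array_equal(r0.u, r1.u)

    def test_very_fast_finite_speed_matches(self, small_sheet):
        kw = dict(noise=NoiseSpec(0.5, seed=4), duration=300.0)
        r0 = simulate_sheet(small_sheet.model, small_sheet.unit, **kw)
        r1 = simulate_sheet(small_sheet.model, small_sheet.unit,
                            delay_speed=1e9, **kw)
        assert np.max(np.abs(r0.u - r1.u)) < 1e-12

    def test_slow_speed_changes_dynamics_and_buffer_validated(self, small_sheet):
        kw = dict(noise=NoiseSpec(0.5, seed=4), duration=300.0)
        r0 = simulate_sheet(small_sheet.model, small_sheet.unit, **kw)
        r1 = simulate_sheet(small_sheet.model, small_sheet.unit,
                            delay_speed=5.0, **kw)  # um/ms: several-step delays
        assert not np.array_equal(r0.u, r1.u)
        with pytest.raises(ValueError):
            simulate_sheet(small_sheet.model, small_sheet.unit,
                           delay_speed=0.05, noise=NoiseSpec(0.5, 4), duration=40.0)


class TestLFP:
    def test_uniform_sheet_lfp_equals_signal(self, small_sheet):
        res = simulate_sheet(small_sheet.model, small_sheet.unit,
                             noise=NoiseSpec(0.0, 0), duration=100.0)
        assert np.allclose(res.lfp, res.u[:, :1], atol=1e-6)

    def test_linearity_and_checkerboard(self, torus_geom):
        from seizuresheet.simulator import SimulationResult

        n = torus_geom.n_units
        u = np.zeros((3, n), dtype=np.float32)
        u[1] = ((torus_geom.rows + torus_geom.cols) % 2).astype(np.float32)
        u[2] = 2 * u[1] * 0.5
        res = SimulationResult(np.arange(3.0), u, u.copy(), torus_geom, 1.0, NoiseSpec(0, 0))
        lfp = compute_lfp(res)
        assert np.allclose(lfp[1], 0.5)          # checkerboard averages to 1/2
        assert np.allclose(2 * compute_lfp(res)[1], compute_lfp(res)[2] * 2)
        with pytest.raises(ValueError):
            compute_lfp(res, mode="esp")


class TestStimuli:
    def test_state_reset_sets_u_only(self, small_sheet):
        mask = np.arange(50)
        stim = StimulusSpec("state_reset", mask, 1.0, onset=10.0)
        res = simulate_sheet(small_sheet.model, small_sheet.unit, stimuli=(stim,),
                             noise=NoiseSpec(0.0, 0), duration=20.0, dt=2.0)
        k = np.searchsorted(res.t, 10.0) + 1
        assert np.allclose(res.u[k, mask], 1.0)
        ref = simulate_sheet(small_sheet.model, small_sheet.unit,
                             noise=NoiseSpec(0.0, 0), duration=20.0, dt=2.0)
        assert np.allclose(res.v[k, mask], ref.v[k, mask])

    def test_ramp_clamps_and_interpolates(self):
        r = RampSpec("p_basal", -3.0, -1.0, 1000.0, 3000.0)
        assert r.value(0) == -3.0
        assert r.value(2000.0) == -2.0
        assert r.value(5000.0) == -1.0

    def test_heterogeneity_validation(self):
        het = HeterogeneityMap()
        with pytest.raises(ValueError):
            het.set_absolute("bogus_field", [0], 1.0)
        het.set_absolute("p_basal", [999999], -1.0)
        with pytest.raises(ValueError):
            het.apply({"p_basal": np.zeros(10)}, 10)


class TestThresholdProbe:
    def test_bracket_failure_reported(self, small_sheet):
        crit = lfp_excursion_criterion(threshold=2.0)  # impossible: u <= 1
        out = stimulus_threshold_probe(
            small_sheet.model, small_sheet.unit,
            probe_mask=np.arange(60), response_criterion=crit,
            bracket=(0.1, 0.2), duration=600.0,
        )
        assert out == "no threshold in range"

    def test_threshold_matches_grid_scan_and_monotone_in_p(self, small_sheet):
        """Bisection equals a fine amplitude grid scan within one grid
        step, and the threshold does not increase as the basal drive
        steps toward the oscillatory regime."""
        crit = lfp_excursion_criterion(threshold=0.3, after=550.0)
        mask = small_sheet.geometry.disc(
            small_sheet.geometry.unit_index(15, 15), 5)

        thresholds = []
        for p_off in (0.0, 0.6):
            unit = small_sheet.unit.replace(p_basal=small_sheet.unit.p_basal + p_off)
            thr = stimulus_threshold_probe(
                small_sheet.model, unit, probe_mask=mask,
                response_criterion=crit, bracket=(0.0, 6.0),
                duration=1600.0, noise_seed=3,
            )
            assert isinstance(thr, float)
            thresholds.append(thr)

            if p_off == 0.0:
                from seizuresheet.simulator import NoiseSpec, StimulusSpec, simulate_sheet

                grid = np.linspace(0.0, 6.0, 100)
                responded = []
                for amp in grid:
                    stim = StimulusSpec("input_pulse", mask, amp, 500.0, 100.0)
                    res = simulate_sheet(
                        small_sheet.model, unit, stimuli=(stim,),
                        noise=NoiseSpec(unit.noise_coupling, 3),
                        duration=1600.0,
                    )
                    responded.append(crit(res))
                first = grid[int(np.argmax(responded))]
                assert abs(thr - first) <= grid[1] - grid[0] + 1e-9
        assert thresholds[1] <= thresholds[0]
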