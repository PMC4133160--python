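"""Fixed-step stochastic integration of the coupled cortical sheet.

The sheet obeys the vectorized minicolumn equations

    tau_e * du/dt = -u + f(W_EE u - W_IE v + P_t + B xi_t + pulses)
    tau_i * dv/dt = -v + f(W_EI u - W_II v + Q_t)

integrated with explicit Euler at a fixed step (2 ms by default).  Noise
``xi_t`` is one standard-normal draw per macrocolumn per step, broadcast
to member minicolumns and scaled by the coupling B at the point of use
(no sqrt-dt rescaling: B is a per-step kick by convention, tied to the
default step).  Basal drives can be ramped in time over spatial masks,
stimuli can inject input pulses or reset the E state, and network terms
can optionally be carried over distance-dependent propagation delays.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp

from .connectivity import ConnectivityModel
from .geometry import SheetGeometry
from .params import UnitParams
from .unit import sigmoid


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Per-macrocolumn shared standard-normal noise."""

    coupling: float = 0.3
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.coupling < 0:
            raise ValueError("noise coupling must be non-negative")


@dataclasses.dataclass(frozen=True)
class RampSpec:
    """Linear ramp of a parameter between ``t_start`` and ``t_end`` (ms),
    clamped outside, over an optional spatial mask (unit indices).

    Supported parameters: ``p_basal``, ``q_basal``, ``ffe_scale`` and
    ``ffi_scale`` (multiplicative scale on incoming off-diagonal E->E /
    E->I network input; 1 = unscaled).
    """

    parameter: str
    start: float
    end: float
    t_start: float
    t_end: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.t_start > self.t_end:
            raise ValueError("t_start must not exceed t_end")
        if self.parameter not in ("p_basal", "q_basal", "ffe_scale", "ffi_scale"):
            raise ValueError(f"unknown ramp parameter {self.parameter!r}")

    def value(self, t: float) -> float:
        if t <= self.t_start:
            return self.start
        if t >= self.t_end or self.t_end == self.t_start:
            return self.end
        frac = (t - self.t_start) / (self.t_end - self.t_start)
        return self.start + frac * (self.end - self.start)


@dataclasses.dataclass(frozen=True)
class StimulusSpec:
    """Input pulse (adds ``amplitude`` to the E input for ``duration`` ms)
    or instantaneous state reset (sets u to ``amplitude`` once, after the
    step at ``onset``)."""

    kind: str
    mask: np.ndarray
    amplitude: float
    onset: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("input_pulse", "state_reset"):
            raise ValueError("stimulus kind must be 'input_pulse' or 'state_reset'")
        if len(np.atleast_1d(self.mask)) == 0:
            raise ValueError("stimulus mask must be nonempty")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")


class HeterogeneityMap:
    """Per-unit overrides of unit parameters.

    Overrides are applied to the per-unit base arrays before simulation:
    ``set_absolute`` replaces the value inside the mask, ``set_scale``
    multiplies it.  Supported fields: ``p_basal``, ``q_basal``,
    ``noise_coupling``, ``ffe_scale``, ``ffi_scale``.
    """

    FIELDS = ("p_basal", "q_basal", "noise_coupling", "ffe_scale", "ffi_scale")

    def __init__(self) -> None:
        self._ops: list[tuple[str, str, np.ndarray, float]] = []

    def set_absolute(self, field: str, mask, value: float) -> "HeterogeneityMap":
        self._check(field)
        self._ops.append((field, "abs", np.atleast_1d(np.asarray(mask)), float(value)))
        return self

    def set_scale(self, field: str, mask, factor: float) -> "HeterogeneityMap":
        self._check(field)
        self._ops.append((field, "scale", np.atleast_1d(np.asarray(mask)), float(factor)))
        return self

    def _check(self, field: str) -> None:
        if field not in self.FIELDS:
            raise ValueError(f"unknown heterogeneity field {field!r}")

    def apply(self, arrays: dict[str, np.ndarray], n_units: int) -> None:
        for field, mode, mask, value in self._ops:
            if mask.max(initial=-1) >= n_units or mask.min(initial=0) < 0:
                raise ValueError("heterogeneity mask outside sheet")
            if mode == "abs":
                arrays[field][mask] = value
            else:
                arrays[field][mask] *= value


@dataclasses.dataclass
class SimulationResult:
    """Recorded sheet trajectory plus macrocolumn reductions."""

    t: np.ndarray                  # recorded times, ms
    u: np.ndarray                  # (n_samples, n_units) E activity
    v: np.ndarray                  # (n_samples, n_units) I activity
    geometry: SheetGeometry
    dt: float
    noise: NoiseSpec
    schedule: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape or self.u.shape[0] != len(self.t):
            raise ValueError("inconsistent result array shapes")

    @property
    def macro_u(self) -> np.ndarray:
        return _macro_average(self.u, self.geometry)

    @property
    def macro_v(self) -> np.ndarray:
        return _macro_average(self.v, self.geometry)

    @property
    def lfp(self) -> np.ndarray:
        return compute_lfp(self)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("t", data=self.t)
            fh.create_dataset("u", data=self.u, compression="gzip")
            fh.create_dataset("v", data=self.v, compression="gzip")
            fh.create_dataset("lfp", data=self.lfp)
            fh.attrs["dt"] = self.dt
            fh.attrs["noise_coupling"] = self.noise.coupling
            fh.attrs["noise_seed"] = -1 if self.noise.seed is None else self.noise.seed
            g = self.geometry
            fh.attrs["geometry"] = f"{g.n_rows}x{g.n_cols}/me{g.macro_edge}/p{g.pitch_um}/{g.boundary}"
            fh.attrs["schedule"] = repr(self.schedule)

    @classmethod
    def load(cls, path: str | Path, geometry: SheetGeometry) -> "SimulationResult":
        with h5py.File(path, "r") as fh:
            seed = int(fh.attrs["noise_seed"])
            return cls(
                t=fh["t"][:], u=fh["u"][:], v=fh["v"][:], geometry=geometry,
                dt=float(fh.attrs["dt"]),
                noise=NoiseSpec(float(fh.attrs["noise_coupling"]), None if seed < 0 else seed),
            )

    def export_macro_csv(self, path: str | Path, every: int = 1) -> None:
        import pandas as pd

        lfp = self.lfp[::every]
        df = pd.DataFrame(lfp, columns=[f"macro_{i}" for i in range(lfp.shape[1])])
        df.insert(0, "t_ms", self.t[::every])
        df.to_csv(path, index=False)


def _macro_average(x: np.ndarray, geom: SheetGeometry) -> np.ndarray:
    macro = geom.macro_of_unit
    sums = np.zeros((x.shape[0], geom.n_macros), dtype=float)
    counts = np.bincount(macro, minlength=geom.n_macros).astype(float)
    for m in range(geom.n_macros):
        sums[:, m] = x[:, macro == m].sum(axis=1)
    return sums / counts


def generate_noise(geom: SheetGeometry, spec: NoiseSpec, n_steps: int) -> np.ndarray:
    """(n_steps, n_units) array of unit-variance noise, identical within
    each macrocolumn, drawn exactly as the integrator draws it."""
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(spec.seed)
    macro = geom.macro_of_unit
    out = np.empty((n_steps, geom.n_units))
    for k in range(n_steps):
        out[k] = rng.standard_normal(geom.n_macros)[macro]
    return out


def _delay_split(w: sp.csr_matrix, geom: SheetGeometry, delay_speed: float, dt: float,
                 n_steps: int):
    """Split the off-diagonal part of ``w`` into per-delay-step matrices.

    Distances are binned at one pitch; the delay of a bin is
    ``round(distance / (speed * dt))`` steps.
    """
    m = w.tocoo()
    off = m.row != m.col
    dist = geom.distance_um(m.row[off], m.col[off])
    binned = np.round(dist / geom.pitch_um) * geom.pitch_um
    steps = np.round(binned / (delay_speed * dt)).astype(int)
    max_delay = int(steps.max(initial=0))
    if max_delay >= n_steps:
        raise ValueError(
            f"delay buffer ({max_delay} steps) longer than simulation ({n_steps} steps)"
        )
    groups = []
    r, c, d = m.row[off], m.col[off], m.data[off]
    for k in np.unique(steps):
        sel = steps == k
        groups.append((int(k), sp.csr_matrix((d[sel], (r[sel], c[sel])), shape=w.shape)))
    return groups, max_delay


def simulate_sheet(
    model: ConnectivityModel,
    globals_: UnitParams,
    het: HeterogeneityMap | None = None,
    ramps: tuple[RampSpec, ...] = (),
    stimuli: tuple[StimulusSpec, ...] = (),
    noise: NoiseSpec | None = None,
    duration: float = 10000.0,
    dt: float = 2.0,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    delay_speed: float | None = None,
    record_every: int = 1,
) -> SimulationResult:
    """Integrate the full sheet and return the recorded trajectory.

    ``delay_speed`` is a signal propagation speed in um/ms; ``None`` (or
    ``inf``) means instantaneous network interaction.  ``record_every``
    thins the recorded samples (the integration step is unaffected).
    The output is fully determined by (connectivity, noise seed,
    schedule).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    geom = model.geometry
    n = geom.n_units
    if noise is None:
        noise = NoiseSpec(coupling=globals_.noise_coupling)
    if dt > min(globals_.tau_e, globals_.tau_i):
        warnings.warn("dt exceeds the smallest time constant; states may leave [0,1]",
                      RuntimeWarning, stacklevel=2)

    # per-unit base arrays
    arrays = {
        "p_basal": np.full(n, globals_.p_basal),
        "q_basal": np.full(n, globals_.q_basal),
        "noise_coupling": np.full(n, noise.coupling),
        "ffe_scale": np.ones(n),
        "ffi_scale": np.ones(n),
    }
    if het is not None:
        het.apply(arrays, n)

    diag_ee = np.asarray(model.w_ee.diagonal())
    diag_ei = np.asarray(model.w_ei.diagonal())
    c_ie = np.asarray(model.w_ie.diagonal())
    c_ii = np.asarray(model.w_ii.diagonal())
    off_ee = (model.w_ee - sp.diags(diag_ee)).tocsr()
    off_ei = (model.w_ei - sp.diags(diag_ei)).tocsr()

    n_steps = int(round(duration / dt))
    use_delays = delay_speed is not None and np.isfinite(delay_speed)
    if use_delays:
        if delay_speed <= 0:
            raise ValueError("delay_speed must be positive")
        ee_groups, dmax_e = _delay_split(off_ee, geom, delay_speed, dt, n_steps)
        ei_groups, dmax_i = _delay_split(off_ei, geom, delay_speed, dt, n_steps)
        hist_len = max(dmax_e, dmax_i) + 1
        u_hist = np.zeros((hist_len, n))

    if init is None:
        u = np.zeros(n)
        v = np.zeros(n)
    else:
        u = np.array(init[0], dtype=float)
        v = np.array(init[1], dtype=float)
    if use_delays:
        u_hist[:] = u  # history initialised at the initial state

    rng = np.random.default_rng(noise.seed)
    macro = geom.macro_of_unit
    n_macros = geom.n_macros
    sig = globals_.sigmoid

    n_rec = n_steps // record_every + 1
    rec_t = np.empty(n_rec)
    rec_u = np.empty((n_rec, n), dtype=np.float32)
    rec_v = np.empty((n_rec, n), dtype=np.float32)
    rec_t[0], rec_u[0], rec_v[0] = 0.0, u, v
    ptr = 1

    resets_done = [False] * len(stimuli)
    tau_e, tau_i = globals_.tau_e, globals_.tau_i

    for k in range(n_steps):
        t = k * dt
        P = arrays["p_basal"]
        Q = arrays["q_basal"]
        ffe = arrays["ffe_scale"]
        ffi = arrays["ffi_scale"]
        if ramps:
            P = P.copy(); Q = Q.copy(); ffe = ffe.copy(); ffi = ffi.copy()
            tgt = {"p_basal": P, "q_basal": Q, "ffe_scale": ffe, "ffi_scale": ffi}
            for ramp in ramps:
                arr = tgt[ramp.parameter]
                val = ramp.value(t)
                if ramp.mask is None:
                    arr[:] = val
                else:
                    arr[ramp.mask] = val

        if use_delays:
            e_net = np.zeros(n)
            for delay, mat in ee_groups:
                e_net += mat @ u_hist[(k - delay) % hist_len]
            i_net = np.zeros(n)
            for delay, mat in ei_groups:
                i_net += mat @ u_hist[(k - delay) % hist_len]
        else:
            e_net = off_ee @ u
            i_net = off_ei @ u

        xi = rng.standard_normal(n_macros)[macro]
        e_in = ffe * e_net + diag_ee * u - c_ie * v + P + arrays["noise_coupling"] * xi
        i_in = ffi * i_net + diag_ei * u - c_ii * v + Q

        for st in stimuli:
            if st.kind == "input_pulse" and st.onset <= t < st.onset + st.duration:
                e_in[st.mask] += st.amplitude

        u = u + dt * (-u + sigmoid(e_in, sig)) / tau_e
        v = v + dt * (-v + sigmoid(i_in, sig)) / tau_i

        for idx, st in enumerate(stimuli):
            if st.kind == "state_reset" and not resets_done[idx] and t + dt > st.onset:
                u[st.mask] = st.amplitude
                resets_done[idx] = True

        if use_delays:
            u_hist[(k + 1) % hist_len] = u

        if (k + 1) % record_every == 0:
            rec_t[ptr] = (k + 1) * dt
            rec_u[ptr] = u
            rec_v[ptr] = v
            ptr += 1

    schedule = {
        "ramps": [dataclasses.asdict(r) for r in ramps],
        "stimuli": [dataclasses.asdict(s) for s in stimuli],
        "delay_speed": delay_speed,
        "duration": duration,
        "record_every": record_every,
    }
    return SimulationResult(rec_t[:ptr], rec_u[:ptr], rec_v[:ptr], geom, dt, noise, schedule)


def compute_lfp(result: SimulationResult, mode: str = "e_activity") -> np.ndarray:
    """Macrocolumn-averaged LFP proxy, (n_samples, n_macros).

    ``e_activity`` (default) averages the E firing fraction per
    macrocolumn; ``net_input`` averages ``u - v`` as a crude net synaptic
    drive proxy.  The choice is purely a readout convention.
    """
    if mode == "e_activity":
        return _macro_average(result.u, result.geometry)
    if mode == "net_input":
        return _macro_average(result.u - result.v, result.geometry)
    raise ValueError(f"unknown LFP mode {mode!r}")


def stimulus_threshold_probe(
    model: ConnectivityModel,
    globals_: UnitParams,
    probe_mask: np.ndarray,
    response_criterion,
    bracket: tuple[float, float],
    het: HeterogeneityMap | None = None,
    noise_seed: int = 0,
    duration: float = 3000.0,
    onset: float = 500.0,
    pulse_duration: float = 100.0,
    dt: float = 2.0,
    max_iter: int = 20,
    rel_tol: float = 1e-2,
):
    """Minimal pulse amplitude satisfying ``response_criterion``.

    The amplitude-to-response map is made deterministic by freezing the
    noise seed, then bisected.  Returns the threshold, or the string
    ``"no threshold in range"`` when the bracket does not straddle the
    criterion.
    """

    def respond(amp: float) -> bool:
        stim = StimulusSpec("input_pulse", probe_mask, amp, onset, pulse_duration)
        res = simulate_sheet(
            model, globals_, het=het, stimuli=(stim,),
            noise=NoiseSpec(globals_.noise_coupling, noise_seed),
            duration=duration, dt=dt,
        )
        return bool(response_criterion(res))

    lo, hi = bracket
    if respond(lo) or not respond(hi):
        return "no threshold in range"
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if respond(mid):
            hi = mid
        else:
            lo = mid
        if hi - lo <= rel_tol * abs(hi):
            break
    return 0.5 * (lo + hi)


def lfp_excursion_criterion(threshold: float, after: float = 0.0):
    """Response criterion: any macrocolumn LFP exceeds ``threshold`` after
    time ``after`` (ms)."""

    def crit(result: SimulationResult) -> bool:
        sel = result.t >= after
        return bool(np.any(result.lfp[sel] > threshold))

    return crit
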