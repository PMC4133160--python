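"""Seizure-core detection, recruitment metrics and scan experiments.

A unit counts as recruited when a sliding analysis window of its E
activity shows several full oscillation cycles above an amplitude
threshold while being phase-coherent with its spatial neighbourhood —
the operational definition of the "seizure core" as high-amplitude
synchronous oscillation over connected tissue.  On top of the per-unit
detector sit the wavefront-speed estimator (robust onset-time versus
distance regression), the random subcluster placement used by the
microdomain-network experiments, and the scan drivers.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage
from scipy.signal import hilbert
from scipy.stats import theilslopes

from .connectivity import ConnectivityModel
from .geometry import SheetGeometry
from .params import UnitParams
from .simulator import (
    HeterogeneityMap,
    NoiseSpec,
    RampSpec,
    SimulationResult,
    StimulusSpec,
    simulate_sheet,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DetectorSettings:
    """Sliding-window recruitment detector configuration."""

    amp_threshold: float = 0.1       # peak-to-trough, fractional firing units
    min_cycles: int = 3              # full cycles required inside the window
    sync_radius: float = 3.0         # lattice radius of the coherence neighbourhood
    coherence_threshold: float = 0.8
    window_ms: float = 1000.0
    cadence_ms: float = 300.0        # report cadence for the fraction time course


@dataclasses.dataclass
class RecruitmentReport:
    recruited: np.ndarray           # bool per unit: criteria met in the final window
    onset_ms: np.ndarray            # first window start meeting criteria, NaN if never
    times_ms: np.ndarray            # window start times of the fraction course
    fraction_course: np.ndarray     # cumulative fraction with onset <= t
    final_percent: float            # % of units recruited in the final window
    settings: DetectorSettings
    seed_info: dict = dataclasses.field(default_factory=dict)

    def percent_of(self, mask: np.ndarray) -> float:
        """Recruited percentage restricted to ``mask`` (e.g. the surround
        of a microdomain)."""
        return 100.0 * float(self.recruited[mask].mean()) if len(mask) else 0.0


def _neighbour_phase(phase: np.ndarray, geom: SheetGeometry, radius: float) -> np.ndarray:
    """Circular-mean phase of each unit's neighbourhood, per frame."""
    rad = int(np.floor(radius))
    size = 2 * rad + 1
    ker = np.zeros((size, size))
    for dx in range(-rad, rad + 1):
        for dy in range(-rad, rad + 1):
            if np.hypot(dx, dy) <= radius:
                ker[dx + rad, dy + rad] = 1.0
    mode = "wrap" if geom.boundary == "torus" else "constant"
    z = np.exp(1j * phase).reshape(phase.shape[0], geom.n_rows, geom.n_cols)
    out = np.empty_like(z)
    for k in range(z.shape[0]):
        re = ndimage.convolve(z[k].real, ker, mode=mode)
        im = ndimage.convolve(z[k].imag, ker, mode=mode)
        out[k] = re + 1j * im
    return np.angle(out).reshape(phase.shape)


def detect_recruited_units(
    result: SimulationResult,
    settings: DetectorSettings | None = None,
) -> RecruitmentReport:
    """Apply the sliding-window seizure-core detector to a simulation.

    Criteria per unit and window: at least ``min_cycles`` mean-crossing
    cycles, peak-to-trough above ``amp_threshold``, and mean phase
    coherence with the neighbourhood above ``coherence_threshold``.
    """
    st = settings or DetectorSettings()
    t = result.t
    if len(t) < 2:
        raise ValueError("result too short")
    dt_s = float(t[1] - t[0])
    n_win = int(round(st.window_ms / dt_s))
    stride = max(1, int(round(st.cadence_ms / dt_s)))
    n_samp, n_units = result.u.shape
    if n_win > n_samp:
        raise ValueError("detector window longer than the simulation")

    u = np.asarray(result.u, dtype=np.float32)
    # analytic phase of the demeaned signal
    phase = np.angle(hilbert(u - u.mean(axis=0, keepdims=True), axis=0))
    nb_phase = _neighbour_phase(phase, result.geometry, st.sync_radius)
    dphi = np.cos(phase - nb_phase)  # Re e^{i(phi - psi)}; |mean| approx by mean cos

    starts = np.arange(0, n_samp - n_win + 1, stride)
    onset = np.full(n_units, np.nan)
    final_mask = np.zeros(n_units, dtype=bool)
    frac = np.empty(len(starts))
    for w, s0 in enumerate(starts):
        seg = u[s0 : s0 + n_win]
        amp = seg.max(axis=0) - seg.min(axis=0)
        centered = np.signbit(seg - seg.mean(axis=0, keepdims=True))
        crossings = (centered[1:] != centered[:-1]).sum(axis=0)
        cycles = crossings / 2.0
        coh = dphi[s0 : s0 + n_win].mean(axis=0)
        ok = (amp > st.amp_threshold) & (cycles >= st.min_cycles) & (coh > st.coherence_threshold)
        newly = ok & np.isnan(onset)
        onset[newly] = t[s0]
        frac[w] = np.mean(~np.isnan(onset))
        if w == len(starts) - 1:
            final_mask = ok
    return RecruitmentReport(
        recruited=final_mask,
        onset_ms=onset,
        times_ms=t[starts],
        fraction_course=frac,
        final_percent=100.0 * float(final_mask.mean()),
        settings=st,
        seed_info={"noise_seed": result.noise.seed},
    )


# ---------------------------------------------------------------------------
# wavefront speed


def estimate_wavefront_speed(
    report: RecruitmentReport,
    geom: SheetGeometry,
    seed_region: np.ndarray,
    min_units: int = 20,
):
    """Recruitment wavefront speed in m/s from onset times.

    Fits onset time against distance from the seed region with a
    Theil-Sen robust slope (resistant to the early remote-connection
    "jump" outliers); speed is the inverse slope.  Returns a dict with
    ``speed_m_per_s``, ``r_squared`` and ``residual_ms``; degenerate
    onset fields yield ``{"speed": "undefined", ...}``.
    """
    seed_mask = np.zeros(geom.n_units, dtype=bool)
    seed_mask[seed_region] = True
    grid = (~seed_mask).reshape(geom.n_rows, geom.n_cols)
    dist_units = ndimage.distance_transform_edt(grid)
    if geom.boundary == "torus":
        # minimal image: transform a 3x3 tiling and take the central block
        tiled = np.tile(grid, (3, 3))
        d = ndimage.distance_transform_edt(tiled)
        dist_units = d[geom.n_rows : 2 * geom.n_rows, geom.n_cols : 2 * geom.n_cols]
    dist_um = dist_units.ravel() * geom.pitch_um

    sel = ~seed_mask & ~np.isnan(report.onset_ms)
    if sel.sum() < min_units:
        raise ValueError(
            f"need >= {min_units} recruited units outside the seed region, got {int(sel.sum())}"
        )
    x = dist_um[sel]
    y = report.onset_ms[sel]
    if np.ptp(y) < 1e-9 or np.ptp(x) < 1e-9:
        return {"speed": "undefined", "reason": "degenerate onset field",
                "n_units": int(sel.sum())}
    slope, intercept, lo, hi = theilslopes(y, x)
    if slope <= 0:
        return {"speed": "undefined", "reason": "non-positive slope",
                "slope_ms_per_um": float(slope), "n_units": int(sel.sum())}
    pred = intercept + slope * x
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    speed_um_per_ms = 1.0 / slope
    return {
        "speed_m_per_s": speed_um_per_ms * 1e-3,
        "slope_ms_per_um": float(slope),
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0,
        "residual_ms": float(np.median(np.abs(y - pred))),
        "n_units": int(sel.sum()),
    }


# ---------------------------------------------------------------------------
# subcluster placement


@dataclasses.dataclass
class ClusterLayout:
    total_units: int
    n_subclusters: int
    members: list[np.ndarray]
    placement_seed: int

    @property
    def all_units(self) -> np.ndarray:
        return np.concatenate(self.members) if self.members else np.empty(0, dtype=int)


def _quasi_disc(geom: SheetGeometry, center: int, size: int) -> np.ndarray:
    """Contiguous quasi-disc of exactly ``size`` units grown around a
    center by increasing lattice distance (ties broken by index)."""
    r0, c0 = geom.unit_coords(center)
    dr = np.abs(geom.rows - r0)
    dc = np.abs(geom.cols - c0)
    if geom.boundary == "torus":
        dr = np.minimum(dr, geom.n_rows - dr)
        dc = np.minimum(dc, geom.n_cols - dc)
    d2 = dr * dr + dc * dc
    order = np.argsort(d2, kind="stable")
    return np.sort(order[:size])


def place_subclusters(
    geom: SheetGeometry,
    total_units: int,
    n_subclusters: int,
    placement_seed: int,
    max_retries: int = 200,
) -> ClusterLayout:
    """Randomly place ``n_subclusters`` disjoint contiguous quasi-discs
    whose sizes split ``total_units`` as evenly as possible.

    Overlaps are resolved by redrawing the center (never by shrinking),
    so the stated sizes are exact; exhausting the retry budget raises.
    """
    if total_units > geom.n_units:
        raise ValueError("more hyperactive units than sheet units")
    if n_subclusters > total_units:
        raise ValueError("more subclusters than units")
    rng = np.random.default_rng(placement_seed)
    base, extra = divmod(total_units, n_subclusters)
    sizes = [base + (1 if i < extra else 0) for i in range(n_subclusters)]
    taken = np.zeros(geom.n_units, dtype=bool)
    members: list[np.ndarray] = []
    for size in sizes:
        for attempt in range(max_retries):
            center = int(rng.integers(geom.n_units))
            disc = _quasi_disc(geom, center, size)
            if not taken[disc].any():
                members.append(disc)
                taken[disc] = True
                break
        else:
            raise RuntimeError(
                f"could not place disjoint subcluster of {size} units within "
                f"{max_retries} retries"
            )
    return ClusterLayout(total_units, n_subclusters, members, placement_seed)


# ---------------------------------------------------------------------------
# scan driver

SCAN_TEMPLATES = (
    "pulse_stimulus",
    "oscillatory_microdomain",
    "subcluster_network",
    "bistable_microdomain_probe",
)


@dataclasses.dataclass(frozen=True)
class ScanSpec:
    """Declarative recruitment-scan specification.

    ``template`` selects the scenario built per grid cell; ``axis_x`` and
    ``axis_y`` are (name, values) pairs whose meaning depends on the
    template (documented in :func:`run_recruitment_scan`).
    """

    template: str
    axis_x: tuple[str, tuple]
    axis_y: tuple[str, tuple]
    trials: int = 1
    duration_ms: float = 6000.0
    ramp_window_ms: tuple[float, float] = (500.0, 2000.0)
    microdomain_p: float = -1.0
    surround_p: float | None = None
    pulse_amplitude: float = 10.0
    pulse_duration_ms: float = 100.0
    base_seed: int = 0
    detector: DetectorSettings = dataclasses.field(default_factory=DetectorSettings)

    def __post_init__(self) -> None:
        if self.template not in SCAN_TEMPLATES:
            raise ValueError(f"template must be one of {SCAN_TEMPLATES}")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")


@dataclasses.dataclass
class ScanResult:
    spec: ScanSpec
    x_values: np.ndarray
    y_values: np.ndarray
    mean: np.ndarray                # (len(y), len(x)) mean recruited % of surround
    dispersion: np.ndarray          # max-min over trials (0 where trials == 1)
    labels: np.ndarray | None = None  # for the bistable-probe template
    failures: list = dataclasses.field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for j, y in enumerate(self.y_values):
            for i, x in enumerate(self.x_values):
                rows.append(
                    (x, y, self.mean[j, i], self.dispersion[j, i],
                     None if self.labels is None else self.labels[j, i])
                )
        return pd.DataFrame(
            rows, columns=[self.spec.axis_x[0], self.spec.axis_y[0], "mean", "dispersion", "label"]
        )

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def render(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        pc = ax.pcolormesh(self.x_values, self.y_values, self.mean, shading="nearest",
                           cmap="viridis")
        fig.colorbar(pc, ax=ax, label="recruited %")
        ax.set_xlabel(self.spec.axis_x[0])
        ax.set_ylabel(self.spec.axis_y[0])
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _md_ramp(mask: np.ndarray, p_from: float, p_to: float, window) -> RampSpec:
    return RampSpec("p_basal", p_from, p_to, window[0], window[1], mask=mask)


def run_recruitment_scan(
    model: ConnectivityModel,
    globals_: UnitParams,
    spec: ScanSpec,
) -> ScanResult:
    """Run a recruitment scan over a 2-D grid of scenario settings.

    Templates (axis interpretation):

    * ``pulse_stimulus``: x = stimulated-unit count, y = surround
      ``p_basal``; a central contiguous patch receives an input pulse.
    * ``oscillatory_microdomain``: x = microdomain unit count, y =
      surround ``p_basal``; the central microdomain's drive is ramped to
      ``microdomain_p``.  Recruitment is reported for the surround.
    * ``subcluster_network``: x = number of subclusters, y = total
      hyperactive units; surround at ``surround_p`` (or the globals'
      drive); placements re-randomised per trial.
    * ``bistable_microdomain_probe``: x = microdomain unit count, y =
      microdomain ``p_basal``; the microdomain is classified as
      monostable-background / bistable / monostable-oscillatory by a
      local two-initial-condition probe instead of the detector.

    Per cell, ``trials`` runs with distinct noise seeds (and placements)
    are aggregated into a mean and a dispersion (max - min).
    """
    geom = model.geometry
    xs = np.asarray(spec.axis_x[1], dtype=float)
    ys = np.asarray(spec.axis_y[1], dtype=float)
    mean = np.zeros((len(ys), len(xs)))
    disp = np.zeros_like(mean)
    labels = np.empty((len(ys), len(xs)), dtype=object) if spec.template == "bistable_microdomain_probe" else None
    failures: list = []
    center = geom.unit_index(geom.n_rows // 2, geom.n_cols // 2)

    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            vals = []
            cell_labels = []
            for trial in range(spec.trials):
                seed = spec.base_seed + 1000 * trial + 17 * i + 311 * j
                try:
                    vals_or_label = _run_scan_cell(model, globals_, spec, geom, center, x, y, seed, trial)
                except Exception as exc:  # pragma: no cover - defensive
                    failures.append({"x": x, "y": y, "trial": trial, "error": str(exc)})
                    logger.warning("scan cell (%s, %s) trial %d failed: %s", x, y, trial, exc)
                    continue
                if isinstance(vals_or_label, str):
                    cell_labels.append(vals_or_label)
                else:
                    vals.append(vals_or_label)
            if labels is not None:
                # majority label across trials
                labs = cell_labels or ["failed"]
                labels[j, i] = max(set(labs), key=labs.count)
            if vals:
                mean[j, i] = float(np.mean(vals))
                disp[j, i] = float(np.max(vals) - np.min(vals))
    return ScanResult(spec, xs, ys, mean, disp, labels, failures)


def _probe_microdomain_state(model, params, md, p_md, spec, seed) -> str:
    """Two-initial-condition probe of a microdomain's local regime."""
    het = HeterogeneityMap().set_absolute("p_basal", md, p_md)
    out = []
    for excited in (False, True):
        stim = (StimulusSpec("state_reset", md, 1.0, 0.0),) if excited else ()
        res = simulate_sheet(
            model, params, het=het, stimuli=stim,
            noise=NoiseSpec(params.noise_coupling, seed),
            duration=spec.duration_ms, dt=2.0, record_every=2,
        )
        sig = res.u[:, md].mean(axis=1)
        tail = sig[len(sig) // 3:]
        out.append(np.ptp(tail) > spec.detector.amp_threshold)
    rest_osc, excited_osc = out
    if rest_osc:
        return "monostable_oscillatory"
    return "bistable" if excited_osc else "monostable_background"


def _run_scan_cell(model, globals_, spec, geom, center, x, y, seed, trial):
    if spec.template == "bistable_microdomain_probe":
        md = _quasi_disc(geom, center, int(x))
        return _probe_microdomain_state(model, globals_, md, float(y), spec, seed)

    if spec.template == "pulse_stimulus":
        params = globals_.replace(p_basal=float(y))
        mask = _quasi_disc(geom, center, int(x))
        stim = StimulusSpec("input_pulse", mask, spec.pulse_amplitude, 1000.0, spec.pulse_duration_ms)
        res = simulate_sheet(
            model, params, stimuli=(stim,),
            noise=NoiseSpec(params.noise_coupling, seed),
            duration=spec.duration_ms, dt=2.0, record_every=5,
        )
        report = detect_recruited_units(res, spec.detector)
        surround = np.setdiff1d(np.arange(geom.n_units), mask)
        return report.percent_of(surround)

    if spec.template == "oscillatory_microdomain":
        params = globals_.replace(p_basal=float(y))
        md = _quasi_disc(geom, center, int(x))
        ramp = _md_ramp(md, float(y), spec.microdomain_p, spec.ramp_window_ms)
        res = simulate_sheet(
            model, params, ramps=(ramp,),
            noise=NoiseSpec(params.noise_coupling, seed),
            duration=spec.duration_ms, dt=2.0, record_every=5,
        )
        report = detect_recruited_units(res, spec.detector)
        surround = np.setdiff1d(np.arange(geom.n_units), md)
        return report.percent_of(surround)

    if spec.template == "subcluster_network":
        p_surr = globals_.p_basal if spec.surround_p is None else spec.surround_p
        params = globals_.replace(p_basal=p_surr)
        layout = place_subclusters(geom, int(y), int(x), placement_seed=seed + 7)
        md = layout.all_units
        ramp = _md_ramp(md, p_surr, spec.microdomain_p, spec.ramp_window_ms)
        res = simulate_sheet(
            model, params, ramps=(ramp,),
            noise=NoiseSpec(params.noise_coupling, seed),
            duration=spec.duration_ms, dt=2.0, record_every=5,
        )
        report = detect_recruited_units(res, spec.detector)
        surround = np.setdiff1d(np.arange(geom.n_units), md)
        return report.percent_of(surround)

    raise ValueError(f"unknown template {spec.template}")
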