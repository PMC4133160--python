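"""Operational classification of the sheet's mean-field dynamics.

Four regimes are distinguished by a two-run probe protocol: run A starts
from the resting background state, run B from a strongly excited state
(all E activity reset to 1).  Each run's post-transient mean field is
labelled oscillatory / background / upper-steady, and the pair maps to

    A background, B background  -> monostable_background
    A background, B oscillatory -> bistable_background_oscillation
    both oscillatory            -> monostable_oscillation
    A background, B upper       -> bistable_background_upper

Any other combination is reported as ``unresolved`` rather than coerced.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
from scipy import signal as spsignal

from .connectivity import ConnectivityModel
from .params import UnitParams
from .simulator import HeterogeneityMap, NoiseSpec, StimulusSpec, simulate_sheet

logger = logging.getLogger(__name__)

REGIME_LABELS = (
    "monostable_background",
    "bistable_background_oscillation",
    "monostable_oscillation",
    "bistable_background_upper",
    "unresolved",
)


@dataclasses.dataclass(frozen=True)
class OscillationMetrics:
    amplitude: float            # peak-to-trough over the analysis window
    frequency_hz: float         # dominant spectral frequency
    regularity: float           # fraction of spectral power at the peak

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.frequency_hz < 0:
            raise ValueError("amplitude and frequency must be non-negative")


@dataclasses.dataclass(frozen=True)
class RegimeProbe:
    """Probe settings for the two-run classification protocol."""

    duration: float = 4000.0       # ms per run
    dt: float = 2.0
    noise_seed: int = 0
    amp_threshold: float = 0.1     # fractional-firing units on the mean-E signal
    freq_band: tuple[float, float] = (1.0, 30.0)
    upper_mean: float = 0.8        # mean u above this (and no oscillation) = upper state
    transient_fraction: float = 0.2


def detect_oscillation(
    ts: np.ndarray,
    dt_ms: float,
    window_ms: float | None = None,
    amp_threshold: float = 0.1,
    freq_band: tuple[float, float] = (1.0, 30.0),
    transient_fraction: float = 0.2,
) -> tuple[bool, OscillationMetrics]:
    """Detect a sustained oscillation in a scalar time series.

    True iff the peak-to-trough amplitude over the post-transient
    analysis window exceeds ``amp_threshold`` and the dominant frequency
    falls inside ``freq_band``.  Metrics are returned either way.
    """
    ts = np.asarray(ts, dtype=float)
    n0 = int(len(ts) * transient_fraction)
    seg = ts[n0:]
    if window_ms is not None:
        n_win = int(window_ms / dt_ms)
        if n_win > len(ts):
            raise ValueError("analysis window longer than the series")
        seg = seg[-n_win:] if n_win <= len(seg) else ts[-n_win:]
    if len(seg) < 4:
        raise ValueError("series too short to analyse")
    amplitude = float(seg.max() - seg.min())
    freqs, power = spsignal.periodogram(seg - seg.mean(), fs=1000.0 / dt_ms)
    if power.sum() > 0:
        k = int(np.argmax(power))
        freq = float(freqs[k])
        regularity = float(power[k] / power.sum())
    else:
        freq, regularity = 0.0, 0.0
    ok = amplitude > amp_threshold and freq_band[0] <= freq <= freq_band[1]
    return ok, OscillationMetrics(amplitude, freq, regularity)


def _label_run(mean_e: np.ndarray, probe: RegimeProbe) -> str:
    osc, _ = detect_oscillation(
        mean_e, probe.dt,
        amp_threshold=probe.amp_threshold,
        freq_band=probe.freq_band,
        transient_fraction=probe.transient_fraction,
    )
    if osc:
        return "oscillatory"
    tail = mean_e[int(len(mean_e) * probe.transient_fraction):]
    return "upper" if tail.mean() > probe.upper_mean else "background"


def classify_regime(
    model: ConnectivityModel,
    globals_: UnitParams,
    probe: RegimeProbe | None = None,
    het: HeterogeneityMap | None = None,
) -> str:
    """Classify the sheet's mean-field regime with the two-run protocol."""
    probe = probe or RegimeProbe()
    n = model.geometry.n_units
    labels = []
    for excited in (False, True):
        stimuli = ()
        if excited:
            stimuli = (StimulusSpec("state_reset", np.arange(n), 1.0, 0.0),)
        res = simulate_sheet(
            model, globals_, het=het, stimuli=stimuli,
            noise=NoiseSpec(globals_.noise_coupling, probe.noise_seed),
            duration=probe.duration, dt=probe.dt,
        )
        labels.append(_label_run(res.u.mean(axis=1), probe))
    a, b = labels
    table = {
        ("background", "background"): "monostable_background",
        ("background", "oscillatory"): "bistable_background_oscillation",
        ("oscillatory", "oscillatory"): "monostable_oscillation",
        ("background", "upper"): "bistable_background_upper",
        ("upper", "upper"): "monostable_background",  # degenerate: both runs pinned high
    }
    label = table.get((a, b), "unresolved")
    if label == "unresolved":
        logger.warning("inconsistent probe outcome: rest -> %s, excited -> %s", a, b)
    if (a, b) == ("upper", "upper"):
        label = "unresolved"
        logger.warning("both probe runs settle in the upper state; labelling unresolved")
    return label


@dataclasses.dataclass
class RegimeMap:
    """2-D regime scan over two parameter axes."""

    axis_x: str
    axis_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    labels: np.ndarray                 # (len(y), len(x)) of label strings
    probe: RegimeProbe
    metadata: dict = dataclasses.field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        rows = [
            (x, y, self.labels[j, i])
            for j, y in enumerate(self.y_values)
            for i, x in enumerate(self.x_values)
        ]
        return pd.DataFrame(rows, columns=[self.axis_x, self.axis_y, "label"])

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def render(self, path) -> None:
        """Raster with the conventional colour semantics (black background,
        light blue bistable, dark blue oscillatory, yellow upper)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        order = list(REGIME_LABELS)
        idx = np.vectorize(order.index)(self.labels)
        cmap = ListedColormap(["black", "#7fc4ff", "#00268f", "#e8d44d", "#999999"])
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.pcolormesh(self.x_values, self.y_values, idx, cmap=cmap, vmin=0, vmax=4,
                      shading="nearest")
        ax.set_xlabel(self.axis_x)
        ax.set_ylabel(self.axis_y)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


_SCALE_AXES = ("ffe_scale", "ffi_scale")


def scan_regime_2d(
    model: ConnectivityModel,
    globals_: UnitParams,
    axis_x: tuple[str, np.ndarray],
    axis_y: tuple[str, np.ndarray],
    probe: RegimeProbe | None = None,
) -> RegimeMap:
    """Classify every point of a 2-D parameter grid.

    Axis names may be ``UnitParams`` fields (``p_basal``, ``q_basal``,
    ``c_ee``, ...) or the network-input scales ``ffe_scale``/``ffi_scale``.
    Points are independent; unresolved points carry their own label.
    """
    probe = probe or RegimeProbe()
    name_x, xs = axis_x
    name_y, ys = axis_y
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    labels = np.empty((len(ys), len(xs)), dtype=object)
    all_units = np.arange(model.geometry.n_units)
    for (j, y), (i, x) in itertools.product(enumerate(ys), enumerate(xs)):
        params = globals_
        het = HeterogeneityMap()
        used_het = False
        for name, val in ((name_x, x), (name_y, y)):
            if name in _SCALE_AXES:
                het.set_absolute(name, all_units, val)
                used_het = True
            else:
                params = params.replace(**{name: val})
        labels[j, i] = classify_regime(model, params, probe, het if used_het else None)
    g = model.geometry
    meta = {
        "sheet": f"{g.n_rows}x{g.n_cols}", "boundary": g.boundary,
        "probe": dataclasses.asdict(probe),
        "connectivity_seed": model.provenance.get("seed"),
    }
    return RegimeMap(name_x, name_y, xs, ys, labels, probe, meta)
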