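"""Seeded test fixtures: small sheets and planted-truth synthetic data.

These are first-class generators used by the test-suite and by anyone
wanting a quick, reproducible miniature of the full experiments:

* ``small_sheet`` — a reduced geometry with full three-type connectivity
  at the packaged preset parameters.
* ``planted_wavefront`` — a synthetic recruitment-onset field expanding
  at a known speed, for validating the wavefront-speed estimator.
* ``planted_oscillation`` — multichannel series with a known oscillation
  amplitude and frequency in some channels, for validating the
  oscillation and recruitment detectors.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .connectivity import ConnectivityModel, build_connectivity, ConnectivityParams
from .geometry import SheetGeometry, build_geometry
from .params import UnitParams, load_preset
from .recruitment import RecruitmentReport, DetectorSettings

FIXTURE_KINDS = ("small_sheet", "planted_wavefront", "planted_oscillation")


@dataclasses.dataclass
class SmallSheetFixture:
    geometry: SheetGeometry
    model: ConnectivityModel
    unit: UnitParams
    seed: int


@dataclasses.dataclass
class PlantedWavefront:
    geometry: SheetGeometry
    report: RecruitmentReport
    seed_region: np.ndarray
    true_speed_m_per_s: float


@dataclasses.dataclass
class PlantedOscillation:
    t_ms: np.ndarray
    series: np.ndarray          # (n_samples, n_channels)
    oscillating: np.ndarray     # bool per channel
    amplitude: float
    frequency_hz: float


def make_test_fixture(kind: str, seed: int = 0, **kw):
    """Build one of the packaged fixtures (see module docstring)."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"kind must be one of {FIXTURE_KINDS}")
    if kind == "small_sheet":
        return _small_sheet(seed, **kw)
    if kind == "planted_wavefront":
        return _planted_wavefront(seed, **kw)
    return _planted_oscillation(seed, **kw)


def _small_sheet(seed: int, n_rows: int = 30, n_cols: int = 30,
                 boundary: str = "torus", preset: str = "standard") -> SmallSheetFixture:
    cfg = load_preset(preset)
    unit = cfg["unit"]
    conn = ConnectivityParams(**cfg.get("connectivity", {}))
    # reduced patch reach so the distance bound fits the small sheet
    max_d = min(conn.max_patch_distance_um,
                (min(n_rows, n_cols) // 2) * cfg.get("geometry", {}).get("pitch_um", 50.0))
    conn = dataclasses.replace(conn, max_patch_distance_um=max_d)
    geom = build_geometry(
        n_rows, n_cols,
        macro_edge=cfg.get("geometry", {}).get("macro_edge", 10),
        pitch_um=cfg.get("geometry", {}).get("pitch_um", 50.0),
        boundary=boundary,
    )
    model = build_connectivity(geom, unit, conn, seed)
    return SmallSheetFixture(geom, model, unit, seed)


def _planted_wavefront(seed: int, n_rows: int = 30, n_cols: int = 30,
                       speed_m_per_s: float = 0.05, jitter_ms: float = 0.5) -> PlantedWavefront:
    rng = np.random.default_rng(seed)
    geom = build_geometry(n_rows, n_cols, macro_edge=min(10, n_rows), boundary="zero_flux")
    center = geom.unit_index(n_rows // 2, n_cols // 2)
    seed_region = geom.disc(center, 2)
    speed_um_per_ms = speed_m_per_s * 1e3
    dist = geom.distances_from(center) - 2 * geom.pitch_um
    dist = np.clip(dist, 0, None)
    onset = dist / speed_um_per_ms + rng.normal(0.0, jitter_ms, geom.n_units)
    onset[seed_region] = 0.0
    recruited = np.ones(geom.n_units, dtype=bool)
    times = np.arange(0.0, onset.max() + 300.0, 300.0)
    frac = np.array([(onset <= t).mean() for t in times])
    report = RecruitmentReport(
        recruited=recruited, onset_ms=onset, times_ms=times,
        fraction_course=frac, final_percent=100.0,
        settings=DetectorSettings(), seed_info={"planted_seed": seed},
    )
    return PlantedWavefront(geom, report, seed_region, speed_m_per_s)


def _planted_oscillation(seed: int, n_channels: int = 16, n_samples: int = 1000,
                         dt_ms: float = 10.0, amplitude: float = 0.3,
                         frequency_hz: float = 10.0,
                         noise_sd: float = 0.005) -> PlantedOscillation:
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) * dt_ms
    osc = np.zeros(n_channels, dtype=bool)
    osc[rng.choice(n_channels, n_channels // 2, replace=False)] = True
    series = rng.normal(0.0, noise_sd, (n_samples, n_channels))
    phase = rng.uniform(0, 2 * np.pi, n_channels)
    wave = 0.5 * amplitude * np.sin(2 * np.pi * frequency_hz * t[:, None] / 1000.0 + phase)
    series[:, osc] += wave[:, osc]
    series += 0.2  # baseline firing fraction
    return PlantedOscillation(t, series, osc, amplitude, frequency_hz)
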