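"""Turn-key drivers for the focal seizure onset experiment battery.

Each scenario prepares the sheet in a specific global regime, applies the
scenario's heterogeneity or stimulation protocol, runs the recruitment
detector and verifies the scenario's dynamical contract (for example:
an oscillatory microdomain must stay isolated in a monostable surround
but recruit a bistable one).  Contract violations raise
:class:`ContractViolation`, which the command-line wrapper converts into
a nonzero exit status.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .connectivity import apply_microincision, build_connectivity
from .geometry import build_geometry
from .params import UnitParams, load_preset
from .recruitment import (
    DetectorSettings,
    RecruitmentReport,
    detect_recruited_units,
    place_subclusters,
)
from .simulator import (
    HeterogeneityMap,
    NoiseSpec,
    RampSpec,
    SimulationResult,
    StimulusSpec,
    simulate_sheet,
)

logger = logging.getLogger(__name__)

SCENARIOS = (
    "class1_global_ramp",
    "class2a_pulse",
    "class2b_microdomain",
    "class3a_subclusters",
    "class3b_bistable_microdomains",
    "counter_stimulation",
    "microincision",
)


class ContractViolation(RuntimeError):
    """A scenario's dynamical contract failed."""


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    name: str
    preset: str = "standard"
    n_rows: int = 60
    n_cols: int = 60
    boundary: str = "torus"
    connectivity_seed: int = 1
    noise_seed: int = 0
    placement_seed: int = 0
    duration_ms: float = 10000.0
    outdir: str | None = None
    overrides: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIOS}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunArtifact:
    config: ScenarioConfig
    result: SimulationResult
    report: RecruitmentReport
    contract: dict
    extra: dict = dataclasses.field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.result.save(out / "result.h5")
        manifest = {
            "config": dataclasses.asdict(self.config),
            "config_hash": self.config.config_hash(),
            "contract": self.contract,
            "final_percent": self.report.final_percent,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        _render_snapshots(self.result, out / "snapshots.png")


def _render_snapshots(result: SimulationResult, path: Path, n_frames: int = 5) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = result.geometry
    idx = np.linspace(0, len(result.t) - 1, n_frames).astype(int)
    fig, axes = plt.subplots(1, n_frames, figsize=(3 * n_frames, 3))
    for ax, k in zip(np.atleast_1d(axes), idx):
        ax.imshow(
            result.u[k].reshape(g.n_rows, g.n_cols),
            vmin=0.0, vmax=1.0, cmap="inferno", interpolation="nearest",
        )
        ax.set_title(f"T = {result.t[k] / 1000:.1f} s")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# helpers


def _setup(cfg: ScenarioConfig):
    preset = load_preset(cfg.preset)
    unit: UnitParams = preset["unit"]
    for key, val in cfg.overrides.items():
        if key.startswith("unit."):
            unit = unit.replace(**{key.split(".", 1)[1]: val})
    conn_kwargs = preset.get("connectivity", {})
    from .connectivity import ConnectivityParams

    conn = ConnectivityParams(**conn_kwargs)
    geom = build_geometry(
        cfg.n_rows, cfg.n_cols,
        macro_edge=preset.get("geometry", {}).get("macro_edge", 10),
        pitch_um=preset.get("geometry", {}).get("pitch_um", 50.0),
        boundary=cfg.boundary,
    )
    model = build_connectivity(geom, unit, conn, cfg.connectivity_seed)
    sim_cfg = dict(preset.get("simulation", {}))
    exp_cfg = dict(preset.get("experiments", {}))
    return model, unit, sim_cfg, exp_cfg


def _center_disc(geom, n_units: int) -> np.ndarray:
    from .recruitment import _quasi_disc

    center = geom.unit_index(geom.n_rows // 2, geom.n_cols // 2)
    return _quasi_disc(geom, center, n_units)


def _detect(result, exp_cfg) -> RecruitmentReport:
    det = DetectorSettings(**exp_cfg.get("detector", {})) if "detector" in exp_cfg else DetectorSettings()
    return detect_recruited_units(result, det)


def _require(condition: bool, name: str, detail: str, contract: dict) -> None:
    contract[name] = {"passed": bool(condition), "detail": detail}
    if not condition:
        raise ContractViolation(f"contract {name!r} violated: {detail}")


# ---------------------------------------------------------------------------
# scenarios


def run_scenario(cfg: ScenarioConfig) -> RunArtifact:
    """Execute a scenario, verify its contract, optionally save artifacts."""
    runner = _RUNNERS[cfg.name]
    artifact = runner(cfg)
    if cfg.outdir:
        artifact.save(cfg.outdir)
    return artifact


def _run_class1(cfg: ScenarioConfig) -> RunArtifact:
    """Global drive ramp with a silent heterogeneity patch.

    The whole sheet's basal E drive is ramped from the interictal value
    into the oscillatory region; a central patch receiving stronger
    feed-forward excitation must ignite strictly before the sheet-wide
    median.
    """
    model, unit, sim_cfg, exp = _setup(cfg)
    geom = model.geometry
    p0 = unit.p_basal
    p1 = exp.get("ramp_end", -1.0)
    t0, t1 = exp.get("ramp_window", (1000.0, 7000.0))
    het_scale = exp.get("heterogeneity_scale", 1.5)
    patch = _center_disc(geom, exp.get("heterogeneity_units", 150))
    # the heterogeneous patch receives a (het_scale)x stronger feed-forward
    # drive increment during the ramp
    ramps = [RampSpec("p_basal", p0, p1, t0, t1)]
    if het_scale != 1.0:
        ramps.append(RampSpec("p_basal", p0, p0 + het_scale * (p1 - p0),
                              t0, t1, mask=patch))
    res = simulate_sheet(
        model, unit, ramps=tuple(ramps),
        noise=NoiseSpec(unit.noise_coupling, cfg.noise_seed),
        duration=cfg.duration_ms, dt=sim_cfg.get("dt", 2.0), record_every=5,
    )
    exp = dict(exp)
    exp.setdefault("detector", {})["cadence_ms"] = exp.get("onset_cadence_ms", 100.0)
    report = _detect(res, exp)
    contract: dict = {}
    onset = report.onset_ms
    sheet_median = float(np.nanmedian(onset))
    patch_median = float(np.nanmedian(onset[patch]))
    if het_scale != 1.0:
        _require(
            np.isfinite(patch_median) and patch_median < sheet_median,
            "heterogeneity_leads_onset",
            f"patch median onset {patch_median} vs sheet median {sheet_median}",
            contract,
        )
    return RunArtifact(cfg, res, report, contract,
                       {"patch": patch, "patch_median_onset": patch_median,
                        "sheet_median_onset": sheet_median})


def _run_class2a(cfg: ScenarioConfig) -> RunArtifact:
    """Pulse to a bistable sheet expands; the same pulse at the
    monostable interictal point does not sustain recruitment."""
    model, unit, sim_cfg, exp = _setup(cfg)
    geom = model.geometry
    p_bistable = exp.get("bistable_p", unit.p_basal)
    pulse_units = exp.get("pulse_units", 100)
    mask = _center_disc(geom, pulse_units)
    stim = StimulusSpec("input_pulse", mask, exp.get("pulse_amplitude", 10.0),
                        1000.0, exp.get("pulse_duration", 100.0))

    runs = {}
    for label, p in (("bistable", p_bistable), ("monostable", unit.p_basal)):
        res = simulate_sheet(
            model, unit.replace(p_basal=p), stimuli=(stim,),
            noise=NoiseSpec(unit.noise_coupling, cfg.noise_seed),
            duration=cfg.duration_ms, dt=sim_cfg.get("dt", 2.0), record_every=5,
        )
        runs[label] = (res, _detect(res, exp))
    surround = np.setdiff1d(np.arange(geom.n_units), mask)
    contract: dict = {}
    res_b, rep_b = runs["bistable"]
    res_m, rep_m = runs["monostable"]
    grew = rep_b.fraction_course[-1] > rep_b.fraction_course[len(rep_b.fraction_course) // 3]
    _require(
        rep_b.percent_of(surround) > 50.0 and grew,
        "pulse_recruits_bistable",
        f"surround recruitment {rep_b.percent_of(surround):.1f}% (expanding={grew})",
        contract,
    )
    _require(
        rep_m.percent_of(surround) < 10.0,
        "pulse_fails_monostable",
        f"surround recruitment {rep_m.percent_of(surround):.1f}%",
        contract,
    )
    return RunArtifact(cfg, res_b, rep_b, contract,
                       {"monostable_report": rep_m, "pulse_mask": mask})


def _microdomain_run(cfg, model, unit, sim_cfg, exp, surround_p, md):
    ramp = RampSpec("p_basal", surround_p, exp.get("microdomain_p", -1.0),
                    *exp.get("ramp_window", (500.0, 2000.0)), mask=md)
    return simulate_sheet(
        model, unit.replace(p_basal=surround_p), ramps=(ramp,),
        noise=NoiseSpec(unit.noise_coupling, cfg.noise_seed),
        duration=cfg.duration_ms, dt=sim_cfg.get("dt", 2.0), record_every=5,
    )


def _run_class2b(cfg: ScenarioConfig) -> RunArtifact:
    """Oscillatory microdomain: isolated in a monostable surround,
    recruiting in a bistable surround."""
    model, unit, sim_cfg, exp = _setup(cfg)
    geom = model.geometry
    md = _center_disc(geom, exp.get("microdomain_units", 200))
    surround = np.setdiff1d(np.arange(geom.n_units), md)
    contract: dict = {}
    res_m = _microdomain_run(cfg, model, unit, sim_cfg, exp, unit.p_basal, md)
    rep_m = _detect(res_m, exp)
    res_b = _microdomain_run(cfg, model, unit, sim_cfg, exp, exp.get("bistable_p", unit.p_basal), md)
    rep_b = _detect(res_b, exp)
    _require(
        rep_m.percent_of(surround) < 10.0,
        "microdomain_isolated_monostable",
        f"surround recruitment {rep_m.percent_of(surround):.1f}%",
        contract,
    )
    _require(
        rep_b.percent_of(surround) > 50.0,
        "microdomain_recruits_bistable",
        f"surround recruitment {rep_b.percent_of(surround):.1f}%",
        contract,
    )
    return RunArtifact(cfg, res_b, rep_b, contract,
                       {"monostable_report": rep_m, "microdomain": md})


def _run_class3a(cfg: ScenarioConfig) -> RunArtifact:
    """Subcluster network versus one compact patch at equal totals."""
    model, unit, sim_cfg, exp = _setup(cfg)
    geom = model.geometry
    total = exp.get("total_units", geom.n_units // 10)
    # default subcluster count keeps the single-cluster size near the
    # patch scale (~90 units) regardless of sheet size
    n_sub = exp.get("n_subclusters", max(2, total // exp.get("subcluster_size_target", 90)))
    p_surr = exp.get("scan_surround_p", unit.p_basal)
    layout = place_subclusters(geom, total, n_sub, cfg.placement_seed)
    md_sub = layout.all_units
    md_one = place_subclusters(geom, total, 1, cfg.placement_seed + 50).all_units
    runs = {}
    for label, md in (("subclusters", md_sub), ("compact", md_one)):
        res = _microdomain_run(cfg, model, unit, sim_cfg, exp, p_surr, md)
        rep = _detect(res, exp)
        surround = np.setdiff1d(np.arange(geom.n_units), md)
        runs[label] = (res, rep, rep.percent_of(surround))
    contract: dict = {}
    pct_sub = runs["subclusters"][2]
    pct_one = runs["compact"][2]
    _require(
        pct_sub > pct_one,
        "subclusters_recruit_more",
        f"subclustered {pct_sub:.1f}% vs compact {pct_one:.1f}%",
        contract,
    )
    res, rep, _ = runs["subclusters"]
    return RunArtifact(cfg, res, rep, contract,
                       {"compact_percent": pct_one, "subcluster_percent": pct_sub,
                        "layout": layout})


def _run_class3b(cfg: ScenarioConfig) -> RunArtifact:
    """Bistable microdomains progressively activated by repeated random
    local pulses."""
    model, unit, sim_cfg, exp = _setup(cfg)
    geom = model.geometry
    n_domains = exp.get("n_microdomains", 10)
    md_units = exp.get("microdomain_units", 60)
    layout = place_subclusters(geom, n_domains * md_units, n_domains, cfg.placement_seed)
    het = HeterogeneityMap()
    md_all = layout.all_units
    het.set_absolute("p_basal", md_all, exp.get("microdomain_bistable_p", -2.0))
    rng = np.random.default_rng(cfg.noise_seed + 99)
    stimuli = []
    period = exp.get("stimulus_period", 3000.0)
    n_stim = int(cfg.duration_ms // period)
    for k in range(n_stim):
        center = int(rng.integers(geom.n_units))
        from .recruitment import _quasi_disc

        mask = _quasi_disc(geom, center, exp.get("pulse_units", 100))
        stimuli.append(StimulusSpec("input_pulse", mask,
                                    exp.get("pulse_amplitude", 10.0),
                                    onset=k * period + 500.0,
                                    duration=exp.get("pulse_duration", 100.0)))
    res = simulate_sheet(
        model, unit, het=het, stimuli=tuple(stimuli),
        noise=NoiseSpec(unit.noise_coupling, cfg.noise_seed),
        duration=cfg.duration_ms, dt=sim_cfg.get("dt", 2.0), record_every=5,
    )
    report = _detect(res, exp)
    # active domains over time: a domain is active when its mean E amplitude
    # in a trailing window exceeds the detector threshold
    u = res.u
    w = max(2, int(1000.0 / (res.t[1] - res.t[0])))
    checkpoints = np.linspace(w, len(res.t) - 1, 8).astype(int)
    active_counts = []
    for k in checkpoints:
        seg = u[k - w : k]
        active = sum(
            1 for mem in layout.members
            if np.ptp(seg[:, mem].mean(axis=1)) > report.settings.amp_threshold
        )
        active_counts.append(active)
    contract: dict = {}
    _require(
        active_counts[-1] > active_counts[0],
        "progressive_activation",
        f"active domains over time: {active_counts}",
        contract,
    )
    return RunArtifact(cfg, res, report, contract,
                       {"active_counts": active_counts, "layout": layout})


def _run_counter_stimulation(cfg: ScenarioConfig) -> RunArtifact:
    """A counter-stimulus shortly after seizure onset must strictly
    reduce the final recruited fraction versus the matched run."""
    model, unit, sim_cfg, exp = _setup(cfg)
    geom = model.geometry
    p_bistable = exp.get("bistable_p", unit.p_basal)
    mask = _center_disc(geom, exp.get("pulse_units", 100))
    trigger = StimulusSpec("input_pulse", mask, exp.get("pulse_amplitude", 10.0),
                           1000.0, exp.get("pulse_duration", 100.0))
    counter_delay = exp.get("counter_delay", 300.0)
    counter = StimulusSpec(
        "input_pulse",
        geom.disc(int(np.median(mask)), exp.get("counter_radius", 20)),
        exp.get("counter_amplitude", -25.0),
        1000.0 + counter_delay,
        exp.get("counter_duration", 600.0),
    )
    runs = {}
    params = unit.replace(p_basal=p_bistable)
    for label, stims in (("plain", (trigger,)), ("countered", (trigger, counter))):
        res = simulate_sheet(
            model, params, stimuli=stims,
            noise=NoiseSpec(unit.noise_coupling, cfg.noise_seed),
            duration=cfg.duration_ms, dt=sim_cfg.get("dt", 2.0), record_every=5,
        )
        runs[label] = (res, _detect(res, exp))
    contract: dict = {}
    plain_pct = runs["plain"][1].final_percent
    countered_pct = runs["countered"][1].final_percent
    _require(
        countered_pct < plain_pct,
        "counter_stimulation_reduces_recruitment",
        f"countered {countered_pct:.1f}% vs plain {plain_pct:.1f}%",
        contract,
    )
    res, rep = runs["countered"]
    return RunArtifact(cfg, res, rep, contract,
                       {"plain_percent": plain_pct, "countered_percent": countered_pct})


def _run_microincision(cfg: ScenarioConfig) -> RunArtifact:
    """An enclosing double cut around the microdomain suppresses
    recruitment of the outside tissue."""
    model, unit, sim_cfg, exp = _setup(cfg)
    geom = model.geometry
    md = _center_disc(geom, exp.get("microdomain_units", 200))
    p_surr = exp.get("bistable_p", unit.p_basal)
    rows, cols = geom.unit_coords(md)
    r_lo, r_hi = rows.min(), rows.max()
    c_lo, c_hi = cols.min(), cols.max()
    pad = exp.get("cut_padding_units", 3)
    p = geom.pitch_um
    x0, x1 = (c_lo - pad) * p, (c_hi + pad) * p
    y0, y1 = (r_lo - pad) * p, (r_hi + pad) * p
    ov = p  # overlap past corners: endpoint touches do not cut
    box = [((x0 - ov, y0), (x1 + ov, y0)), ((x1, y0 - ov), (x1, y1 + ov)),
           ((x1 + ov, y1), (x0 - ov, y1)), ((x0, y1 + ov), (x0, y0 - ov))]
    cut_model = apply_microincision(model, box)
    runs = {}
    for label, mdl in (("intact", model), ("cut", cut_model)):
        res = _microdomain_run(cfg, mdl, unit, sim_cfg, exp, p_surr, md)
        runs[label] = (res, _detect(res, exp))
    outside = np.setdiff1d(np.arange(geom.n_units), geom.disc(
        geom.unit_index((r_lo + r_hi) // 2, (c_lo + c_hi) // 2),
        max(r_hi - r_lo, c_hi - c_lo) // 2 + pad + 1))
    contract: dict = {}
    intact_pct = runs["intact"][1].percent_of(outside)
    cut_pct = runs["cut"][1].percent_of(outside)
    _require(
        cut_pct < intact_pct,
        "microincision_suppresses_recruitment",
        f"cut {cut_pct:.1f}% vs intact {intact_pct:.1f}% outside the cut",
        contract,
    )
    res, rep = runs["cut"]
    return RunArtifact(cfg, res, rep, contract,
                       {"intact_percent": intact_pct, "cut_percent": cut_pct,
                        "cuts": box})


_RUNNERS = {
    "class1_global_ramp": _run_class1,
    "class2a_pulse": _run_class2a,
    "class2b_microdomain": _run_class2b,
    "class3a_subclusters": _run_class3a,
    "class3b_bistable_microdomains": _run_class3b,
    "counter_stimulation": _run_counter_stimulation,
    "microincision": _run_microincision,
}
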