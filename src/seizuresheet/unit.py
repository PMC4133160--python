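"""Single Wilson-Cowan E-I minicolumn: drift field, fixed points, simulation.

The unit obeys

    tau_e * du/dt = -u + f(c_ee*u - c_ie*v + P + e_ext)
    tau_i * dv/dt = -v + f(c_ei*u - c_ii*v + Q + i_ext)

with ``u``/``v`` the fractional firing activity of the excitatory and
inhibitory populations and ``f`` the logistic transfer.  In isolation the
unit is used for fixed-point analysis (it is parameterised so that it
cannot oscillate on its own; collective oscillation emerges only through
sheet coupling), and as a bit-exact oracle for the decoupled limit of the
sheet integrator.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize

from .params import SigmoidParams, UnitParams

STABILITY_KINDS = (
    "stable_node",
    "stable_focus",
    "saddle",
    "unstable_node",
    "unstable_focus",
)

#: |Re(lambda)| below this is reported as "marginal"
_EIG_REAL_TOL = 1e-8
#: |Im(lambda)| above this classifies a focus
_EIG_IMAG_TOL = 1e-8
#: state-space distance under which two roots are the same fixed point
_DEDUP_TOL = 1e-6


def sigmoid(x, params: SigmoidParams):
    """Logistic transfer; strictly increasing, range (0, 1).

    Accepts scalars or arrays; rejects non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid input must be finite")
    # split by sign for overflow-free evaluation
    z = params.steepness * (x - params.offset)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def sigmoid_deriv(x, params: SigmoidParams):
    f = sigmoid(x, params)
    return params.steepness * f * (1.0 - f)


def unit_drift(
    state,
    params: UnitParams,
    external_e: float = 0.0,
    external_i: float = 0.0,
):
    """Deterministic right-hand side ``(du/dt, dv/dt)`` in 1/ms.

    ``external_e`` carries network and noise input to the E population
    (``external_i`` likewise for I; zero in the standard configuration).
    """
    u, v = state
    fe = sigmoid(params.c_ee * u - params.c_ie * v + params.p_basal + external_e, params.sigmoid)
    fi = sigmoid(params.c_ei * u - params.c_ii * v + params.q_basal + external_i, params.sigmoid)
    return (-u + fe) / params.tau_e, (-v + fi) / params.tau_i


def _jacobian(u: float, v: float, p: UnitParams) -> np.ndarray:
    ge = sigmoid_deriv(p.c_ee * u - p.c_ie * v + p.p_basal, p.sigmoid)
    gi = sigmoid_deriv(p.c_ei * u - p.c_ii * v + p.q_basal, p.sigmoid)
    return np.array(
        [
            [(-1.0 + p.c_ee * ge) / p.tau_e, (-p.c_ie * ge) / p.tau_e],
            [(p.c_ei * gi) / p.tau_i, (-1.0 - p.c_ii * gi) / p.tau_i],
        ]
    )


@dataclasses.dataclass(frozen=True)
class FixedPoint:
    u: float
    v: float
    stability: str
    eigenvalues: tuple[complex, complex]
    marginal: bool = False
    converged: bool = True

    @property
    def state(self) -> tuple[float, float]:
        return (self.u, self.v)


def _classify(eig: np.ndarray) -> tuple[str, bool]:
    re = eig.real
    marginal = bool(np.any(np.abs(re) < _EIG_REAL_TOL))
    is_focus = bool(np.any(np.abs(eig.imag) > _EIG_IMAG_TOL))
    if np.all(re < 0):
        return ("stable_focus" if is_focus else "stable_node"), marginal
    if np.all(re > 0):
        return ("unstable_focus" if is_focus else "unstable_node"), marginal
    return "saddle", marginal


def find_unit_fixed_points(params: UnitParams, grid_resolution: int = 100) -> list[FixedPoint]:
    """All fixed points of the unit drift inside the unit square.

    Candidate cells are located by sign changes of the drift field on a
    ``grid_resolution``-squared lattice, polished with a Newton-type root
    solver, classified by the Jacobian eigenvalues and deduplicated.
    Candidates whose polishing does not converge are returned with
    ``converged=False`` rather than dropped.
    """
    if grid_resolution < 50:
        raise ValueError("grid_resolution must be >= 50")
    gs = np.linspace(0.0, 1.0, grid_resolution)
    U, V = np.meshgrid(gs, gs, indexing="ij")
    du, dv = unit_drift((U, V), params)

    def fun(x):
        return np.array(unit_drift((x[0], x[1]), params))

    candidates: list[tuple[float, float, bool]] = []
    # sign-change cells: both components change sign within a 2x2 cell
    sdu, sdv = np.sign(du), np.sign(dv)
    for i in range(grid_resolution - 1):
        for j in range(grid_resolution - 1):
            cu = sdu[i : i + 2, j : j + 2]
            cv = sdv[i : i + 2, j : j + 2]
            if cu.min() < cu.max() and cv.min() < cv.max():
                x0 = (gs[i] + gs[i + 1]) / 2, (gs[j] + gs[j + 1]) / 2
                sol = optimize.root(fun, x0, method="hybr", tol=1e-13)
                ok = sol.success and np.max(np.abs(fun(sol.x))) < 1e-10
                candidates.append((float(sol.x[0]), float(sol.x[1]), ok))

    out: list[FixedPoint] = []
    for u, v, ok in candidates:
        if ok and not (-1e-9 <= u <= 1 + 1e-9 and -1e-9 <= v <= 1 + 1e-9):
            continue
        if any(abs(u - fp.u) < _DEDUP_TOL and abs(v - fp.v) < _DEDUP_TOL for fp in out):
            continue
        eig = np.linalg.eigvals(_jacobian(u, v, params))
        kind, marginal = _classify(eig)
        out.append(
            FixedPoint(u, v, kind, (complex(eig[0]), complex(eig[1])), marginal, ok)
        )
    out.sort(key=lambda fp: (fp.u, fp.v))
    return out


def simulate_unit(
    params: UnitParams,
    init: tuple[float, float] = (0.0, 0.0),
    duration: float = 1000.0,
    dt: float = 2.0,
    noise_seed: int | None = None,
    external_e: float = 0.0,
):
    """Fixed-step explicit-Euler trajectory of a single unit.

    Returns ``(t, u, v)`` arrays including the initial state.  With
    ``noise_seed`` set, a standard-normal value scaled by the unit's
    ``noise_coupling`` is added to the E input at every step, drawn from
    ``numpy.random.default_rng(noise_seed)`` — the same stream layout the
    sheet integrator uses for a one-macrocolumn sheet, so the decoupled
    limits match bit for bit.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least one step")
    if dt > min(params.tau_e, params.tau_i):
        warnings.warn(
            "dt exceeds the smallest time constant; states may leave [0,1]",
            RuntimeWarning,
            stacklevel=2,
        )
    n = int(round(duration / dt))
    u = np.empty(n + 1)
    v = np.empty(n + 1)
    u[0], v[0] = init
    rng = np.random.default_rng(noise_seed) if noise_seed is not None else None
    p = params
    for k in range(n):
        noise = p.noise_coupling * rng.standard_normal(1)[0] if rng is not None else 0.0
        du, dv = unit_drift((u[k], v[k]), p, external_e=external_e + noise)
        u[k + 1] = u[k] + dt * du
        v[k + 1] = v[k] + dt * dv
    t = np.arange(n + 1) * dt
    return t, u, v
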