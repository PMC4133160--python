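"""Parameter containers for the minicolumn model and packaged presets.

A minicolumn is a coupled excitatory/inhibitory (E-I) pair of neural
populations.  ``UnitParams`` holds the within-unit coupling constants,
basal drives, time constants and the shared sigmoid of the firing-rate
transfer.  Presets live in ``presets/*.toml`` and can be loaded by name;
the ``standard`` preset is the interictal working point used throughout
the experiments: it sits in the monostable-background regime close to
the onset of collective oscillation.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from importlib import resources
from pathlib import Path


@dataclasses.dataclass(frozen=True)
class SigmoidParams:
    """Logistic firing-rate transfer ``f(x) = 1/(1+exp(-steepness*(x-offset)))``.

    ``steepness`` sets the spread of firing thresholds in the underlying
    population (larger = sharper threshold); ``offset`` is the input at
    which half of the population fires.
    """

    steepness: float = 2.4
    offset: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.steepness) and math.isfinite(self.offset)):
            raise ValueError("sigmoid parameters must be finite")
        if self.steepness <= 0:
            raise ValueError(f"sigmoid steepness must be > 0, got {self.steepness}")


@dataclasses.dataclass(frozen=True)
class UnitParams:
    """Parameters of a single Wilson-Cowan E-I minicolumn.

    ``c_ee``/``c_ie``/``c_ei``/``c_ii`` are within-unit coupling constants
    (dimensionless); ``p_basal``/``q_basal`` the basal drives to the E and I
    populations; ``tau_e``/``tau_i`` membrane-scale relaxation times in ms;
    ``noise_coupling`` the strength B multiplying the per-macrocolumn
    standard-normal noise fed to the E population.
    """

    c_ee: float = 11.5
    c_ie: float = 18.0
    c_ei: float = 10.5
    c_ii: float = 4.0
    p_basal: float = -3.0
    q_basal: float = -6.5
    tau_e: float = 50.0
    tau_i: float = 30.0
    noise_coupling: float = 0.3
    sigmoid: SigmoidParams = dataclasses.field(default_factory=SigmoidParams)

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_coupling < 0:
            raise ValueError("noise_coupling must be non-negative")
        for name in ("c_ee", "c_ie", "c_ei", "c_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "UnitParams":
        return dataclasses.replace(self, **kw)


_UNIT_FIELDS = {f.name for f in dataclasses.fields(UnitParams)} - {"sigmoid"}


def _params_from_dict(d: dict) -> UnitParams:
    d = dict(d)
    sig = d.pop("sigmoid", {})
    unknown = set(d) - _UNIT_FIELDS
    if unknown:
        raise KeyError(f"unknown unit-parameter keys: {sorted(unknown)}")
    return UnitParams(sigmoid=SigmoidParams(**sig), **d)


def load_config(path: str | Path) -> dict:
    """Read a TOML configuration file into a plain dict."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def load_preset(name: str = "standard") -> dict:
    """Load a packaged preset by name.

    Returns a dict with (at least) keys ``unit`` (an :class:`UnitParams`)
    and ``connectivity``/``geometry``/``simulation`` sub-dicts as present
    in the preset file.
    """
    ref = resources.files("seizuresheet.presets").joinpath(f"{name}.toml")
    try:
        raw = tomllib.loads(ref.read_text())
    except FileNotFoundError:
        raise KeyError(f"no packaged preset named {name!r}") from None
    out = dict(raw)
    if "unit" in raw:
        out["unit"] = _params_from_dict(raw["unit"])
    return out
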