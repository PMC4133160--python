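# seizuresheet

A multiscale model of neocortical focal seizure onset: thousands of
Wilson–Cowan excitatory/inhibitory minicolumn units coupled into a
cortical sheet by dense local Gaussian connectivity and remote patchy
projections, together with the experiment battery that distinguishes
three dynamical classes of focal onset — globally induced (a slow
parameter shift crosses a bifurcation; a silent heterogeneity merely
ignites first), globally supported (a bistable sheet tipped by a local
trigger), and network induced (hyperactive microdomains recruiting a
monostable surround).

It is written for computational neuroscientists and epilepsy modellers
who want a reproducible mesoscopic sandbox: every simulation is fully
determined by (connectivity seed, noise seed, schedule).

## Model

Each minicolumn obeys

    tau_e du/dt = -u + f(C_EE u - C_IE v + P + B xi + E_net)
    tau_i dv/dt = -v + f(C_EI u - C_II v + Q + I_net)

with `f` a logistic transfer, `u`/`v` the fractional firing of the E/I
populations, `P`/`Q` basal drives, and `xi` standard-normal noise shared
within each 10 x 10-minicolumn macrocolumn.  Network input enters
through four sparse matrices (local E->E, local E->I, remote patchy
E->E; I->E and I->I act only within a unit).  The isolated unit cannot
oscillate for any drive; collective rhythms (~20 Hz) emerge from the
coupling, and the sheet passes through monostable background ->
bistable -> monostable oscillatory as P is ramped from -3 to -1.  See
`docs/methods.md` for the full parameter account.

## Worked example

```python
import numpy as np
from seizuresheet import (build_geometry, load_preset, simulate_sheet,
                          NoiseSpec, RampSpec, detect_recruited_units)
from seizuresheet.connectivity import ConnectivityParams, build_connectivity

preset = load_preset("standard")
unit = preset["unit"]
geom = build_geometry(60, 60, macro_edge=10, boundary="torus")
model = build_connectivity(geom, unit,
                           ConnectivityParams(**preset["connectivity"]), seed=1)

# oscillatory microdomain (radius 5) inside a bistable surround (P = -2)
md = geom.disc(geom.unit_index(30, 30), 5)
ramp = RampSpec("p_basal", -2.0, -1.0, 500.0, 2000.0, mask=md)
res = simulate_sheet(model, unit.replace(p_basal=-2.0), ramps=(ramp,),
                     noise=NoiseSpec(0.5, seed=3), duration=8000.0,
                     record_every=5)
rep = detect_recruited_units(res)
surround = np.setdiff1d(np.arange(geom.n_units), md)
print(f"surround recruited: {rep.percent_of(surround):.1f}%")
print(f"final recruited (all units): {rep.final_percent:.1f}%")
```

prints

    surround recruited: 90.4%
    final recruited (all units): 90.6%

— the microdomain's sustained rhythm has recruited essentially the whole
bistable sheet.  Re-running with a monostable surround
(`p_basal=-3.0` and ramp start `-3.0`) prints `surround recruited:
0.0%`: the same microdomain stays an isolated microseizure, the class
IIb dichotomy.

The same experiments are available from the shell:

    seizuresheet scenario class2b_microdomain --outdir out/
    seizuresheet scan --axis-x p_basal:-3.4:-1.0:7 --outdir out/
    seizuresheet build-connectivity --rows 150 --cols 150 --outdir conn/

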