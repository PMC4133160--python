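# Standard interictal working point.
#
# The isolated minicolumn at these constants has only stable fixed
# points (no limit cycle for any basal drive); collective oscillation
# emerges from sheet coupling.  The basal E drive P = -3 places the
# coupled sheet in the monostable background regime below the
# network-bistable band (pulse-sustained oscillation from about
# P = -2.3), and the sheet becomes spontaneously oscillatory near
# P = -1.25, so the canonical ramp from -3 to -1 crosses both
# transitions.  The collective rhythm at the oscillatory drive sits in
# the beta band.

[unit]
c_ee = 12.0
c_ie = 19.5
c_ei = 4.0
c_ii = 0.5
p_basal = -3.0
q_basal = -7.85
tau_e = 30.0
tau_i = 13.2
noise_coupling = 0.5

[unit.sigmoid]
steepness = 2.5
offset = 1.15

[geometry]
macro_edge = 10      # minicolumns per macrocolumn side
pitch_um = 50.0      # minicolumn size

[connectivity]
sigma_um = 170.0             # Gaussian fall-off of local connection probability
local_radius_um = 510.0      # hard cutoff (~3 sigma) for local connections
n_patches_per_macro = 3
patch_radius_units = 5       # 81 minicolumns per full patch
max_patch_distance_um = 2500.0
n_out_remote = 20
n_shared_patches = 1
w_local = 0.08463            # local E->E: total 6 over ~70.9 expected in-degree
w_local_ei = 0.24683         # local E->I: total 17.5 (fast feed-forward inhibition)
w_remote = 0.10417           # remote E->E: total 2 over ~19.2 expected in-degree
w_self_e = 12.0              # equals unit c_ee
w_self_ei = 4.0              # equals unit c_ei

[simulation]
dt = 2.0

[experiments]
# sheet-level working points used by the scenario battery
bistable_p = -2.0            # mid network-bistable band
scan_surround_p = -2.7       # monostable surround for microdomain-network scans
microdomain_p = -1.0         # oscillatory drive for hyperactive microdomains
ramp_end = -1.0
ramp_window = [1000.0, 7000.0]
heterogeneity_scale = 1.5
pulse_amplitude = 10.0
pulse_duration = 100.0
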