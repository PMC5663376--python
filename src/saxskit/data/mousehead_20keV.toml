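# Default mouse-head SAXS-CT configuration: concentric-cylinder phantom
# (white-matter core 8 mm, gray-matter annulus 1 mm, skull shell 0.2 mm),
# translate-rotate plan (100 x 0.1 mm translations, 360 x 1 deg) at
# 20 keV, and the ideal annular detector (3 cm radius, 30 cm distance,
# 300 bins, q = 0-10 nm^-1).

[phantom]
slice_thickness_mm = 1.0

[[phantom.region]]
r_inner_mm = 0.0
r_outer_mm = 4.0
material = "WM1"
half = "upper"

[[phantom.region]]
r_inner_mm = 0.0
r_outer_mm = 4.0
material = "WM2"
half = "lower"

[[phantom.region]]
r_inner_mm = 4.0
r_outer_mm = 5.0
material = "GM1"
half = "upper"

[[phantom.region]]
r_inner_mm = 4.0
r_outer_mm = 5.0
material = "GM2"
half = "lower"

[[phantom.region]]
r_inner_mm = 5.0
r_outer_mm = 5.2
material = "skull"

[plan]
n_translations = 100
step_mm = 0.1
n_projections = 360
angular_step_deg = 1.0
histories_per_position = 1000000000
energy_keV = 20.0
divergence_deg = 0.08
field_width_mm = 10.0

[detector]
distance_mm = 300.0
radius_mm = 30.0
n_bins = 300
efficiency = 1.0
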