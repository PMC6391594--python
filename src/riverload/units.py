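"""Unit-conversion constants used throughout the package.

Internal conventions: concentrations in ug/L, discharge in m3/s, loads in
ng/s.  Reports use kg/y (emissions, inventories) and tonnes/y (sea loads).
"""

#: Seconds in one (Julian-ish) reporting year.
SECONDS_PER_YEAR = 3.15576e7

#: ng/s -> kg/y  (x 3.15576e7 s/y x 1e-12 kg/ng)
NG_S_TO_KG_Y = SECONDS_PER_YEAR * 1e-12  # = 3.15576e-5

#: kg/y -> tonnes/y
KG_Y_TO_T_Y = 1e-3

#: (ug/L) x (m3/s) -> ng/s   (1 ug/L = 1e6 ng/m3)
UGL_TIMES_M3S_TO_NG_S = 1e6

#: ng/s / (m3/s) -> ug/L
NG_S_PER_M3S_TO_UGL = 1e-6

#: (mm/y over 1 km2) -> m3/s   (1 mm x 1 km2 = 1e3 m3, spread over a year)
MM_KM2_Y_TO_M3_S = 1e3 / SECONDS_PER_YEAR
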