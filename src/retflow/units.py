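"""Unit conversion constants.

Internal conventions: velocities in mm/s, diameters and distances in um,
flows computed in um^3/s internally and reported in ul/min, hemoglobin in
g/ml, pressures in mmHg, oxygen contents in ml(O2) per ml blood, oxygen
extraction in ul(O2)/min. Saturations are fractions in [0, 1] internally
and percent on disk.
"""

NM_TO_M = 1e-9
US_TO_S = 1e-6
MM_TO_UM = 1e3
UM_TO_CM = 1e-4
UM3_PER_S_TO_UL_PER_MIN = 60.0 / 1e9  # 1 ul = 1e9 um^3
UL_TO_ML = 1e-3
MG_TO_G = 1e-3
M_PER_S_TO_MM_PER_S = 1e3
PERCENT = 100.0
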