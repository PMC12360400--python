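"""Unit conversion constants.

All solver internals work in CGS (cm, s, dyn, poise, cm3 O2).  Interface
quantities keep the units customary in the microcirculation literature:
pressures in mmHg, diameters and lengths in µm, flows in nl/min, viscosity
in cP, wall shear stress in dyn/cm2, oxygen demand in cm3 O2/100 cm3/min.
"""

MMHG_TO_DYN_CM2 = 1333.22
UM_TO_CM = 1e-4
CM_TO_UM = 1e4
CP_TO_POISE = 1e-2
NL_MIN_TO_CM3_S = 1e-6 / 60.0  # 1 nl/min in cm3/s
CM3_S_TO_NL_MIN = 1.0 / NL_MIN_TO_CM3_S
# oxygen demand: cm3 O2 / 100 cm3 tissue / min  ->  cm3 O2 / cm3 / s
M0_TO_CGS = 1.0 / (100.0 * 60.0)
MM_TO_CM = 0.1
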