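"""Physical constants in CGS units.

All internal computation in sedgrid uses CGS (cm, g, s, poise, erg, K).
Sedimentation coefficients are stored in seconds and reported in Svedberg
(1 S = 1e-13 s); hydrodynamic radii are stored in cm and reported in nm.
"""

#: Universal gas constant, erg mol^-1 K^-1
R_GAS = 8.314462e7

#: Avogadro's number, mol^-1
N_AVOGADRO = 6.02214076e23

#: One Svedberg in seconds
SVEDBERG = 1e-13

#: One nanometre in cm
NM = 1e-7
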