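"""Unit conventions and the single conversion table for the pipeline.

Internal conventions, used by every module:

==============  =========================
quantity        unit
==============  =========================
q               nm^-1
distances       nm (d-spacing, Rg, R, Dmax, correlation length)
elution time    min
concentration   mg/mL
molar mass      Da (g/mol); MW estimates reported in kDa
density         g/mL
volume          nm^3
particle mass   g
==============  =========================

Conversions between these happen only through the constants below.
"""

# Avogadro's number [1/mol]
N_A = 6.02214076e23

# 1 nm^3 in mL
NM3_TO_ML = 1.0e-21

# 1 mg in g
MG_TO_G = 1.0e-3

# 1 Angstrom^-1 in nm^-1 (q conversion: q[nm^-1] = 10 * q[A^-1])
INV_ANGSTROM_TO_INV_NM = 10.0

# 1 nm in Angstrom
NM_TO_ANGSTROM = 10.0

# 1 Da in kDa
DA_TO_KDA = 1.0e-3
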