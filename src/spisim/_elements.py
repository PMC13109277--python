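"""Shared element data and physical constants (nm / fs / eV / u units)."""

from __future__ import annotations

# Planck constant times speed of light, eV nm (CODATA)
HC_EV_NM = 1239.84198

# classical electron radius
R_E_NM = 2.8179403262e-6
R_E_CM = 2.8179403262e-13

# Coulomb constant e^2 / (4 pi eps0), eV nm
COULOMB_EV_NM = 1.4399645478

# speed of light, nm/fs
C_NM_FS = 299.792458

# 1 u in eV/c^2
U_EV = 931.49410242e6

# acceleration conversion: a [nm/fs^2] = (F [eV/nm] / m [u]) * ACC_CONV
ACC_CONV = C_NM_FS**2 / U_EV  # 9.6485e-5

# kinetic energy conversion: KE [eV] = 0.5 * m [u] * v^2 [nm/fs]^2 * KE_CONV
KE_CONV = U_EV / C_NM_FS**2  # 10364.27

SUPPORTED_ELEMENTS = ("H", "C", "N", "O", "S", "P")

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}

# standard atomic weights, u
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "S": 32.06,
}

# K-shell binding energies, eV (photoabsorption above these is treated as
# K-shell and can trigger one Auger secondary ionization)
K_EDGE_EV = {"H": None, "C": 284.2, "N": 409.9, "O": 543.1, "P": 2145.5, "S": 2472.0}
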