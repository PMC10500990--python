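"""Physical constants and unit conventions.

Energies and frequencies are carried in eV, time in fs, transition dipoles
in atomic units, distances in Angstrom (RMSD matrices in nm).  Nuclear
coordinates are dimensionless normal coordinates, so the harmonic reference
Hamiltonian reads H0 = sum_a w_a (p_a^2 + q_a^2) / 2.
"""

#: hbar in eV fs
HBAR_EVFS = 0.6582119569

#: Hartree in eV (CODATA)
HARTREE_EV = 27.211386245988

#: Angstrom per nm
ANG_PER_NM = 10.0
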