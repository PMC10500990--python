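# Methods and numerical choices

This document records the physical model implemented by `lvcspec`, the
default parameters and why they were chosen, the numerical algorithms,
and the known limitations.

## 1. Model

### 1.1 Linear vibronic coupling Hamiltonian

The electronic structure near the Franck–Condon (FC) point is described
by a linear vibronic coupling (LVC) model over dimensionless
ground-state normal coordinates **q**:

* diagonal:  V_ii(q) = E_i + ½ qᵀ W q + λ_i · q
* off-diagonal:  V_ij(q) = C_ij + λ_ij · q

with W the (by default diagonal) frequency matrix in eV, E_i the
vertical excitation energies, λ_i the excited-state gradients, C_ij
constant inter-state couplings and λ_ij linear (Jahn–Teller-type)
couplings.  Energies are in eV, time in fs, ħ = 0.6582119569 eV·fs.
Every diabatic state carries a transition dipole from the ground state
(atomic units); charge-transfer states are dark (zero dipole).

The Huang–Rhys factor of state i along mode a is S_a = λ²_{i,a}/(2ω_a²),
and the per-mode reorganization energy is S_a ω_a.

### 1.2 Dimer assembly

`assemble_dimer` builds the 8-state stacked-dimer Hamiltonian from
fragment data in the fixed order

|L1⟩, |L1′⟩, |L2⟩, |L2′⟩, |CT(1→2)⟩, |CT′(1→2)⟩, |CT(2→1)⟩, |CT′(2→1)⟩

where the primes are the second component of the doubly degenerate local
excitation.  The mode space is the direct sum of the two monomer mode
spaces; local-excitation gradients are block-padded with zeros on the
partner fragment, and CT gradients are composed from the ionic-fragment
gradients (cation on the donor, anion on the acceptor).  Jahn–Teller
pairs within a fragment get purely linear couplings (zero constant).
The coupling matrix of constants must be symmetric and is classified
into LE–LE (exciton), LE–CT (charge transfer), CT–CT and JT classes;
`toggle_couplings` switches whole classes on and off to attribute
spectral features to specific interactions.

### 1.3 Adiabatic analysis

`adiabatic_analysis` diagonalizes the electronic Hamiltonian at the FC
point and reports adiabatic energies, dipole/oscillator strengths and
the percentage composition in the diabatic basis.  The sum of dipole
strengths is invariant under the diagonalization, which is used as an
internal consistency check.

## 2. Quantum dynamics

### 2.1 Basis and Hamiltonian matrix

Propagation uses a direct-product basis |electronic⟩ ⊗ |n₁…n_f⟩ of
harmonic-oscillator number states, truncated at `n_max` quanta per mode
(a per-mode list is accepted).  The vibrational Hamiltonian is written
with the zero-point constant dropped, H₀ = Σ_ab W_ab a†_a a_b, so the
ground vibrational level defines the energy zero.  Two consequences are
exploited throughout:

* propagated correlation functions match the analytic FC|VG limit
  including the phase, and
* the vacuum is invariant under orthogonal coordinate transformations,
  which makes the effective-mode machinery (section 4) exact at full
  depth.

Linear terms enter through q_a = (a_a + a†_a)/√2; bilinear W
off-diagonals appear as number-conserving hops.  A dimension cap
(default 5 × 10⁶ configurations) aborts with a message pointing to the
effective-mode reduction rather than attempting an infeasible build.

### 2.2 Propagators

Two interchangeable propagators are provided (`method="auto"` picks by
size):

* **exact** — one dense diagonalization, then analytic time evolution;
  used up to dimension 4000.  It is the reference for everything else.
* **krylov** — short-iterative Lanczos per step (default order 15, full
  reorthogonalization).  On Krylov-space exhaustion (β < 10⁻¹⁴, e.g. a
  two-level problem) the step reconstructs from the basis vectors
  actually built.  If the requested step-error tolerance is not met at
  the maximum order, propagation aborts with advice to reduce `dt` or
  raise the order.

Default time step 0.1 fs; norm and total energy conservation are
monitored and returned with every run.  For a real symmetric
Hamiltonian the correlation functions obey transpose symmetry,
φ_ji(t) = φ_ij(t) (no conjugation), which is enforced in the tests.

### 2.3 Outputs

`PropagationResult` holds times, cross-correlations φ_ji(t) with the
chosen initial state, diabatic populations, norm/energy traces and
optional wavefunction snapshots.  Snapshots allow re-projection onto any
orthonormal electronic combination basis (e.g. adiabatic or
exciton states) via `populations_in_combination_basis`.
`converged_propagation` raises `n_max` until the top-level occupancy of
every mode falls below a tolerance, giving an a-posteriori basis check.
HDF5 round-tripping and CSV export of populations are built in.

## 3. Lineshapes

### 3.1 Fourier transform

Spectra are shape-only cross-section kernels: the cosine Fourier
transform of Re φ(t) with Gaussian damping exp(−(Γt/ħ)²/2), where
Γ = HWHM/√(2 ln 2), integrated by the trapezoid rule on the recorded
time grid.  The energy grid must respect the Nyquist limit πħ/dt; a
guard raises otherwise.  For multi-state models the spectrum decomposes
into components ε_ij weighted by μ_i·μ_j; each unordered off-diagonal
pair is counted once with a factor 2, and the total is their sum.  Dark
states contribute nothing and are skipped.

### 3.2 Analytic FC|VG limit

For an uncoupled displaced-oscillator state the correlation function is
analytic:

φ(t) = exp(−i E₀₀ t/ħ) · exp(Σ_a S_a (e^{−iω_a t/ħ} − 1)),
E₀₀ = E_vert − Σ_a S_a ω_a.

`fcvg_spectrum` uses this closed form; `nonadiabatic_spectrum` uses
propagation and reduces to it when couplings are absent (this
equivalence is an acceptance test at 10⁻⁵).  The zero-temperature
Franck–Condon stick progression (Poisson intensities S^n e^{−S}/n! at
E₀₀ + n ω) is available for quick inspection and underlies
`recover_progression_parameters`, which reads ω, S and E₀₀ back off a
broadened band from its peak spacing and intensity ratio.

### 3.3 Defaults

HWHM 0.04 eV (a typical solution-phase inhomogeneous width for
phthalocyanines), t_max 100 fs, dt 0.1 fs.  The 100 fs window resolves
~0.04 eV structure; longer windows add nothing once the Gaussian
damping has decayed.  Normalization options: `none`, `max`, `area`.
Ensemble spectra are convex combinations on a shared energy grid
(`weighted_average_spectrum`; weights must sum to 1).

## 4. Hierarchical effective modes

`build_hierarchy` constructs an orthogonal transformation T of the mode
space in blocks: block 1 is an orthonormal basis (SVD) of the span of
all coupling vectors {λ_i, λ_ij}; block k+1 is W·(block k) orthogonalized
against everything before it; the remainder is completed with a
null-space basis.  Rank decisions use an SVD threshold relative to the
**pre-projection** scale of the candidate block, so that a W-invariant
block (whose residual is pure rounding noise) terminates the chain
instead of spawning spurious blocks.

`truncate(hier, m)` keeps the first m blocks and returns a model with
the dense reduced frequency matrix W′ = T_kᵀ W T_k and transformed
gradients/couplings.  Its metadata reports
`dropped_coupling_norm = ‖T_kᵀ W T_d‖_F`, the norm of the kept–dropped
block of the transformed frequency matrix — the actual source of
truncation error, zero exactly when the kept space is W-invariant.  At
full depth the transformation is exactly unitary-equivalent to the
original model (spectra agree to rounding); truncation error in |φ(t)|
decreases monotonically with m over short-time windows, the regime the
construction is designed for.  The bundled 12-mode demonstration (one
bright state, gradients on 6 of 12 modes, chain depth 6) shows
short-time errors 1.8 × 10⁻¹ → 9.3 × 10⁻³ → 2.3 × 10⁻⁴ for m = 1, 2, 3
over 30 fs.

## 5. Conformations

Pairwise RMSD uses Kabsch superposition restricted to proper rotations
(no reflections).  Clustering follows the Daura (GROMOS) algorithm:
repeatedly take the structure with the most neighbors within the cutoff
(ties broken by lowest frame index), remove it and its neighbors as one
cluster.  Default cutoff 0.10 nm.  Cluster weights are exact rational
fractions of the trajectory (computed with `fractions.Fraction`, so
they sum to 1 exactly); the central structure minimizes the mean RMSD
to its cluster.

Stacking descriptors of a dimer frame: metal–metal distance, mean-plane
(ring–ring) distance, the eight tilt angles α₁..₈ between opposing
isoindole axes folded into [0°, 90°], and the signed twist β about the
stacking axis.  `descriptor_table` tabulates them over a trajectory and
`linear_correlation` (scipy's OLS with a constant-y R² = 0 convention)
quantifies descriptor–descriptor or descriptor–observable trends.

## 6. Synthetic generators

All generators are deterministic given a seed.

* `make_displaced_monomer` — one bright state, default S = 0.5,
  ω = 0.15 eV, E_vert = 2.0 eV: a caricature of a phthalocyanine
  Q band (dominant ~0.15 eV ring mode, moderate displacement).
* `make_jt_monomer` — degenerate E-state pair with linear JT coupling
  (conical intersection at q = 0).
* `make_kasha_ct_dimer` — the 8-state LE/CT template with exciton
  coupling J (default +0.05 eV, H-type: blue-shifted bright upper
  exciton, dark lower), LE–CT transfer and CT–CT mixing parameters.
* `make_stacked_trajectory` — a rigid 21-atom phthalocyanine-like ring
  template (outer shell radius ~4.6 Å) stacked into dimers at planted
  (distance, twist, tilt) centers (3.5 Å, −40°; 4.2 Å, 5°, 25°;
  5.0 Å, −40°, 50°) with 0.10 Å Cartesian noise and cluster sizes
  12/5/3 by default.  The centers span the experimentally relevant
  3.5–5 Å stacking range and are separated by ≳0.15 nm RMSD, well
  beyond the default clustering cutoff, so the planted families are
  recoverable by construction rather than by luck.  Atom-group
  selections (metal and ring indices per fragment) are emitted alongside
  the coordinates.

Limits of realism: rigid fragments (no intramolecular distortion in the
trajectory), isotropic Gaussian noise, point-count far below a real
phthalocyanine (57 atoms), and the distance→coupling map used in the
examples is an illustrative point-dipole 1/d³ scaling, not a computed
diabatic coupling.

## 7. Serialization and CLI

Models round-trip bit-exactly through JSON or YAML (`save_hamiltonian` /
`load_hamiltonian`); unknown keys anywhere in the document are rejected
by name.  A reserved `meta` key `numerical_differentiation_delta`
records the finite-difference step when gradients come from numerical
differentiation; `gradients_from_csv` ingests tabulated gradients.
Propagation results use HDF5; spectra use CSV plus a JSON sidecar of
parameters.

The `lvcspec` CLI exposes each stage (`synth`, `spectrum`,
`populations`, `hems`, `cluster`, `descriptors`, `correlate`,
`average`) and a `run` driver that validates a YAML/JSON pipeline
config (unknown keys rejected by name), executes the stages in order
and writes a manifest with the config's SHA-256, package version, seed
and per-artifact checksums for provenance.

## 8. Limitations

* Zero temperature throughout; no thermal occupation of vibrations.
* Harmonic diagonal potentials and strictly linear couplings; no
  quadratic (mode-mixing/Duschinsky) diabatic terms beyond what the
  effective-mode W′ introduces within the model.
* Shape-only spectra: the ω prefactor and condensed-phase local-field
  factors are left to the caller.
* The product basis grows exponentially in mode count; large mode
  spaces must go through the effective-mode reduction, whose truncation
  is controlled but approximate beyond short times.
* Conformational sampling is consumed, not generated: trajectories come
  from external MD (or the synthetic generator); no force field is
  included.
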