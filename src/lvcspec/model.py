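"""Linear vibronic coupling (LVC) Hamiltonians for chromophore monomers and
stacked dimers.

The model couples a set of diabatic electronic states through a shared set of
harmonic ground-state normal modes ``q`` (dimensionless).  The potential is

    V_ii(q) = E_ii(0) + 1/2 q^T W q + lambda_ii . q
    V_ij(q) = E_ij(0) + lambda_ij . q          (i != j)

where ``W`` is the (normally diagonal) frequency matrix of the ground-state
modes, ``lambda_ii`` are diabatic gradients at the reference geometry and the
inter-state terms are constant electronic couplings, except for Jahn-Teller
pairs where the linear term dominates and the constant vanishes.

Dimer Hamiltonians are assembled from two monomer fragments: four local
excitations (LE) whose gradients are block-padded with zeros, and four
charge-transfer (CT) states whose gradients are concatenated from the ionic
(cation/anion) fragment gradients.  CT states carry no transition dipole from
the ground state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import HARTREE_EV

__all__ = [
    "ModeBasis",
    "DiabaticState",
    "InterStateCoupling",
    "LVCHamiltonian",
    "FragmentData",
    "AdiabaticStateSet",
    "DIMER_STATE_LABELS",
    "COUPLING_CLASSES",
    "evaluate_diabatic_potential",
    "assemble_dimer_hamiltonian",
    "adiabatic_analysis",
    "diabatic_minimum",
    "toggle_couplings",
    "classify_coupling",
]

#: canonical ordering of the eight dimer diabatic states
DIMER_STATE_LABELS = (
    "L1", "L1p", "L2", "L2p",
    "CT12", "CT12p", "CT21", "CT21p",
)

#: recognised inter-state coupling classes for toggling experiments
COUPLING_CLASSES = frozenset({"LE-LE", "LE-CT", "CT-CT", "JT"})


class LVCError(ValueError):
    """Raised on inconsistent LVC model input."""


@dataclass(frozen=True)
class ModeBasis:
    """Ground-state normal modes: frequencies ``w_a`` in eV, one per
    dimensionless coordinate."""

    frequencies: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        freq = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        object.__setattr__(self, "frequencies", freq)
        if freq.ndim != 1 or freq.size < 1:
            raise LVCError("mode frequencies must be a non-empty 1-D vector")
        if np.any(freq <= 0):
            raise LVCError("all mode frequencies must be positive")
        if self.labels is not None and len(self.labels) != freq.size:
            raise LVCError("mode labels must match the number of modes")

    @property
    def count(self) -> int:
        return int(self.frequencies.size)


@dataclass(frozen=True)
class DiabaticState:
    """One diabatic electronic state.

    ``character`` is "LE" (local excitation, may carry a transition dipole)
    or "CT" (charge transfer, dark from the ground state by construction).
    ``energy0`` is the vertical diabatic energy E_ii(0) in eV, ``gradient``
    the reference-geometry gradient lambda_ii (eV per dimensionless unit),
    ``dipole`` the Condon transition dipole mu_gi in atomic units.
    """

    label: str
    character: str
    energy0: float
    gradient: np.ndarray
    dipole: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.character not in ("LE", "CT"):
            raise LVCError(f"unknown state character {self.character!r}")
        grad = np.atleast_1d(np.asarray(self.gradient, dtype=float))
        dip = np.asarray(self.dipole, dtype=float).reshape(3)
        object.__setattr__(self, "gradient", grad)
        object.__setattr__(self, "dipole", dip)
        if self.character == "CT" and np.linalg.norm(dip) != 0.0:
            raise LVCError(f"CT state {self.label!r} must have zero dipole")


@dataclass(frozen=True)
class InterStateCoupling:
    """Coupling between diabatic states ``pair = (i, j)`` with ``i < j``:
    constant part E_ij(0) in eV, optional linear vector lambda_ij (present
    only for Jahn-Teller pairs, where it is the leading term)."""

    pair: tuple[int, int]
    constant: float = 0.0
    linear: np.ndarray | None = None

    def __post_init__(self):
        i, j = self.pair
        if i == j:
            raise LVCError("coupling pair must reference two distinct states")
        if i > j:
            object.__setattr__(self, "pair", (j, i))
        if self.linear is not None:
            lin = np.atleast_1d(np.asarray(self.linear, dtype=float))
            object.__setattr__(self, "linear", lin)


@dataclass(frozen=True)
class LVCHamiltonian:
    """Full LVC model: modes, diabatic states and inter-state couplings.

    ``frequency_matrix`` is an optional dense symmetric matrix W replacing
    the diagonal diag(w); it is produced by the hierarchical effective-mode
    transformation, which introduces bilinear inter-mode couplings.
    """

    modes: ModeBasis
    states: tuple[DiabaticState, ...]
    couplings: tuple[InterStateCoupling, ...] = ()
    frequency_matrix: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "couplings", tuple(self.couplings))
        n = self.modes.count
        for s in self.states:
            if s.gradient.size != n:
                raise LVCError(
                    f"state {s.label!r}: gradient length {s.gradient.size} "
                    f"!= mode count {n}")
        seen = set()
        for c in self.couplings:
            i, j = c.pair
            if not (0 <= i < self.n_states and 0 <= j < self.n_states):
                raise LVCError(f"coupling pair {c.pair} out of range")
            if c.pair in seen:
                raise LVCError(f"duplicate coupling for pair {c.pair}")
            seen.add(c.pair)
            if c.linear is not None and c.linear.size != n:
                raise LVCError(f"coupling {c.pair}: linear vector length "
                               f"{c.linear.size} != mode count {n}")
        if self.frequency_matrix is not None:
            W = np.asarray(self.frequency_matrix, dtype=float)
            if W.shape != (n, n):
                raise LVCError("frequency matrix must be N x N")
            if not np.allclose(W, W.T, atol=1e-12):
                raise LVCError("frequency matrix must be symmetric")
            object.__setattr__(self, "frequency_matrix", W)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_modes(self) -> int:
        return self.modes.count

    @property
    def W(self) -> np.ndarray:
        """Dense frequency matrix (diagonal unless HEMS-transformed)."""
        if self.frequency_matrix is not None:
            return self.frequency_matrix
        return np.diag(self.modes.frequencies)

    def coupling_for(self, i: int, j: int) -> InterStateCoupling | None:
        key = (min(i, j), max(i, j))
        for c in self.couplings:
            if c.pair == key:
                return c
        return None

    @property
    def energies0(self) -> np.ndarray:
        return np.array([s.energy0 for s in self.states])

    @property
    def gradients(self) -> np.ndarray:
        """(n_states, n_modes) stack of diabatic gradients."""
        return np.array([s.gradient for s in self.states])

    @property
    def dipoles(self) -> np.ndarray:
        return np.array([s.dipole for s in self.states])

    def electronic_matrix(self) -> np.ndarray:
        """Constant part of V: diag(E_ii(0)) plus E_ij(0) off-diagonals."""
        V0 = np.diag(self.energies0)
        for c in self.couplings:
            i, j = c.pair
            V0[i, j] = V0[j, i] = c.constant
        return V0


@dataclass(frozen=True)
class FragmentData:
    """Monomer-level quantities entering the dimer assembly.

    ``grad_le`` / ``grad_le2`` are the |L> and |L'> diabatic gradients g, g';
    ``jt_linear`` is the Jahn-Teller linear coupling vector between them;
    ``grad_cation``, ``grad_anion``, ``grad_anion2`` are the ionic-species
    gradients used for CT-state gradients; ``ct_energy`` / ``ct_energy2`` are
    the vertical energies of the CT states with the hole on this fragment and
    the transferred electron in the lower / higher acceptor orbital.
    """

    modes: ModeBasis
    e_le: float
    e_le2: float
    grad_le: np.ndarray
    grad_le2: np.ndarray
    jt_linear: np.ndarray
    grad_cation: np.ndarray
    grad_anion: np.ndarray
    grad_anion2: np.ndarray
    dipole_le: np.ndarray
    dipole_le2: np.ndarray
    ct_energy: float
    ct_energy2: float

    def __post_init__(self):
        n = self.modes.count
        for name in ("grad_le", "grad_le2", "jt_linear", "grad_cation",
                     "grad_anion", "grad_anion2"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if v.size != n:
                raise LVCError(f"fragment {name} must have length {n}")
            object.__setattr__(self, name, v)
        for name in ("dipole_le", "dipole_le2"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), float).reshape(3))


@dataclass(frozen=True)
class AdiabaticStateSet:
    """Eigenstates of V(q): energies (eV, ascending), orthonormal
    eigenvectors over the diabatic basis (columns), adiabatic transition
    dipoles, oscillator strengths and LE/CT percentage composition."""

    q: np.ndarray
    energies: np.ndarray
    eigenvectors: np.ndarray
    dipoles: np.ndarray
    oscillator_strengths: np.ndarray
    composition: np.ndarray  # (n_states, 2): % LE, % CT


def evaluate_diabatic_potential(H: LVCHamiltonian, q: Sequence[float]) -> np.ndarray:
    """Diabatic potential matrix V(q) in eV at dimensionless coordinates q."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if q.size != H.n_modes:
        raise LVCError(f"coordinate vector length {q.size} != {H.n_modes}")
    harm = 0.5 * q @ H.W @ q
    V = H.electronic_matrix().copy()
    idx = np.arange(H.n_states)
    V[idx, idx] += harm + H.gradients @ q
    for c in H.couplings:
        if c.linear is not None:
            i, j = c.pair
            V[i, j] += c.linear @ q
            V[j, i] = V[i, j]
    return V


def assemble_dimer_hamiltonian(
    fragA: FragmentData,
    fragB: FragmentData,
    constant_couplings: np.ndarray,
    meta: dict | None = None,
) -> LVCHamiltonian:
    """Build the 8-state dimer LVC Hamiltonian from two monomer fragments.

    State order: |L1>, |L1'>, |L2>, |L2'>, |CT(1->2)>, |CT'(1->2)>,
    |CT(2->1)>, |CT'(2->1)>.  Dimer coordinates are q_dim = {q1, q2}; LE
    gradients are block-padded with zeros, CT gradients concatenate the
    cation gradient (hole fragment) with the anion gradient (electron
    fragment).  All inter-state couplings are constant except the two
    intra-monomer Jahn-Teller pairs, which carry the monomer JT linear
    vector and a zero constant.

    ``constant_couplings`` is the 8 x 8 symmetric zero-diagonal matrix of
    E_ij(0); entries on the JT pairs (0,1) and (2,3) are ignored (forced 0).
    """
    if fragA.modes.count != fragB.modes.count:
        raise LVCError("fragments must share the mode count")
    C = np.asarray(constant_couplings, dtype=float)
    if C.shape != (8, 8):
        raise LVCError("constant_couplings must be 8 x 8")
    if not np.allclose(C, C.T, atol=1e-12):
        raise LVCError("constant_couplings must be symmetric")
    if np.any(np.abs(np.diag(C)) > 0):
        raise LVCError("constant_couplings must have zero diagonal")

    n = fragA.modes.count
    z = np.zeros(n)
    freqs = np.concatenate([fragA.modes.frequencies, fragB.modes.frequencies])
    modes = ModeBasis(freqs)

    def pad1(v):
        return np.concatenate([v, z])

    def pad2(v):
        return np.concatenate([z, v])

    states = (
        DiabaticState("L1", "LE", fragA.e_le, pad1(fragA.grad_le), fragA.dipole_le),
        DiabaticState("L1p", "LE", fragA.e_le2, pad1(fragA.grad_le2), fragA.dipole_le2),
        DiabaticState("L2", "LE", fragB.e_le, pad2(fragB.grad_le), fragB.dipole_le),
        DiabaticState("L2p", "LE", fragB.e_le2, pad2(fragB.grad_le2), fragB.dipole_le2),
        DiabaticState("CT12", "CT", fragA.ct_energy,
                      np.concatenate([fragA.grad_cation, fragB.grad_anion])),
        DiabaticState("CT12p", "CT", fragA.ct_energy2,
                      np.concatenate([fragA.grad_cation, fragB.grad_anion2])),
        DiabaticState("CT21", "CT", fragB.ct_energy,
                      np.concatenate([fragA.grad_anion, fragB.grad_cation])),
        DiabaticState("CT21p", "CT", fragB.ct_energy2,
                      np.concatenate([fragA.grad_anion2, fragB.grad_cation])),
    )

    jt_pairs = {(0, 1), (2, 3)}
    couplings = [
        InterStateCoupling((0, 1), 0.0, pad1(fragA.jt_linear)),
        InterStateCoupling((2, 3), 0.0, pad2(fragB.jt_linear)),
    ]
    for i in range(8):
        for j in range(i + 1, 8):
            if (i, j) in jt_pairs:
                continue
            if C[i, j] != 0.0:
                couplings.append(InterStateCoupling((i, j), C[i, j]))

    return LVCHamiltonian(modes, states, tuple(couplings), meta=dict(meta or {}))


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude component of each
    eigenvector is made positive (ties broken by lowest index)."""
    out = vecs.copy()
    for k in range(out.shape[1]):
        idx = int(np.argmax(np.abs(out[:, k])))
        if out[idx, k] < 0:
            out[:, k] = -out[:, k]
    return out


def adiabatic_analysis(
    H: LVCHamiltonian,
    q: Sequence[float] | None = None,
    oscillator_convention: bool = True,
) -> AdiabaticStateSet:
    """Diagonalize V(q) (default: the Franck-Condon point q = 0).

    Adiabatic dipoles are eigenvector-weighted sums of the diabatic (Condon)
    dipoles; oscillator strengths use f = (2/3) dE[hartree] |mu[a.u.]|^2
    unless ``oscillator_convention`` is False, in which case |mu|^2 itself is
    reported.  Composition columns give percent LE / percent CT character.
    """
    if q is None:
        q = np.zeros(H.n_modes)
    V = evaluate_diabatic_potential(H, q)
    evals, evecs = np.linalg.eigh(V)
    evecs = _fix_eigenvector_signs(evecs)
    dip = evecs.T @ H.dipoles  # (n_states, 3)
    mu2 = np.sum(dip**2, axis=1)
    if oscillator_convention:
        f = (2.0 / 3.0) * (evals / HARTREE_EV) * mu2
    else:
        f = mu2
    is_le = np.array([s.character == "LE" for s in H.states], dtype=float)
    w = evecs**2
    pct_le = 100.0 * (w * is_le[:, None]).sum(axis=0)
    comp = np.column_stack([pct_le, 100.0 - pct_le])
    return AdiabaticStateSet(
        q=np.atleast_1d(np.asarray(q, float)),
        energies=evals,
        eigenvectors=evecs,
        dipoles=dip,
        oscillator_strengths=f,
        composition=comp,
    )


def diabatic_minimum(H: LVCHamiltonian, i: int) -> tuple[np.ndarray, float, float]:
    """Minimum of the i-th diabatic surface.

    Returns (q_min, E_min, E_reorg) with q_min = -W^-1 lambda_ii,
    E_reorg = 1/2 lambda^T W^-1 lambda and E_min = E_ii(0) - E_reorg.
    For diagonal W this is q_min,a = -lambda_a / w_a and
    E_reorg = sum_a lambda_a^2 / (2 w_a).
    """
    s = H.states[i]
    q_min = -np.linalg.solve(H.W, s.gradient)
    e_reorg = -0.5 * s.gradient @ q_min
    return q_min, s.energy0 - e_reorg, e_reorg


def classify_coupling(H: LVCHamiltonian, c: InterStateCoupling) -> str:
    """Class label for one inter-state coupling: JT when a linear vector is
    present, otherwise LE-LE / LE-CT / CT-CT by state characters."""
    if c.linear is not None and np.any(c.linear != 0):
        return "JT"
    i, j = c.pair
    chars = sorted([H.states[i].character, H.states[j].character])
    return "-".join(chars) if chars != ["CT", "LE"] else "LE-CT"


def toggle_couplings(H: LVCHamiltonian, classes: Sequence[str]) -> LVCHamiltonian:
    """Copy of H keeping only inter-state couplings in the selected classes
    (subset of {"LE-LE", "LE-CT", "CT-CT", "JT"}); intra-state terms are
    untouched.  Mirrors the coupling-class switching experiments used to
    decompose aggregation effects on the spectrum."""
    classes = set(classes)
    unknown = classes - COUPLING_CLASSES
    if unknown:
        raise LVCError(f"unknown coupling classes: {sorted(unknown)}")
    kept = tuple(c for c in H.couplings if classify_coupling(H, c) in classes)
    return replace(H, couplings=kept)
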