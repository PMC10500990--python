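"""Exact-basis wavepacket propagation on coupled LVC surfaces.

The nuclear wavepacket is expanded in a product harmonic-oscillator number
basis (one ladder per mode) tensored with the diabatic electronic basis.
The Hamiltonian is sparse in this basis: positional couplings q_a connect
n <-> n +/- 1 and bilinear frequency couplings W_ab (a != b, produced by the
effective-mode transformation) act as number-conserving hops a+_a a_b.

The zero of energy is the ground vibrational state of the electronic ground
state, so the harmonic reference enters as H0 = sum_ab W_ab a+_a a_b with no
zero-point constant; propagated correlation functions then match the analytic
adiabatic (FC|VG) limit, phase included.

Propagation is unitary: a short-iterative Lanczos (Krylov) integrator with a
per-step error estimate, or exact diagonalization for small dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .constants import HBAR_EVFS
from .model import LVCHamiltonian, LVCError

__all__ = [
    "ProductBasisSpec",
    "PropagationResult",
    "build_basis",
    "build_hamiltonian_matrix",
    "propagate",
    "converged_propagation",
    "populations_in_combination_basis",
    "ct_population_summary",
]

DEFAULT_DIMENSION_CAP = 5_000_000


class PropagationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ProductBasisSpec:
    """Product number-state basis: ``levels[a] = n_max,a + 1`` states per
    mode, total dimension n_states * prod(levels)."""

    n_states: int
    levels: tuple[int, ...]
    cap: int = DEFAULT_DIMENSION_CAP

    def __post_init__(self):
        if any(l < 1 for l in self.levels):
            raise LVCError("each mode needs at least one basis level")
        if self.dimension > self.cap:
            raise LVCError(
                f"basis dimension {self.dimension} exceeds cap {self.cap}; "
                "reduce n_max or truncate the Hamiltonian with the "
                "hierarchical effective-mode transform (lvcspec.hierarchy)")

    @property
    def n_modes(self) -> int:
        return len(self.levels)

    @property
    def n_vib(self) -> int:
        return int(np.prod(self.levels, dtype=np.int64))

    @property
    def dimension(self) -> int:
        return self.n_states * self.n_vib


def build_basis(
    H: LVCHamiltonian,
    n_max: int | Sequence[int] = 10,
    cap: int = DEFAULT_DIMENSION_CAP,
) -> ProductBasisSpec:
    """Product basis for ``H`` with per-mode maximum quanta ``n_max``."""
    if np.isscalar(n_max):
        levels = tuple([int(n_max) + 1] * H.n_modes)
    else:
        n_max = list(n_max)
        if len(n_max) != H.n_modes:
            raise LVCError("n_max must be scalar or one entry per mode")
        levels = tuple(int(n) + 1 for n in n_max)
    return ProductBasisSpec(H.n_states, levels, cap)


def _mode_operators(levels: Sequence[int]):
    """Vibrational-space sparse operators: returns (q_ops, hop(a, b) builder,
    number_ops) acting on the full product space."""
    n_modes = len(levels)
    eye = [sp.identity(l, format="csr") for l in levels]
    a_ops = []
    for l in levels:
        data = np.sqrt(np.arange(1, l))
        a_ops.append(sp.diags(data, offsets=1, shape=(l, l), format="csr"))

    def lift(op, mode):
        mats = [eye[m] if m != mode else op for m in range(n_modes)]
        out = mats[0]
        for m in mats[1:]:
            out = sp.kron(out, m, format="csr")
        return out

    q_ops = []
    n_ops = []
    adag_full = []
    a_full = []
    for m in range(n_modes):
        a = a_ops[m]
        adag = a.T
        q = (a + adag) / np.sqrt(2.0)
        q_ops.append(lift(q, m))
        n_ops.append(lift(adag @ a, m))
        a_full.append(lift(a, m))
        adag_full.append(lift(adag, m))
    return q_ops, n_ops, a_full, adag_full


def build_hamiltonian_matrix(
    H: LVCHamiltonian, basis: ProductBasisSpec
) -> sp.csr_matrix:
    """Sparse real-symmetric Hamiltonian matrix in the product basis
    (electronic index slowest)."""
    if basis.n_states != H.n_states or basis.n_modes != H.n_modes:
        raise LVCError("basis does not match the Hamiltonian dimensions")
    q_ops, n_ops, a_full, adag_full = _mode_operators(basis.levels)
    W = H.W
    n_vib = basis.n_vib

    # shared vibrational reference (zero-point energy subtracted)
    H0 = sp.csr_matrix((n_vib, n_vib))
    for a in range(H.n_modes):
        H0 = H0 + W[a, a] * n_ops[a]
        for b in range(a + 1, H.n_modes):
            if W[a, b] != 0.0:
                hop = adag_full[a] @ a_full[b]
                H0 = H0 + W[a, b] * (hop + hop.T)

    blocks: dict[tuple[int, int], sp.csr_matrix] = {}
    eye_vib = sp.identity(n_vib, format="csr")
    for i, s in enumerate(H.states):
        blk = H0 + s.energy0 * eye_vib
        for a in np.nonzero(s.gradient)[0]:
            blk = blk + s.gradient[a] * q_ops[a]
        blocks[(i, i)] = blk
    for c in H.couplings:
        i, j = c.pair
        blk = sp.csr_matrix((n_vib, n_vib))
        if c.constant != 0.0:
            blk = blk + c.constant * eye_vib
        if c.linear is not None:
            for a in np.nonzero(c.linear)[0]:
                blk = blk + c.linear[a] * q_ops[a]
        if blk.nnz:
            blocks[(i, j)] = blk

    grid = [[None] * H.n_states for _ in range(H.n_states)]
    for (i, j), blk in blocks.items():
        grid[i][j] = blk
        if i != j:
            grid[j][i] = blk.T
    return sp.bmat(grid, format="csr")


@dataclass
class PropagationResult:
    """Time-resolved output of one wavepacket propagation.

    ``correlations[j, k]`` is phi_ji(t_k) = <d_j; 0| psi(t_k)> for the run's
    initial state i; ``populations[i, k]`` the diabatic populations P_i(t_k);
    ``occupancy[a]`` the largest population found in the top number state of
    mode a over the run (basis-convergence diagnostic).
    """

    times: np.ndarray
    correlations: np.ndarray
    populations: np.ndarray
    norm: np.ndarray
    energy: np.ndarray
    occupancy: np.ndarray
    initial: np.ndarray
    basis: ProductBasisSpec
    state_labels: tuple[str, ...]
    state_characters: tuple[str, ...]
    snapshots: np.ndarray | None = None
    snapshot_times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("correlations", data=self.correlations)
            f.create_dataset("populations", data=self.populations)
            f.create_dataset("norm", data=self.norm)
            f.create_dataset("energy", data=self.energy)
            f.create_dataset("occupancy", data=self.occupancy)
            f.create_dataset("initial", data=self.initial)
            if self.snapshots is not None:
                f.create_dataset("snapshots", data=self.snapshots)
                f.create_dataset("snapshot_times", data=self.snapshot_times)
            f.attrs["state_labels"] = list(self.state_labels)
            f.attrs["state_characters"] = list(self.state_characters)
            f.attrs["levels"] = list(self.basis.levels)

    @classmethod
    def from_hdf5(cls, path) -> "PropagationResult":
        import h5py

        with h5py.File(path, "r") as f:
            levels = tuple(int(l) for l in f.attrs["levels"])
            labels = tuple(str(s) for s in f.attrs["state_labels"])
            chars = tuple(str(s) for s in f.attrs["state_characters"])
            kw = {}
            if "snapshots" in f:
                kw["snapshots"] = f["snapshots"][...]
                kw["snapshot_times"] = f["snapshot_times"][...]
            return cls(
                times=f["times"][...],
                correlations=f["correlations"][...],
                populations=f["populations"][...],
                norm=f["norm"][...],
                energy=f["energy"][...],
                occupancy=f["occupancy"][...],
                initial=f["initial"][...],
                basis=ProductBasisSpec(len(labels), levels),
                state_labels=labels,
                state_characters=chars,
                **kw,
            )

    def populations_to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.populations.T, columns=list(self.state_labels))
        df.insert(0, "time_fs", self.times)
        df.to_csv(path, index=False)


def _initial_vector(H: LVCHamiltonian, basis: ProductBasisSpec,
                    initial) -> np.ndarray:
    """|psi(0)> = sum_i c_i |d_i; 0>, from a state index or a coefficient
    vector over the diabatic basis (normalized)."""
    n_vib = basis.n_vib
    psi = np.zeros(basis.dimension, dtype=complex)
    if np.isscalar(initial):
        c = np.zeros(H.n_states)
        c[int(initial)] = 1.0
    else:
        c = np.asarray(initial, dtype=complex)
        if c.size != H.n_states:
            raise LVCError("initial combination vector length mismatch")
        nrm = np.linalg.norm(c)
        if nrm == 0:
            raise LVCError("initial vector must be nonzero")
        c = c / nrm
    for i in range(H.n_states):
        psi[i * n_vib] = c[i]
    return psi


def _lanczos_step(Hmat, psi, dt, order, tol, hbar=HBAR_EVFS):
    """One short-iterative Lanczos step exp(-i H dt / hbar) psi.

    Returns the propagated vector; raises if the Krylov error estimate does
    not meet ``tol`` at the maximum order.
    """
    dim = psi.shape[0]
    m = min(order, dim)
    V = np.empty((m, dim), dtype=complex)
    alpha = np.zeros(m)
    beta = np.zeros(m)
    nrm0 = np.linalg.norm(psi)
    V[0] = psi / nrm0
    w = Hmat @ V[0]
    alpha[0] = np.real(np.vdot(V[0], w))
    w = w - alpha[0] * V[0]
    k_used = 1
    for k in range(1, m):
        beta[k - 1] = np.linalg.norm(w)
        if beta[k - 1] < 1e-14:
            break
        V[k] = w / beta[k - 1]
        # full reorthogonalization for numerical stability
        proj = V[:k].conj() @ V[k]
        V[k] -= proj @ V[:k]
        V[k] /= np.linalg.norm(V[k])
        w = Hmat @ V[k]
        alpha[k] = np.real(np.vdot(V[k], w))
        w = w - alpha[k] * V[k] - beta[k - 1] * V[k - 1]
        k_used = k + 1
    T = np.diag(alpha[:k_used])
    for k in range(k_used - 1):
        T[k, k + 1] = T[k + 1, k] = beta[k]
    evals, evecs = np.linalg.eigh(T)
    phase = np.exp(-1j * evals * dt / hbar)
    small = evecs @ (phase * evecs[0].conj())
    if k_used == m and k_used > 2:
        # magnitude of the last Krylov component bounds the step error
        err = abs(small[-1])
        if err > tol:
            raise PropagationError(
                f"Krylov step error estimate {err:.2e} exceeds tolerance "
                f"{tol:.0e}; reduce dt or raise the Krylov order")
    return (small @ V[:k_used]) * nrm0


def _top_level_occupancy(psi_el, levels):
    """Per-mode population of the highest number state, summed over all
    electronic states and the other modes.  psi_el: (n_states, n_vib)."""
    dens = np.abs(psi_el) ** 2
    dens_modes = dens.reshape((psi_el.shape[0],) + tuple(levels))
    occ = np.empty(len(levels))
    for a in range(len(levels)):
        occ[a] = np.take(dens_modes, -1, axis=1 + a).sum()
    return occ


def propagate(
    H: LVCHamiltonian,
    basis: ProductBasisSpec,
    initial,
    t_max: float = 100.0,
    dt: float = 0.1,
    method: str = "auto",
    exact_cap: int = 4000,
    krylov_order: int = 15,
    krylov_tol: float = 1e-9,
    snapshot_stride: float | None = None,
) -> PropagationResult:
    """Propagate |d_i; 0> (or a diabatic combination) under H for ``t_max``
    fs, recording correlation functions, diabatic populations, norm, energy
    and basis-occupancy diagnostics on the grid ``t = 0, dt, 2 dt, ...``.

    ``method`` is "exact" (dense diagonalization, dimension <= ``exact_cap``),
    "krylov" (short-iterative Lanczos) or "auto".  ``snapshot_stride`` (fs)
    requests storage of the full wavepacket at decimated times, needed by
    :func:`populations_in_combination_basis`.
    """
    if dt <= 0:
        raise LVCError("dt must be positive")
    Hmat = build_hamiltonian_matrix(H, basis)
    dim = basis.dimension
    if method == "auto":
        method = "exact" if dim <= exact_cap else "krylov"
    psi0 = _initial_vector(H, basis, initial)
    n_steps = int(round(t_max / dt))
    times = np.arange(n_steps + 1) * dt
    n_vib = basis.n_vib
    n_states = H.n_states
    levels = basis.levels

    snap_every = None
    if snapshot_stride is not None:
        snap_every = max(1, int(round(snapshot_stride / dt)))

    corr = np.empty((n_states, times.size), dtype=complex)
    pops = np.empty((n_states, times.size))
    norm = np.empty(times.size)
    energy = np.empty(times.size)
    occupancy = np.zeros(H.n_modes)
    snaps, snap_times = [], []

    def record(k, psi):
        psi_el = psi.reshape(n_states, n_vib)
        corr[:, k] = psi_el[:, 0]
        pops[:, k] = np.sum(np.abs(psi_el) ** 2, axis=1)
        norm[k] = np.linalg.norm(psi)
        energy[k] = np.real(np.vdot(psi, Hmat @ psi))
        np.maximum(occupancy, _top_level_occupancy(psi_el, levels),
                   out=occupancy)
        if snap_every is not None and k % snap_every == 0:
            snaps.append(psi_el.copy())
            snap_times.append(times[k])

    if method == "exact":
        if dim > exact_cap:
            raise LVCError(
                f"dimension {dim} too large for exact diagonalization "
                f"(cap {exact_cap}); use method='krylov'")
        evals, evecs = np.linalg.eigh(Hmat.toarray())
        c0 = evecs.conj().T @ psi0
        # chunked reconstruction keeps peak memory bounded
        chunk = max(1, int(2e7 // max(dim, 1)))
        for start in range(0, times.size, chunk):
            tt = times[start:start + chunk]
            phases = np.exp(-1j * np.outer(evals, tt) / HBAR_EVFS)
            Psi = evecs @ (c0[:, None] * phases)
            for k in range(tt.size):
                record(start + k, Psi[:, k])
    elif method == "krylov":
        psi = psi0.copy()
        record(0, psi)
        for k in range(1, times.size):
            psi = _lanczos_step(Hmat, psi, dt, krylov_order, krylov_tol)
            record(k, psi)
    else:
        raise LVCError(f"unknown propagation method {method!r}")

    result = PropagationResult(
        times=times,
        correlations=corr,
        populations=pops,
        norm=norm,
        energy=energy,
        occupancy=occupancy,
        initial=np.asarray(_initial_vector(H, basis, initial)
                           .reshape(n_states, n_vib)[:, 0]),
        basis=basis,
        state_labels=tuple(s.label for s in H.states),
        state_characters=tuple(s.character for s in H.states),
        snapshots=np.array(snaps) if snaps else None,
        snapshot_times=np.array(snap_times) if snap_times else None,
        meta={"method": method, "dt": dt},
    )
    return result


def converged_propagation(
    H: LVCHamiltonian,
    initial,
    n_max: int = 10,
    occupancy_tol: float = 1e-6,
    n_max_limit: int = 30,
    **kwargs,
) -> PropagationResult:
    """Propagate with automatic basis enlargement: raise every n_max by 2
    until the top-level occupancy diagnostic drops below ``occupancy_tol``."""
    n = int(n_max)
    while True:
        basis = build_basis(H, n)
        result = propagate(H, basis, initial, **kwargs)
        if result.occupancy.max() < occupancy_tol or n >= n_max_limit:
            if result.occupancy.max() >= occupancy_tol:
                result.meta["occupancy_warning"] = float(result.occupancy.max())
            return result
        n += 2


def populations_in_combination_basis(
    result: PropagationResult, vectors: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Populations of fixed diabatic combinations (e.g. the FC-point
    adiabatic eigenvectors) from stored wavepacket snapshots.

    ``vectors``: (n_states, n_vectors) array with orthonormal columns.
    Returns (snapshot_times, populations[(n_vectors, n_snap)]).  For a
    complete orthonormal set the populations sum to the squared norm.
    """
    if result.snapshots is None:
        raise LVCError("propagation was run without snapshots; pass "
                       "snapshot_stride to propagate()")
    V = np.asarray(vectors, dtype=complex)
    if V.ndim != 2 or V.shape[0] != len(result.state_labels):
        raise LVCError("vectors must be (n_states, n_vectors)")
    G = V.conj().T @ V
    if not np.allclose(G, np.eye(V.shape[1]), atol=1e-8):
        raise LVCError("combination vectors must be orthonormal")
    # amplitude of combination v at each vibrational basis function
    amp = np.einsum("iv,tin->tvn", V.conj().T, result.snapshots)
    pops = np.sum(np.abs(amp) ** 2, axis=2).T
    return result.snapshot_times, pops


def ct_population_summary(
    result: PropagationResult | Sequence[PropagationResult],
    t_query: float = 100.0,
) -> float:
    """Total population on CT-labeled diabatic states at ``t_query`` fs;
    for a list of runs (e.g. initial |L1> and |L1'>) the average is
    returned."""
    if not isinstance(result, PropagationResult):
        vals = [ct_population_summary(r, t_query) for r in result]
        return float(np.mean(vals))
    times = result.times
    if not (times[0] - 1e-9 <= t_query <= times[-1] + 1e-9):
        raise LVCError(f"t_query {t_query} fs outside the recorded grid")
    k = int(np.argmin(np.abs(times - t_query)))
    ct = [i for i, ch in enumerate(result.state_characters) if ch == "CT"]
    return float(result.populations[ct, k].sum()) if ct else 0.0
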