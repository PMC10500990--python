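"""Hierarchical effective-mode selection (HEMS).

An orthogonal coordinate transformation T concentrates all vibronic coupling
(diabatic gradients and linear inter-state couplings) into a leading block of
effective modes.  Subsequent blocks are generated by a block-Lanczos
recursion with the frequency matrix as generator, so that keeping the first
m blocks reproduces the short-time dynamics -- and hence the spectral shape
-- of the full model, with accuracy growing with m.

The transformed Hamiltonian carries a dense symmetric frequency matrix
T^T W T (bilinear inter-mode couplings appear symmetrically in the kinetic
and potential terms in the dimensionless-coordinate convention), which the
propagation module handles natively.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import null_space

from .model import (DiabaticState, InterStateCoupling, LVCHamiltonian,
                    LVCError, ModeBasis)

__all__ = ["EffectiveModeHierarchy", "build_hierarchy", "truncate"]


@dataclass(frozen=True)
class EffectiveModeHierarchy:
    """Orthogonal transformation ``T`` (columns: effective modes, leading
    blocks first, residual uncoupled modes last) and the per-block column
    index lists."""

    T: np.ndarray
    blocks: tuple[np.ndarray, ...]
    n_residual: int
    svd_threshold: float
    requested_depth: int
    truncated_chain: bool  # True when fewer blocks than requested exist

    @property
    def depth(self) -> int:
        return len(self.blocks)

    @property
    def n_effective(self) -> int:
        return sum(len(b) for b in self.blocks)

    def block_columns(self, m_keep: int) -> np.ndarray:
        idx = np.concatenate([self.blocks[k] for k in range(m_keep)]) \
            if m_keep > 0 else np.array([], dtype=int)
        return idx.astype(int)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("T", data=self.T)
            f.attrs["n_residual"] = self.n_residual
            f.attrs["svd_threshold"] = self.svd_threshold
            f.attrs["requested_depth"] = self.requested_depth
            f.attrs["truncated_chain"] = self.truncated_chain
            for k, b in enumerate(self.blocks):
                f.create_dataset(f"block_{k}", data=b)

    @classmethod
    def from_hdf5(cls, path) -> "EffectiveModeHierarchy":
        import h5py

        with h5py.File(path, "r") as f:
            blocks = []
            k = 0
            while f"block_{k}" in f:
                blocks.append(f[f"block_{k}"][...].astype(int))
                k += 1
            return cls(
                T=f["T"][...],
                blocks=tuple(blocks),
                n_residual=int(f.attrs["n_residual"]),
                svd_threshold=float(f.attrs["svd_threshold"]),
                requested_depth=int(f.attrs["requested_depth"]),
                truncated_chain=bool(f.attrs["truncated_chain"]),
            )


def _coupling_vectors(H: LVCHamiltonian) -> np.ndarray:
    """All nonzero lambda vectors (diabatic gradients and linear couplings)
    as columns of an (N, k) matrix."""
    vecs = [s.gradient for s in H.states if np.any(s.gradient != 0)]
    vecs += [c.linear for c in H.couplings
             if c.linear is not None and np.any(c.linear != 0)]
    if not vecs:
        return np.zeros((H.n_modes, 0))
    return np.column_stack(vecs)


def _orthonormal_columns(M: np.ndarray, against: np.ndarray | None,
                         threshold: float) -> np.ndarray:
    """Orthonormal basis of the part of span(M) orthogonal to span(against),
    discarding directions below the relative SVD threshold."""
    if M.shape[1] == 0:
        return M
    # the cut is relative to the scale *before* projection: directions whose
    # residual is pure rounding noise must not survive as spurious blocks
    scale = np.linalg.svd(M, compute_uv=False)[0]
    if against is not None and against.shape[1] > 0:
        M = M - against @ (against.T @ M)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or scale == 0:
        return np.zeros((M.shape[0], 0))
    keep = s > threshold * scale
    return U[:, keep]


def build_hierarchy(
    H: LVCHamiltonian, n_blocks: int, svd_threshold: float = 1e-8
) -> EffectiveModeHierarchy:
    """Build the effective-mode hierarchy of ``H`` to depth ``n_blocks``.

    Block 1 spans all nonzero coupling vectors (SVD with relative threshold
    on singular values); block k+1 is obtained by applying the frequency
    matrix W to block k and orthogonalizing against all earlier blocks.  If
    the chain exhausts before ``n_blocks``, the achieved depth is returned
    with ``truncated_chain`` set.
    """
    if n_blocks < 1:
        raise LVCError("n_blocks must be >= 1")
    N = H.n_modes
    W = H.W
    L = _coupling_vectors(H)
    B1 = _orthonormal_columns(L, None, svd_threshold)
    blocks_mats = []
    if B1.shape[1] > 0:
        blocks_mats.append(B1)
        for _ in range(1, n_blocks):
            prev = blocks_mats[-1]
            allb = np.column_stack(blocks_mats)
            Bk = _orthonormal_columns(W @ prev, allb, svd_threshold)
            # second orthogonalization pass guards against rounding drift
            Bk = _orthonormal_columns(Bk, allb, svd_threshold)
            if Bk.shape[1] == 0:
                break
            blocks_mats.append(Bk)
    truncated = len(blocks_mats) < n_blocks

    if blocks_mats:
        B = np.column_stack(blocks_mats)
        resid = null_space(B.T)
        T = np.column_stack([B, resid]) if resid.shape[1] else B
    else:
        T = np.eye(N)
        resid = T
    # deterministic residual orientation is irrelevant; enforce exact shape
    if T.shape != (N, N):
        raise LVCError("hierarchy transformation is not square; "
                       "coupling vectors may be degenerate beyond tolerance")

    blocks_idx = []
    start = 0
    for Bm in blocks_mats:
        blocks_idx.append(np.arange(start, start + Bm.shape[1]))
        start += Bm.shape[1]
    return EffectiveModeHierarchy(
        T=T,
        blocks=tuple(blocks_idx),
        n_residual=N - start,
        svd_threshold=svd_threshold,
        requested_depth=n_blocks,
        truncated_chain=truncated,
    )


def truncate(
    hier: EffectiveModeHierarchy,
    H: LVCHamiltonian,
    m_keep: int,
    include_residual: bool = False,
) -> LVCHamiltonian:
    """Reduced Hamiltonian over hierarchy blocks 1..m_keep.

    Bilinear frequency couplings among kept modes are retained exactly.
    Block 1 spans every coupling vector, so truncation discards no lambda
    components; what is lost is the bilinear frequency coupling between the
    kept and discarded coordinates, whose Frobenius norm is reported in
    ``meta['dropped_coupling_norm']`` (zero exactly when the kept space is
    W-invariant, i.e. at full depth of an exhausted chain).  With
    ``include_residual`` and ``m_keep`` equal to the full depth the result
    is unitarily equivalent to the input.
    """
    if m_keep > hier.depth:
        raise LVCError(f"m_keep {m_keep} exceeds built depth {hier.depth}")
    cols = hier.block_columns(m_keep)
    if include_residual:
        resid_cols = np.arange(hier.n_effective, hier.T.shape[1])
        cols = np.concatenate([cols, resid_cols]).astype(int)
    Tk = hier.T[:, cols]

    all_cols = np.arange(hier.T.shape[1])
    Td = hier.T[:, np.setdiff1d(all_cols, cols)]
    dropped = float(np.linalg.norm(Tk.T @ H.W @ Td)) if Td.size else 0.0

    meta = dict(H.meta)
    meta.update({"hems_m_keep": int(m_keep),
                 "dropped_coupling_norm": dropped})

    if Tk.shape[1] == 0:
        # no coupled coordinates at all: keep one spectator mode so the
        # model remains well-formed; it is exactly uncoupled
        spect = np.argmin(H.modes.frequencies)
        meta["spectator_mode"] = True
        modes = ModeBasis(np.array([H.modes.frequencies[spect]]))
        states = tuple(
            replace(s, gradient=np.zeros(1)) for s in H.states)
        coups = tuple(
            replace(c, linear=None) for c in H.couplings)
        return LVCHamiltonian(modes, states, coups, meta=meta)

    Wp = Tk.T @ H.W @ Tk
    Wp = 0.5 * (Wp + Wp.T)
    modes = ModeBasis(np.diag(Wp).copy(),
                      labels=tuple(f"eff{k}" for k in range(Tk.shape[1])))
    states = tuple(
        replace(s, gradient=Tk.T @ s.gradient) for s in H.states)
    coups = tuple(
        replace(c, linear=(Tk.T @ c.linear) if c.linear is not None else None)
        for c in H.couplings)
    return LVCHamiltonian(modes, states, coups, frequency_matrix=Wp,
                          meta=meta)
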