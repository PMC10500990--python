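"""Conformational analysis of stacked-dimer trajectories.

Covers trajectory ingestion (multi-model PDB or XYZ via MDAnalysis), the
Daura/GROMOS RMSD clustering with central-structure selection used to pick
representative dimer conformations, the inter-monomer geometry descriptors
(metal-metal distance, inter-ring distance along the ring normal, tilt
angles alpha_1..8 against in-plane reference axes, signed twist beta), and
ordinary least-squares correlations between geometry and electronic
quantities.

Conventions: coordinates and descriptors in Angstrom / degrees; RMSD
matrices and cluster cutoffs in nm (matching the usual 0.10 nm cutoff).
Superposition is unweighted Kabsch on the union of both rings' selected
atoms (configurable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import ANG_PER_NM

__all__ = [
    "MonomerSelection",
    "Selections",
    "ConformerEnsemble",
    "ClusterResult",
    "GeometryDescriptors",
    "read_trajectory",
    "write_xyz",
    "kabsch_rmsd",
    "pairwise_rmsd",
    "daura_cluster",
    "geometry_descriptors",
    "descriptor_table",
    "linear_correlation",
]


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class MonomerSelection:
    """Atom bookkeeping for one macrocycle: ring atoms (plane fit and RMSD
    set), the metal-center index, and four atoms defining the in-plane
    reference axes metal -> atom (the first is the primary axis used for
    the twist angle)."""

    ring: tuple[int, ...]
    metal: int
    axis_atoms: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "ring", tuple(int(i) for i in self.ring))
        object.__setattr__(self, "axis_atoms",
                           tuple(int(i) for i in self.axis_atoms))
        if len(self.ring) < 3:
            raise SelectionError("ring selection needs at least 3 atoms "
                                 "(plane undefined otherwise)")
        if len(self.axis_atoms) != 4:
            raise SelectionError("exactly four reference-axis atoms required")


@dataclass(frozen=True)
class Selections:
    monomer1: MonomerSelection
    monomer2: MonomerSelection

    @property
    def ring_union(self) -> np.ndarray:
        return np.array(self.monomer1.ring + self.monomer2.ring, dtype=int)

    def validate(self, n_atoms: int) -> None:
        for mono in (self.monomer1, self.monomer2):
            all_idx = list(mono.ring) + [mono.metal] + list(mono.axis_atoms)
            for i in all_idx:
                if not (0 <= i < n_atoms):
                    raise SelectionError(
                        f"selection index {i} out of range for {n_atoms} atoms")

    def to_json(self, path) -> None:
        data = {
            "monomer1": {"ring": list(self.monomer1.ring),
                         "metal": self.monomer1.metal,
                         "axis_atoms": list(self.monomer1.axis_atoms)},
            "monomer2": {"ring": list(self.monomer2.ring),
                         "metal": self.monomer2.metal,
                         "axis_atoms": list(self.monomer2.axis_atoms)},
        }
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path) -> "Selections":
        data = json.loads(Path(path).read_text())
        monos = {}
        for key in ("monomer1", "monomer2"):
            if key not in data:
                raise SelectionError(f"selection file missing {key!r}")
            d = data[key]
            if "metal" not in d:
                raise SelectionError(f"{key}: missing metal index")
            monos[key] = MonomerSelection(tuple(d["ring"]), int(d["metal"]),
                                          tuple(d["axis_atoms"]))
        return cls(monos["monomer1"], monos["monomer2"])


@dataclass
class ConformerEnsemble:
    """Cartesian frames (n_frames, n_atoms, 3) in Angstrom plus selections
    and optional per-frame timestamps (arbitrary units, e.g. ns)."""

    coordinates: np.ndarray
    selections: Selections
    elements: tuple[str, ...] | None = None
    timestamps: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise SelectionError("coordinates must be (n_frames, n_atoms, 3)")
        self.selections.validate(self.n_atoms)
        if self.timestamps is None:
            self.timestamps = np.arange(self.n_frames, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


def read_trajectory(path, selections: Selections) -> ConformerEnsemble:
    """Load a multi-frame XYZ or multi-model PDB trajectory."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    u = mda.Universe(str(path))
    frames = [u.atoms.positions.copy() for _ in u.trajectory]
    try:
        elements = tuple(u.atoms.elements)
    except Exception:
        try:
            elements = tuple(u.atoms.names)
        except Exception:
            elements = None
    coords = np.array(frames, dtype=float)
    return ConformerEnsemble(coords, selections, elements=elements)


def write_xyz(path, coordinates: np.ndarray, elements: Sequence[str],
              comment: str = "frame") -> None:
    """Write a multi-frame XYZ trajectory (fixed-point, 1e-3 A precision)."""
    coordinates = np.asarray(coordinates, float)
    if coordinates.ndim == 2:
        coordinates = coordinates[None]
    with open(path, "w") as fh:
        for k, frame in enumerate(coordinates):
            fh.write(f"{len(elements)}\n{comment} {k}\n")
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el} {x:.3f} {y:.3f} {z:.3f}\n")


def kabsch_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Minimum RMSD (Angstrom) between two coordinate sets after optimal
    unweighted rigid superposition (Kabsch)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    C = Xc.T @ Yc
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    diff = Xc @ R - Yc
    return float(np.sqrt((diff**2).sum() / X.shape[0]))


def pairwise_rmsd(ensemble: ConformerEnsemble,
                  atom_indices: np.ndarray | None = None) -> np.ndarray:
    """Symmetric all-pair RMSD matrix in nm over the macrocycle-ring atoms
    (default: union of both rings' selections)."""
    if ensemble.n_frames < 2:
        raise SelectionError("need at least two frames")
    idx = ensemble.selections.ring_union if atom_indices is None \
        else np.asarray(atom_indices, int)
    coords = ensemble.coordinates[:, idx, :]
    n = ensemble.n_frames
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = kabsch_rmsd(coords[i], coords[j]) / ANG_PER_NM
    return M


@dataclass
class ClusterResult:
    """Daura clustering output: per-frame assignment (cluster ids ordered by
    discovery, i.e. descending neighbor count), sizes, population weights
    C^k (exact rationals, also as floats), central-structure frame per
    cluster, and the cutoff used (nm)."""

    assignments: np.ndarray
    sizes: np.ndarray
    weights: np.ndarray
    weight_fractions: tuple[Fraction, ...]
    centrals: np.ndarray
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return self.sizes.size

    def to_json(self, path) -> None:
        data = {
            "cutoff_nm": self.cutoff,
            "sizes": self.sizes.tolist(),
            "weights": self.weights.tolist(),
            "centrals": self.centrals.tolist(),
            "assignments": self.assignments.tolist(),
        }
        Path(path).write_text(json.dumps(data, indent=2))


def daura_cluster(rmsd: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy RMSD neighbor-count clustering (Daura/GROMOS).

    Iteratively: count each remaining frame's neighbors within the cutoff,
    take the frame with the most neighbors (ties: lowest original index) as
    a cluster together with its neighbors, remove them, repeat.  The central
    structure of each cluster minimizes the mean RMSD to the other members.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rmsd = np.asarray(rmsd, float)
    n = rmsd.shape[0]
    within = rmsd <= cutoff
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    sizes, centrals = [], []
    cid = 0
    while remaining.any():
        counts = np.where(remaining,
                          (within & remaining[None, :]).sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax takes the lowest tied index
        members = np.flatnonzero(within[center] & remaining)
        assignments[members] = cid
        # central structure: smallest mean RMSD to the other members
        if members.size == 1:
            centrals.append(int(members[0]))
        else:
            sub = rmsd[np.ix_(members, members)]
            mean_r = sub.sum(axis=1) / (members.size - 1)
            centrals.append(int(members[int(np.argmin(mean_r))]))
        sizes.append(int(members.size))
        remaining[members] = False
        cid += 1
    sizes = np.asarray(sizes, int)
    fracs = tuple(Fraction(int(s), int(n)) for s in sizes)
    weights = np.array([float(f) for f in fracs])
    return ClusterResult(assignments, sizes, weights, fracs,
                         np.asarray(centrals, int), float(cutoff))


@dataclass(frozen=True)
class GeometryDescriptors:
    """Inter-monomer geometry of one frame: d_Zn-Zn and d_P-P in Angstrom,
    eight tilt angles alpha_i in [0, 90] degrees and the signed twist beta
    in degrees.  d_P-P can exceed or undercut d_Zn-Zn when the rings tilt."""

    d_metal_metal: float
    d_ring_ring: float
    alpha: np.ndarray
    beta: float


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the SVD-fit plane through ``points``."""
    centered = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    return Vt[-1]


def geometry_descriptors(
    frame: np.ndarray,
    selections: Selections,
    normal: str = "average",
) -> GeometryDescriptors:
    """Compute the stacking descriptors for one frame.

    ``normal`` selects the reference axis for d_P-P: the ring-1 plane
    normal ("ring1"), ring-2 ("ring2"), or the mean of the two ("average",
    default) -- the rings of real stacks show out-of-plane distortions, so
    the two normals differ slightly.
    """
    frame = np.asarray(frame, float)
    m1 = selections.monomer1
    m2 = selections.monomer2
    r1 = frame[list(m1.ring)]
    r2 = frame[list(m2.ring)]
    zn1 = frame[m1.metal]
    zn2 = frame[m2.metal]
    u = zn2 - zn1
    d_mm = float(np.linalg.norm(u))

    n1 = _plane_normal(r1)
    n2 = _plane_normal(r2)
    # orient both normals along the inter-metal direction
    if d_mm > 0:
        if n1 @ u < 0:
            n1 = -n1
        if n2 @ u < 0:
            n2 = -n2
    if normal == "ring1":
        nref = n1
    elif normal == "ring2":
        nref = n2
    elif normal == "average":
        nref = n1 + n2
        nref = nref / np.linalg.norm(nref)
    else:
        raise SelectionError(f"unknown normal convention {normal!r}")

    # inter-ring distance: mean |projection| of atom-pair displacements
    if len(m1.ring) == len(m2.ring):
        disp = r2 - r1
    else:  # unequal ring sizes: all cross pairs
        disp = (r2[None, :, :] - r1[:, None, :]).reshape(-1, 3)
    d_pp = float(np.mean(np.abs(disp @ nref)))

    # tilt angles: inter-metal vector vs the 8 in-plane reference axes
    alphas = []
    if d_mm == 0:
        raise SelectionError("coincident metal centers; angles undefined")
    uhat = u / d_mm
    for mono in (m1, m2):
        metal = frame[mono.metal]
        for a in mono.axis_atoms:
            axis = frame[a] - metal
            axis = axis / np.linalg.norm(axis)
            c = abs(float(axis @ uhat))
            alphas.append(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    alpha = np.array(alphas)

    # signed twist between the primary in-plane axes about the mean normal
    nmean = n1 + n2
    nmean = nmean / np.linalg.norm(nmean)
    a1 = frame[m1.axis_atoms[0]] - zn1
    a2 = frame[m2.axis_atoms[0]] - zn2
    p1 = a1 - (a1 @ nmean) * nmean
    p2 = a2 - (a2 @ nmean) * nmean
    beta = float(np.degrees(np.arctan2(nmean @ np.cross(p1, p2), p1 @ p2)))

    return GeometryDescriptors(d_mm, d_pp, alpha, beta)


def descriptor_table(ensemble: ConformerEnsemble, normal: str = "average"):
    """Per-frame descriptor DataFrame (one row per frame)."""
    import pandas as pd

    rows = []
    for k in range(ensemble.n_frames):
        g = geometry_descriptors(ensemble.coordinates[k],
                                 ensemble.selections, normal=normal)
        row = {"frame": k, "time": float(ensemble.timestamps[k]),
               "d_metal_metal_A": g.d_metal_metal,
               "d_ring_ring_A": g.d_ring_ring, "beta_deg": g.beta}
        for i, a in enumerate(g.alpha, start=1):
            row[f"alpha{i}_deg"] = float(a)
        rows.append(row)
    return pd.DataFrame(rows)


def linear_correlation(x: Sequence[float], y: Sequence[float]
                       ) -> tuple[float, float, float]:
    """Ordinary least squares y = slope x + intercept and the coefficient of
    determination R^2 = 1 - SS_res / SS_tot.

    A constant y returns R^2 = 0 by convention (the fit explains nothing);
    a constant x raises (the fit is undefined).
    """
    from scipy.stats import linregress

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the linear fit is undefined")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
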