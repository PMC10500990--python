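"""Deterministic, seeded generators for every input class of the protocol.

These build the study conditions end-to-end without external data: displaced
single-state monomers (Poisson progressions), two-state Jahn-Teller
monomers (E x e conical intersections), the 4 LE + 4 CT stacked-dimer
template with exciton / charge-transfer / Jahn-Teller couplings, random LVC
models for property testing, and rigid two-ring stacked trajectories with
planted cluster structure for the conformational analysis.

All randomness flows through one explicit ``numpy`` generator seeded per
call; identical arguments give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conformations import ConformerEnsemble, MonomerSelection, Selections
from .model import (DiabaticState, FragmentData, InterStateCoupling,
                    LVCHamiltonian, ModeBasis, assemble_dimer_hamiltonian)

__all__ = [
    "make_displaced_monomer",
    "make_jt_monomer",
    "make_kasha_ct_dimer",
    "make_random_lvc",
    "make_stacked_trajectory",
    "ring_template",
    "DEFAULT_CLUSTER_CENTERS",
]

#: planted conformer centers (d_stack / A, twist / deg, tilt / deg) spanning
#: the stacking distances and restricted twist range seen for solvated
#: phthalocyanine dimers
DEFAULT_CLUSTER_CENTERS = ((3.5, -40.0, 0.0), (4.2, 5.0, 25.0),
                           (5.0, -40.0, 50.0))


def make_displaced_monomer(
    vertical_energy: float = 2.0,
    frequencies=(0.15,),
    huang_rhys=(0.5,),
    dipole=(1.0, 0.0, 0.0),
    label: str = "L",
) -> LVCHamiltonian:
    """Single bright state with per-mode displacements lambda_a =
    w_a sqrt(2 S_a): the minimal FC|VG progression model."""
    w = np.atleast_1d(np.asarray(frequencies, float))
    S = np.atleast_1d(np.asarray(huang_rhys, float))
    if np.any(S < 0):
        raise ValueError("Huang-Rhys factors must be >= 0")
    lam = w * np.sqrt(2.0 * S)
    modes = ModeBasis(w)
    state = DiabaticState(label, "LE", vertical_energy, lam,
                          np.asarray(dipole, float))
    return LVCHamiltonian(modes, (state,), meta={"generator": "displaced"})


def make_jt_monomer(
    energy: float = 2.0,
    splitting: float = 0.0,
    tuning=(0.15, 0.1),
    coupling=(0.15, 0.1),
    dipoles=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
) -> LVCHamiltonian:
    """Two quasi-degenerate states with linear Jahn-Teller coupling.

    ``tuning = (w_t, kappa)`` puts opposite gradients +/- kappa on the
    tuning mode; ``coupling = (w_c, lam)`` puts the linear inter-state
    vector on the coupling mode.  Constant inter-state coupling is zero by
    symmetry.  With equal frequencies and ``splitting`` 0 this is the E x e
    model with a conical intersection at q = 0.
    """
    w_t, kappa = tuning
    w_c, lam = coupling
    modes = ModeBasis(np.array([w_t, w_c]), labels=("tuning", "coupling"))
    states = (
        DiabaticState("L", "LE", energy - 0.5 * splitting,
                      np.array([kappa, 0.0]), np.asarray(dipoles[0], float)),
        DiabaticState("Lp", "LE", energy + 0.5 * splitting,
                      np.array([-kappa, 0.0]), np.asarray(dipoles[1], float)),
    )
    coup = (InterStateCoupling((0, 1), 0.0, np.array([0.0, lam])),)
    return LVCHamiltonian(modes, states, coup, meta={"generator": "jt"})


def make_kasha_ct_dimer(
    e_le: float = 2.0,
    exciton_coupling: float = 0.05,
    ct_offset: float = 0.3,
    t_le_ct: float = 0.0,
    t_ct_ct: float = 0.0,
    huang_rhys_le: float = 0.2,
    huang_rhys_ion: float = 0.4,
    frequencies=(0.15, 0.12),
    jt_coupling: float = 0.0,
    geometry: str = "H",
    dipole_norm: float = 1.0,
) -> LVCHamiltonian:
    """Stacked-dimer template: 4 LE + 4 CT diabatic states over two
    monomers with two modes each (one tuning, one coupling).

    H geometry places parallel transition dipoles with positive exciton
    coupling (bright state above the dark one, blue-shifted absorption);
    J geometry uses the head-to-tail sign.  ``ct_offset`` is the vertical
    CT energy above the LE states, ``t_le_ct`` the electron/hole transfer
    integral coupling each LE to the CT states, ``t_ct_ct`` the direct
    CT-CT mixing.  Assembled through the fragment route: LE gradients are
    zero-padded per monomer, CT gradients concatenate the ionic-fragment
    gradients.
    """
    if geometry not in ("H", "J"):
        raise ValueError("geometry must be 'H' or 'J'")
    w = np.asarray(frequencies, float)
    lam_le = w[0] * np.sqrt(2.0 * huang_rhys_le)
    lam_ion = w[0] * np.sqrt(2.0 * huang_rhys_ion)
    frag = FragmentData(
        modes=ModeBasis(w, labels=("tuning", "coupling")),
        e_le=e_le, e_le2=e_le,
        grad_le=np.array([lam_le, 0.0]),
        grad_le2=np.array([lam_le, 0.0]),
        jt_linear=np.array([0.0, jt_coupling]),
        grad_cation=np.array([lam_ion, 0.0]),
        grad_anion=np.array([lam_ion, 0.0]),
        grad_anion2=np.array([lam_ion, 0.0]),
        dipole_le=np.array([dipole_norm, 0.0, 0.0]),
        dipole_le2=np.array([0.0, dipole_norm, 0.0]),
        ct_energy=e_le + ct_offset,
        ct_energy2=e_le + ct_offset,
    )
    J = exciton_coupling if geometry == "H" else -exciton_coupling
    C = np.zeros((8, 8))
    # exciton couplings between parallel-dipole LE pairs
    C[0, 2] = C[2, 0] = J      # L1 - L2
    C[1, 3] = C[3, 1] = J      # L1' - L2'
    # electron/hole transfer: each LE couples to the CT states of matching
    # orbital character
    for le, cts in ((0, (4, 6)), (1, (5, 7)), (2, (4, 6)), (3, (5, 7))):
        for ct in cts:
            C[le, ct] = C[ct, le] = t_le_ct
    # direct CT-CT mixing between same-character pairs
    C[4, 6] = C[6, 4] = t_ct_ct
    C[5, 7] = C[7, 5] = t_ct_ct
    H = assemble_dimer_hamiltonian(frag, frag, C,
                                   meta={"generator": "kasha_ct_dimer",
                                         "geometry": geometry})
    return H


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducible random-model settings for property tests."""

    seed: int
    n_states: int = 3
    n_modes: int = 2
    energy_range: tuple[float, float] = (1.5, 3.0)
    coupling_scale: float = 0.05
    displacement_scale: float = 0.1
    ct_fraction: float = 0.0


def make_random_lvc(config: GeneratorConfig) -> LVCHamiltonian:
    """Random dense LVC model drawn from ``config`` (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    w = rng.uniform(0.05, 0.25, config.n_modes)
    modes = ModeBasis(w)
    states = []
    for i in range(config.n_states):
        is_ct = rng.random() < config.ct_fraction
        dip = np.zeros(3) if is_ct else rng.normal(size=3)
        states.append(DiabaticState(
            f"s{i}", "CT" if is_ct else "LE",
            float(rng.uniform(*config.energy_range)),
            rng.normal(scale=config.displacement_scale, size=config.n_modes),
            dip))
    coups = []
    for i in range(config.n_states):
        for j in range(i + 1, config.n_states):
            coups.append(InterStateCoupling(
                (i, j), float(rng.normal(scale=config.coupling_scale))))
    return LVCHamiltonian(modes, tuple(states), tuple(coups),
                          meta={"generator": "random", "seed": config.seed})


def ring_template(radius_inner: float = 1.98, radius_mid: float = 3.0,
                  radius_outer: float = 4.6
                  ) -> tuple[np.ndarray, tuple[str, ...]]:
    """Idealized planar metal-macrocycle: metal at the origin, four inner
    (pyrrole-nitrogen-like) atoms on the axes, eight pyrrole carbons and
    eight benzo carbons further out, matching the ~4.5 A radial extent of a
    phthalocyanine ring.  Returns (coordinates (21, 3), element symbols)."""
    coords = [np.zeros(3)]
    elements = ["Zn"]
    for k in range(4):
        ang = np.deg2rad(90.0 * k)
        coords.append(np.array([radius_inner * np.cos(ang),
                                radius_inner * np.sin(ang), 0.0]))
        elements.append("N")
    for k in range(8):
        ang = np.deg2rad(45.0 * k + 22.5)
        coords.append(np.array([radius_mid * np.cos(ang),
                                radius_mid * np.sin(ang), 0.0]))
        elements.append("C")
    for k in range(8):
        ang = np.deg2rad(45.0 * k + 22.5)
        coords.append(np.array([radius_outer * np.cos(ang),
                                radius_outer * np.sin(ang), 0.0]))
        elements.append("C")
    return np.array(coords), tuple(elements)


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def stacked_dimer_frame(d_stack: float, twist: float = 0.0,
                        tilt: float = 0.0) -> tuple[np.ndarray, tuple[str, ...]]:
    """Rigid two-ring stacked frame: ring 1 in the xy plane, ring 2 twisted
    about the stacking axis, tilted about x, and translated by ``d_stack``
    along z."""
    ring, elements = ring_template()
    R = _rot_x(tilt) @ _rot_z(twist)
    ring2 = ring @ R.T + np.array([0.0, 0.0, d_stack])
    return np.vstack([ring, ring2]), elements + elements


def dimer_selections() -> Selections:
    """Atom selections matching :func:`stacked_dimer_frame` ordering."""
    def mono(offset):
        return MonomerSelection(
            ring=tuple(range(offset + 1, offset + 21)),
            metal=offset,
            axis_atoms=tuple(range(offset + 1, offset + 5)),
        )
    return Selections(mono(0), mono(21))


def make_stacked_trajectory(
    centers=DEFAULT_CLUSTER_CENTERS,
    frames_per_cluster=(12, 5, 3),
    noise: float = 0.10,
    seed: int = 0,
) -> tuple[ConformerEnsemble, np.ndarray, tuple[str, ...]]:
    """Seeded trajectory of rigid stacked-dimer frames jittered around
    planted conformer centers.

    ``centers`` are (d_stack / A, twist / deg, tilt / deg) tuples,
    ``noise`` the isotropic per-coordinate Gaussian sigma in Angstrom.
    Returns (ensemble, ground-truth labels, element symbols).
    """
    if len(centers) != len(frames_per_cluster):
        raise ValueError("one frame count per center required")
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    elements = None
    for k, ((d, tw, ti), n) in enumerate(zip(centers, frames_per_cluster)):
        base, elements = stacked_dimer_frame(d, tw, ti)
        for _ in range(int(n)):
            jitter = rng.normal(scale=noise, size=base.shape) if noise > 0 \
                else 0.0
            frames.append(base + jitter)
            labels.append(k)
    coords = np.array(frames)
    ensemble = ConformerEnsemble(coords, dimer_selections(),
                                 elements=elements)
    return ensemble, np.array(labels, dtype=int), elements
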