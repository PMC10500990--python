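"""Absorption lineshapes from time correlation functions.

The zero-kelvin absorption is assembled from auto- and cross-correlation
functions phi_ji(t) = <d_j; 0| exp(-i H t / hbar) |d_i; 0> of wavepackets
launched on the coupled diabatic surfaces:

    eps_ij(w) = c(w) (mu_gi . mu_gj) 2 Re int_0^inf dt e^{i w t / hbar}
                phi_ji(t) e^{-Gamma^2 t^2 / 2}

with a quadratic Gaussian damping whose parameter Gamma maps to a Gaussian
frequency-domain broadening (``hwhm_to_gamma``).  Auto terms carry the whole
integrated intensity; cross terms reshape the band at zero net area.  The
prefactor c(w) = w is optional; by default spectra are shape-only (the
remaining physical constant of the molar absorptivity is a configurable
scalar, and published spectra are normalized at the maximum peak height).

For an uncoupled displaced-oscillator state the correlation function is
analytic (the adiabatic vertical-gradient FC|VG limit):

    phi(t) = exp(-i E_00 t / hbar) exp(sum_a S_a (e^{-i w_a t / hbar} - 1)),
    E_00 = E_v - sum_a S_a w_a,     S_a = lambda_a^2 / (2 w_a^2)

which yields Poisson Franck-Condon progressions in the stick limit.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import HBAR_EVFS
from .model import DiabaticState, LVCHamiltonian, LVCError, ModeBasis

__all__ = [
    "Spectrum",
    "FCProgression",
    "hwhm_to_gamma",
    "fcvg_correlation",
    "spectrum_from_correlations",
    "stick_spectrum_fcvg",
    "weighted_average_spectrum",
    "fcvg_spectrum",
    "nonadiabatic_spectrum",
    "default_energy_grid",
    "peak_hwhm",
    "recover_progression_parameters",
]


def hwhm_to_gamma(hwhm: float) -> float:
    """Damping parameter Gamma (fs^-1) giving a frequency-domain Gaussian of
    the requested half width at half maximum (eV)."""
    if hwhm <= 0:
        raise LVCError("hwhm must be positive")
    return hwhm / (HBAR_EVFS * math.sqrt(2.0 * math.log(2.0)))


def huang_rhys(state: DiabaticState, modes: ModeBasis) -> np.ndarray:
    """Per-mode Huang-Rhys factors S_a = lambda_a^2 / (2 w_a^2)."""
    w = modes.frequencies
    return state.gradient**2 / (2.0 * w**2)


def fcvg_correlation(
    state: DiabaticState, modes: ModeBasis, t: np.ndarray
) -> np.ndarray:
    """Analytic zero-temperature correlation function of one uncoupled
    displaced-oscillator (FC|VG) state on the time grid ``t`` (fs)."""
    t = np.asarray(t, dtype=float)
    w = modes.frequencies
    S = huang_rhys(state, modes)
    e00 = state.energy0 - float(S @ w)
    phase = np.exp(-1j * e00 * t / HBAR_EVFS)
    arg = (S[:, None] * (np.exp(-1j * np.outer(w, t) / HBAR_EVFS) - 1.0)).sum(axis=0)
    return phase * np.exp(arg)


@dataclass
class Spectrum:
    """Frequency-resolved absorption: per-pair components eps_ij(w) and
    their sum.  ``components`` is keyed by (i, j) with i <= j; cross entries
    already include both orderings of the pair sum."""

    omega: np.ndarray
    components: dict[tuple[int, int], np.ndarray]
    total: np.ndarray
    gamma: float
    hwhm: float | None = None
    prefactor: bool = False
    meta: dict = field(default_factory=dict)

    def normalized(self, mode: str = "max") -> "Spectrum":
        """Copy normalized at the maximum peak height ('max') or to unit
        integrated area ('area')."""
        if mode == "max":
            scale = np.max(np.abs(self.total))
        elif mode == "area":
            scale = abs(np.trapezoid(self.total, self.omega))
        else:
            raise LVCError(f"unknown normalization mode {mode!r}")
        if scale == 0:
            return self
        comps = {k: v / scale for k, v in self.components.items()}
        return Spectrum(self.omega.copy(), comps, self.total / scale,
                        self.gamma, self.hwhm, self.prefactor,
                        dict(self.meta, normalized=mode))

    def integrate(self, key: tuple[int, int] | None = None) -> float:
        y = self.total if key is None else self.components[key]
        return float(np.trapezoid(y, self.omega))

    @property
    def max_position(self) -> float:
        return float(self.omega[int(np.argmax(self.total))])

    def to_csv(self, path, metadata_path=None) -> None:
        import pandas as pd

        data = {"energy_eV": self.omega, "total": self.total}
        for (i, j), v in sorted(self.components.items()):
            data[f"eps_{i}_{j}"] = v
        pd.DataFrame(data).to_csv(path, index=False)
        if metadata_path is not None:
            meta = dict(self.meta)
            meta.update({"gamma_inv_fs": self.gamma, "hwhm_eV": self.hwhm,
                         "prefactor": self.prefactor})
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2, default=str)


def _fourier_cos(phis: np.ndarray, t: np.ndarray, omega: np.ndarray,
                 gamma: float) -> np.ndarray:
    """2 Re int_0^tmax e^{i w t / hbar} phi(t) e^{-Gamma^2 t^2/2} dt by
    trapezoid quadrature; phis may be (n_pairs, nt)."""
    damped = phis * np.exp(-0.5 * (gamma * t) ** 2)
    kernel = np.exp(1j * np.outer(omega, t) / HBAR_EVFS)
    # trapezoid weights on a uniform grid
    wgt = np.full(t.size, t[1] - t[0])
    wgt[0] *= 0.5
    wgt[-1] *= 0.5
    return 2.0 * np.real(kernel @ (damped * wgt).T).T


def spectrum_from_correlations(
    phis: Mapping[tuple[int, int], np.ndarray],
    dipoles: np.ndarray,
    t: np.ndarray,
    gamma: float,
    omega: np.ndarray,
    prefactor: bool = False,
    hwhm: float | None = None,
    meta: dict | None = None,
) -> Spectrum:
    """Assemble eps(w) from correlation functions.

    ``phis`` maps ordered pairs (j, i) -- the projection state j of a run
    started on i -- to complex time series on the common grid ``t``; for a
    real symmetric Hamiltonian phi_ji = phi_ij, so a single ordering per
    pair suffices.  ``dipoles`` is the (n_states, 3) Condon dipole stack.
    """
    t = np.asarray(t, float)
    omega = np.asarray(omega, float)
    if t.ndim != 1 or t.size < 2:
        raise LVCError("need a 1-D time grid with at least two points")
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-8):
        raise LVCError("time grid must be uniform")
    if gamma < 0:
        raise LVCError("gamma must be >= 0")
    emax = float(np.max(np.abs(omega))) if omega.size else 0.0
    if emax > math.pi * HBAR_EVFS / dt:
        raise LVCError(
            f"time step {dt} fs too coarse for energies up to {emax} eV "
            f"(Nyquist limit {math.pi * HBAR_EVFS / dt:.3f} eV)")

    dipoles = np.asarray(dipoles, float)
    cw = omega if prefactor else 1.0

    merged: dict[tuple[int, int], np.ndarray] = {}
    counts: dict[tuple[int, int], int] = {}
    for (j, i), phi in phis.items():
        key = (min(i, j), max(i, j))
        phi = np.asarray(phi)
        if phi.shape != t.shape:
            raise LVCError(f"correlation for pair {(j, i)} does not match "
                           "the time grid")
        merged[key] = merged.get(key, 0) + phi
        counts[key] = counts.get(key, 0) + 1

    components: dict[tuple[int, int], np.ndarray] = {}
    total = np.zeros_like(omega)
    for key, phi in merged.items():
        i, j = key
        mu2 = float(dipoles[i] @ dipoles[j])
        if i != j and counts[key] == 1:
            phi = 2.0 * phi  # transpose-symmetric partner not supplied
        ft = _fourier_cos(phi[None, :], t, omega, gamma)[0]
        comp = cw * mu2 * ft
        components[key] = comp
        total = total + comp
    return Spectrum(omega, components, total, gamma, hwhm, prefactor,
                    dict(meta or {}))


@dataclass(frozen=True)
class FCProgression:
    """Franck-Condon stick progression of one FC|VG state: positions
    E_00 + sum_a n_a w_a with product-Poisson intensities."""

    positions: np.ndarray
    intensities: np.ndarray
    e00: float
    vertical_energy: float
    huang_rhys: np.ndarray
    frequencies: np.ndarray

    def broadened(self, omega: np.ndarray, hwhm: float) -> np.ndarray:
        """Gaussian-convolved stick spectrum on the ``omega`` grid."""
        sigma = hwhm / math.sqrt(2.0 * math.log(2.0))  # standard deviation
        y = np.zeros_like(omega, dtype=float)
        for pos, inten in zip(self.positions, self.intensities):
            y += inten * np.exp(-((omega - pos) ** 2) / (2.0 * sigma**2))
        return y


def stick_spectrum_fcvg(
    state: DiabaticState, modes: ModeBasis, max_quanta: int = 8
) -> FCProgression:
    """Multi-mode product Poisson progression up to ``max_quanta`` per mode.

    Intensities follow e^{-S} S^n / n! per mode; the full (infinite)
    progression sums to one.
    """
    if max_quanta < 0:
        raise LVCError("max_quanta must be >= 0")
    w = modes.frequencies
    S = huang_rhys(state, modes)
    e00 = state.energy0 - float(S @ w)
    per_mode = []
    for a in range(modes.count):
        n = np.arange(max_quanta + 1)
        with np.errstate(divide="ignore"):
            terms = np.exp(-S[a]) * S[a] ** n / np.array(
                [math.factorial(int(k)) for k in n], dtype=float)
        per_mode.append(terms)
    positions, intensities = [], []
    for combo in itertools.product(range(max_quanta + 1), repeat=modes.count):
        inten = 1.0
        for a, n in enumerate(combo):
            inten *= per_mode[a][n]
        positions.append(e00 + float(np.dot(combo, w)))
        intensities.append(inten)
    order = np.argsort(positions)
    return FCProgression(
        positions=np.asarray(positions)[order],
        intensities=np.asarray(intensities)[order],
        e00=e00,
        vertical_energy=state.energy0,
        huang_rhys=S,
        frequencies=w.copy(),
    )


def weighted_average_spectrum(
    spectra: Sequence[Spectrum],
    weights: Sequence[float],
    cluster_ids: Sequence | None = None,
) -> Spectrum:
    """Pointwise convex combination of per-conformer spectra with cluster
    population weights C^k (sum to one)."""
    weights = np.asarray(weights, float)
    if len(spectra) != weights.size:
        raise LVCError("one weight per spectrum required")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise LVCError(f"weights must sum to 1 (got {weights.sum()!r})")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.omega.shape != ref.omega.shape or not np.allclose(
                s.omega, ref.omega):
            raise LVCError("spectra must share a common energy grid")
    keys = set()
    for s in spectra:
        keys |= set(s.components)
    components = {}
    for key in keys:
        acc = np.zeros_like(ref.omega)
        for wgt, s in zip(weights, spectra):
            if key in s.components:
                acc = acc + wgt * s.components[key]
        components[key] = acc
    total = sum(wgt * s.total for wgt, s in zip(weights, spectra))
    ids = list(cluster_ids) if cluster_ids is not None else list(
        range(len(spectra)))
    return Spectrum(ref.omega.copy(), components, total, ref.gamma, ref.hwhm,
                    ref.prefactor, {"cluster_ids": ids,
                                    "weights": weights.tolist()})


def default_energy_grid(
    H: LVCHamiltonian, hwhm: float = 0.04, pad: float = 1.0,
    n_points: int = 2000,
) -> np.ndarray:
    """Uniform energy grid spanning the diabatic manifold with padding."""
    e = H.energies0
    lo = float(e.min()) - pad - 10 * hwhm
    hi = float(e.max()) + pad + 10 * hwhm
    return np.linspace(max(lo, 0.0), hi, n_points)


def fcvg_spectrum(
    H: LVCHamiltonian,
    t_max: float = 100.0,
    dt: float = 0.1,
    hwhm: float = 0.04,
    omega: np.ndarray | None = None,
    prefactor: bool = False,
) -> Spectrum:
    """Adiabatic FC|VG spectrum of an uncoupled model: analytic auto
    correlations of every dipole-carrying state, Fourier transformed with
    Gaussian damping."""
    if H.couplings:
        for c in H.couplings:
            if c.constant != 0 or (c.linear is not None
                                   and np.any(c.linear != 0)):
                raise LVCError("fcvg_spectrum applies to uncoupled models; "
                               "use nonadiabatic_spectrum instead")
    if H.frequency_matrix is not None and not np.allclose(
            H.frequency_matrix, np.diag(np.diag(H.frequency_matrix))):
        raise LVCError("fcvg_spectrum requires uncoupled (diagonal) modes")
    t = np.arange(0.0, t_max + dt / 2, dt)
    if omega is None:
        omega = default_energy_grid(H, hwhm)
    gamma = hwhm_to_gamma(hwhm)
    phis = {}
    for i, s in enumerate(H.states):
        if np.linalg.norm(s.dipole) > 0:
            phis[(i, i)] = fcvg_correlation(s, H.modes, t)
    return spectrum_from_correlations(
        phis, H.dipoles, t, gamma, omega, prefactor, hwhm,
        meta={"model": "FC|VG"})


def nonadiabatic_spectrum(
    H: LVCHamiltonian,
    n_max: int | Sequence[int] = 10,
    t_max: float = 100.0,
    dt: float = 0.1,
    hwhm: float = 0.04,
    omega: np.ndarray | None = None,
    prefactor: bool = False,
    method: str = "auto",
    **propagate_kwargs,
) -> Spectrum:
    """Nonadiabatic vibronic spectrum of a coupled LVC model.

    Launches one wavepacket from every dipole-carrying diabatic state,
    collects the full set of auto and cross correlation functions and
    Fourier transforms them with Gaussian damping of the requested HWHM.
    """
    from .dynamics import build_basis, propagate

    t = np.arange(0.0, t_max + dt / 2, dt)
    if omega is None:
        omega = default_energy_grid(H, hwhm)
    gamma = hwhm_to_gamma(hwhm)
    basis = build_basis(H, n_max)
    bright = [i for i, s in enumerate(H.states)
              if np.linalg.norm(s.dipole) > 0]
    # both orderings of every cross pair are collected (one from each run);
    # spectrum_from_correlations sums them without the factor-2 shortcut
    phis: dict[tuple[int, int], np.ndarray] = {}
    occ = 0.0
    for i in bright:
        res = propagate(H, basis, i, t_max=t_max, dt=dt, method=method,
                        **propagate_kwargs)
        occ = max(occ, float(res.occupancy.max()))
        for j in bright:
            phis[(j, i)] = res.correlations[j]
    spec = spectrum_from_correlations(
        phis, H.dipoles, t, gamma, omega, prefactor, hwhm,
        meta={"model": "LVC", "n_max": list(basis.levels),
              "max_top_level_occupancy": occ})
    return spec


def peak_hwhm(omega: np.ndarray, y: np.ndarray) -> float:
    """Measured half width at half maximum of the dominant peak, with linear
    interpolation of the half-maximum crossings."""
    k = int(np.argmax(y))
    half = y[k] / 2.0

    def crossing(direction):
        i = k
        while 0 < i < y.size - 1:
            i += direction
            if y[i] <= half:
                # interpolate between i and i-direction
                x0, x1 = omega[i - direction], omega[i]
                y0, y1 = y[i - direction], y[i]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
        raise LVCError("half maximum not reached inside the grid")

    left = crossing(-1)
    right = crossing(+1)
    return 0.5 * (right - left)


def recover_progression_parameters(
    omega: np.ndarray, y: np.ndarray, min_rel_height: float = 0.01
) -> tuple[float, float]:
    """Estimate the vibronic mode frequency and Huang-Rhys factor from a
    broadened FC|VG progression: the spacing of the first two progression
    peaks recovers w, and their height ratio I(0-1)/I(0-0) recovers S (valid
    while the broadening is narrow compared with w)."""
    from scipy.signal import find_peaks

    peaks, props = find_peaks(y, height=min_rel_height * float(np.max(y)))
    if peaks.size < 2:
        raise LVCError("fewer than two progression peaks resolved")
    first, second = peaks[0], peaks[1]
    w_est = float(omega[second] - omega[first])
    s_est = float(y[second] / y[first])
    return w_est, s_est
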