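"""Forward scattering model for hydration-water quasi-elastic neutron spectra.

The incoherent scattering function is modelled as the sum of three water
populations plus a flat background, per scattering wavenumber ``q``:

.. math::

    S(q, E) = e^{-q^2\\langle u^2\\rangle} \\Big\\{
        \\big[A_i + A_r j_0^2(qb)\\big] R(q, E)
        + A_t\\, L(E; \\Gamma_t(q)) \\otimes R
        + A_r \\sum_{l=1}^{5} (2l+1) j_l^2(qb)\\,
          L(E; l(l+1)\\Gamma_r) \\otimes R \\Big\\} + k(q)

where ``R`` is the measured instrumental resolution, ``L`` a unit-area
Lorentzian, ``j_l`` the spherical Bessel functions, and
``Gamma_t(q) = hbar * D_t * q**lam`` the (possibly anomalous) translational
line width.  The rotational part is the isotropic rotational-diffusion
expansion: an elastic factor ``j_0^2(qb)`` (the rotational EISF) plus
Lorentzians of half-width ``l(l+1) * Gamma_r`` weighted by
``(2l+1) j_l^2(qb)``.  Translational and rotational populations are told
apart by the opposite q-dependence of their widths and intensities, which is
why the model is fitted globally over the whole (q, E) surface.

Two variants are provided: the default *additive* form above, and a
*convolved* form in which the rotational term is additionally convolved with
the translational Lorentzian (Lorentzian widths add, and the rotational
elastic line acquires width ``Gamma_t``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import spherical_jn

__all__ = [
    "HBAR_UEV_PS",
    "DEFAULT_ROTATION_RADIUS",
    "SpectrumGrid",
    "ModelParams",
    "ResolutionFunction",
    "Spectrum",
    "debye_waller",
    "rotational_eisf",
    "sears_quasielastic_weights",
    "translational_hwhm",
    "lorentzian",
    "binned_lorentzian",
    "convolve_resolution",
    "profile_fwhm",
    "forward_model",
]

#: hbar expressed in micro-eV * ps; converts a rate in 1/ps to a HWHM in ueV.
HBAR_UEV_PS = 658.2119

#: H-O distance of a water molecule, used as the hydrogen rotation radius (angstrom).
DEFAULT_ROTATION_RADIUS = 0.98

#: Number of quasi-elastic terms kept in the rotational expansion.
DEFAULT_L_MAX = 5

Variant = Literal["additive", "convolved"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumGrid:
    """A rectangular (q, E) measurement grid.

    Parameters
    ----------
    q_values : array, 1/angstrom
        Scattering wavenumbers, strictly increasing and positive.
    E_values : array, micro-eV
        Energy transfers, ascending and uniformly spaced, symmetric about 0
        to within one channel.
    """

    q_values: np.ndarray
    E_values: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q_values, dtype=float)
        E = np.asarray(self.E_values, dtype=float)
        object.__setattr__(self, "q_values", q)
        object.__setattr__(self, "E_values", E)
        if q.ndim != 1 or q.size < 1:
            raise ValueError("q_values must be a non-empty 1-d array")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q_values must be positive and strictly increasing")
        if E.ndim != 1 or E.size < 3:
            raise ValueError("E_values must hold at least 3 channels")
        dE = np.diff(E)
        if np.any(dE <= 0):
            raise ValueError("E_values must be ascending")
        if np.max(np.abs(dE - dE[0])) > 1e-9 * abs(dE[0]):
            raise ValueError("E_values must be uniformly spaced (1e-9 relative)")
        if abs(E[0] + E[-1]) > dE[0] * (1 + 1e-9):
            raise ValueError("E range must be symmetric about 0 within one channel")

    @property
    def n_q(self) -> int:
        return self.q_values.size

    @property
    def n_E(self) -> int:
        return self.E_values.size

    @property
    def dE(self) -> float:
        return float(self.E_values[1] - self.E_values[0])


def symmetric_energy_grid(half_range: float, channel: float) -> np.ndarray:
    """Build a symmetric, odd-length, uniform energy axis ``[-half, +half]``."""
    n_half = int(round(half_range / channel))
    return np.arange(-n_half, n_half + 1) * channel


@dataclass
class ModelParams:
    """Free parameters of the scattering model at one temperature.

    ``u2`` is the vibrational mean-squared amplitude <u^2> (angstrom^2);
    ``A_i``, ``A_t``, ``A_r`` the immobile / translational / rotational
    intensities; ``D_t`` the translational diffusion coefficient
    (angstrom^lam / ps — its dimension follows the anomalous exponent
    ``lam``); ``Gamma_r`` the rotational broadening unit (ueV), i.e.
    hbar * D_R so that the l-th line has half-width l(l+1)*Gamma_r;
    ``b`` the hydrogen rotation radius (angstrom); ``k`` the flat per-q
    background (one entry per q value).
    """

    u2: float
    A_i: float
    A_t: float
    A_r: float
    D_t: float
    lam: float
    Gamma_r: float
    k: np.ndarray
    b: float = DEFAULT_ROTATION_RADIUS

    def __post_init__(self) -> None:
        self.k = np.atleast_1d(np.asarray(self.k, dtype=float))
        self.validate()

    def validate(self, n_q: int | None = None) -> None:
        if min(self.A_i, self.A_t, self.A_r) < 0:
            raise ValueError("amplitudes A_i, A_t, A_r must be non-negative")
        if not (0 < self.lam <= 2):
            raise ValueError("lam must lie in (0, 2]")
        if self.Gamma_r <= 0:
            raise ValueError("Gamma_r must be positive")
        if self.D_t < 0 or self.u2 < 0:
            raise ValueError("D_t and u2 must be non-negative")
        if self.b <= 0:
            raise ValueError("rotation radius b must be positive")
        if n_q is not None and self.k.size != n_q:
            raise ValueError(f"k has {self.k.size} entries but grid has {n_q} q values")

    def amplitude_sum(self) -> float:
        return self.A_i + self.A_t + self.A_r

    def fractions(self) -> tuple[float, float, float]:
        """Normalized (f_t, f_r, f_i) intensity fractions."""
        total = self.amplitude_sum()
        if total <= 0:
            raise ValueError("cannot normalize fractions: all amplitudes are zero")
        return (self.A_t / total, self.A_r / total, self.A_i / total)

    def as_dict(self) -> dict:
        d = {n: float(getattr(self, n))
             for n in ("u2", "A_i", "A_t", "A_r", "D_t", "lam", "Gamma_r", "b")}
        d["k"] = [float(v) for v in self.k]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(u2=d["u2"], A_i=d["A_i"], A_t=d["A_t"], A_r=d["A_r"],
                   D_t=d["D_t"], lam=d["lam"], Gamma_r=d["Gamma_r"],
                   k=np.asarray(d["k"], dtype=float), b=d.get("b", DEFAULT_ROTATION_RADIUS))


@dataclass
class ResolutionFunction:
    """Measured instrumental resolution, one unit-area profile per q.

    In practice this is the low-temperature (20 K) spectrum of the sample,
    where the signal is almost purely elastic, area-normalized per q.
    """

    grid: SpectrumGrid
    profiles: np.ndarray  # shape (n_q, n_E)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (self.grid.n_q, self.grid.n_E):
            raise ValueError("resolution profiles must have shape (n_q, n_E)")
        if np.any(self.profiles < 0):
            raise ValueError("resolution profiles must be non-negative")
        areas = self.profiles.sum(axis=1) * self.grid.dE
        if np.any(np.abs(areas - 1.0) > 1e-6):
            raise ValueError("each resolution profile must integrate to 1 within 1e-6")

    def fwhm(self, iq: int = 0) -> float:
        return profile_fwhm(self.grid.E_values, self.profiles[iq])


@dataclass
class Spectrum:
    """A model or measured S(q, E) surface with optional per-point errors."""

    intensity: np.ndarray  # shape (n_q, n_E)
    error: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
            if self.error.shape != self.intensity.shape:
                raise ValueError("error surface must match intensity shape")
            if np.any(self.error <= 0):
                raise ValueError("errors must be strictly positive where present")


# ---------------------------------------------------------------------------
# elementary factors
# ---------------------------------------------------------------------------

def debye_waller(q, u2: float):
    """Debye-Waller factor exp(-q^2 <u^2>) from vibrational motion."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or u2 < 0:
        raise ValueError("q and u2 must be non-negative")
    return np.exp(-(q ** 2) * u2)


def rotational_eisf(q, b: float = DEFAULT_ROTATION_RADIUS):
    """Elastic incoherent structure factor j0^2(qb) of rotation at radius b."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    if b <= 0:
        raise ValueError("b must be positive")
    return spherical_jn(0, q * b) ** 2


def sears_quasielastic_weights(q: float, b: float = DEFAULT_ROTATION_RADIUS,
                               l_max: int = DEFAULT_L_MAX) -> np.ndarray:
    """Quasi-elastic weights (2l+1) j_l^2(qb) of the rotational expansion.

    Returns the weights for l = 1..l_max.  Together with the elastic factor
    j0^2(qb) they sum to 1 as l_max grows (completeness of the expansion).
    """
    if l_max < 1:
        raise ValueError("l_max must be at least 1")
    x = float(q) * float(b)
    ls = np.arange(1, l_max + 1)
    return (2 * ls + 1) * spherical_jn(ls, x) ** 2


def translational_hwhm(q, D_t: float, lam: float):
    """Translational Lorentzian half-width hbar * D_t * q**lam in ueV.

    ``lam = 2`` is Brownian diffusion; ``lam < 2`` sub-diffusive motion.
    """
    if not (0 < lam <= 2):
        raise ValueError("lam must lie in (0, 2]")
    if D_t < 0:
        raise ValueError("D_t must be non-negative")
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    return HBAR_UEV_PS * D_t * q ** lam


def lorentzian(E, hwhm: float):
    """Unit-area Lorentzian density (1/pi) * hwhm / (E^2 + hwhm^2)."""
    if hwhm <= 0:
        raise ValueError("hwhm must be positive")
    E = np.asarray(E, dtype=float)
    return hwhm / (np.pi * (E ** 2 + hwhm ** 2))


def binned_lorentzian(E, hwhm: float, dE: float):
    """Channel-averaged Lorentzian: the exact integral of the density over
    each channel of width dE, divided by dE.

    Point sampling misrepresents a line much narrower than the channel
    width; the bin integral (an arctan difference) is accurate for every
    width and tends to a single-channel spike of unit area as hwhm -> 0,
    which is the correct delta-function limit.
    """
    if hwhm <= 0:
        raise ValueError("hwhm must be positive")
    E = np.asarray(E, dtype=float)
    upper = np.arctan((E + 0.5 * dE) / hwhm)
    lower = np.arctan((E - 0.5 * dE) / hwhm)
    return (upper - lower) / (np.pi * dE)


def profile_fwhm(E: np.ndarray, profile: np.ndarray) -> float:
    """Numerical full width at half maximum of a single-peaked profile."""
    p = np.asarray(profile, dtype=float)
    i_max = int(np.argmax(p))
    half = p[i_max] / 2.0
    # walk outwards and interpolate the half-maximum crossings
    left = right = None
    for i in range(i_max, 0, -1):
        if p[i - 1] < half <= p[i]:
            left = np.interp(half, [p[i - 1], p[i]], [E[i - 1], E[i]])
            break
    for i in range(i_max, len(p) - 1):
        if p[i + 1] < half <= p[i]:
            right = np.interp(half, [p[i + 1], p[i]], [E[i + 1], E[i]])
            break
    if left is None or right is None:
        raise ValueError("profile does not fall below half maximum on both sides")
    return float(right - left)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def convolve_resolution(profile: np.ndarray, resolution: np.ndarray,
                        dE: float) -> np.ndarray:
    """Convolve a sampled density with a unit-area resolution profile.

    Both must be sampled on the same uniform energy grid whose zero sits at
    the central channel (odd length).  The discrete linear convolution is
    multiplied by the channel width so that a unit-area input against a
    unit-area kernel stays unit area (up to truncation of tails).
    """
    profile = np.asarray(profile, dtype=float)
    resolution = np.asarray(resolution, dtype=float)
    if profile.shape != resolution.shape:
        raise ValueError("profile and resolution must share the same E grid")
    return np.convolve(profile, resolution, mode="same") * dE


def _padded_axis(E: np.ndarray, dE: float, pad: int) -> np.ndarray:
    left = E[0] - dE * np.arange(pad, 0, -1)
    right = E[-1] + dE * np.arange(1, pad + 1)
    return np.concatenate([left, E, right])


def _padding_channels(resolution: ResolutionFunction, n_fwhm: float = 10.0) -> int:
    """Zero-padding width: at least ``n_fwhm`` resolution FWHM on each side."""
    fwhm = max(resolution.fwhm(iq) for iq in range(resolution.grid.n_q))
    return max(int(np.ceil(n_fwhm * fwhm / resolution.grid.dE)), 16)


# ---------------------------------------------------------------------------
# full forward model
# ---------------------------------------------------------------------------

def forward_model(params: ModelParams, grid: SpectrumGrid,
                  resolution: ResolutionFunction, variant: Variant = "additive",
                  l_max: int = DEFAULT_L_MAX) -> Spectrum:
    """Evaluate the rotation-translation-immobile model on a (q, E) grid.

    The quasi-elastic terms are built analytically on an energy axis padded
    by at least ten resolution widths, convolved with the per-q resolution
    profile, and cropped back to the measurement window.  The elastic terms
    ride on the resolution profile itself (a delta convolved with R is R).
    The flat background ``k(q)`` is neither convolved nor Debye-Waller
    attenuated.
    """
    if variant not in ("additive", "convolved"):
        raise ValueError(f"unknown model variant: {variant!r}")
    params.validate(n_q=grid.n_q)
    if resolution.grid.n_E != grid.n_E or resolution.grid.n_q != grid.n_q:
        raise ValueError("resolution must be sampled on the data grid")

    E = grid.E_values
    dE = grid.dE
    pad = _padding_channels(resolution)
    E_ext = _padded_axis(E, dE, pad)
    crop = slice(pad, pad + grid.n_E)

    dw = debye_waller(grid.q_values, params.u2)
    out = np.empty((grid.n_q, grid.n_E))
    ls = np.arange(1, l_max + 1)
    rot_hwhms = ls * (ls + 1) * params.Gamma_r

    for iq, q in enumerate(grid.q_values):
        R = resolution.profiles[iq]
        eisf = float(rotational_eisf(q, params.b))
        weights = sears_quasielastic_weights(q, params.b, l_max)
        gamma_t = float(translational_hwhm(q, params.D_t, params.lam)) \
            if params.D_t > 0 else 0.0

        quasi = np.zeros_like(E_ext)
        if variant == "additive" or gamma_t == 0.0:
            elastic_coef = params.A_i + params.A_r * eisf
            if gamma_t > 0.0:
                quasi += params.A_t * binned_lorentzian(E_ext, gamma_t, dE)
            else:
                elastic_coef += params.A_t
            for w, g in zip(weights, rot_hwhms):
                quasi += params.A_r * w * binned_lorentzian(E_ext, g, dE)
        else:
            # rotational term convolved with the translational Lorentzian:
            # widths add, and the rotational elastic line picks up gamma_t
            elastic_coef = params.A_i
            quasi += (params.A_t + params.A_r * eisf) * binned_lorentzian(E_ext, gamma_t, dE)
            for w, g in zip(weights, rot_hwhms):
                quasi += params.A_r * w * binned_lorentzian(E_ext, g + gamma_t, dE)

        conv = np.convolve(quasi, R, mode="same")[crop] * dE
        out[iq] = dw[iq] * (elastic_coef * R + conv) + params.k[iq]

    if not np.all(np.isfinite(out)):
        iq, iE = np.argwhere(~np.isfinite(out))[0]
        raise FloatingPointError(
            f"non-finite model value at q={grid.q_values[iq]:.4g}, "
            f"E={grid.E_values[iE]:.4g}")
    return Spectrum(intensity=out)
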