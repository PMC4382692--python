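"""Global chi-square fitting of the QENS model over a full (q, E) surface.

The shared shape parameters (<u^2>, D_t, lam, Gamma_r) are optimized by
bounded least squares on the weighted residuals, while the parameters the
model is linear in — the three population amplitudes and the per-q flat
backgrounds — are profiled out at every step by a non-negative linear
solve.  This exploits the structure of the model (separable nonlinear least
squares) and keeps the nonlinear search four-dimensional regardless of the
number of q slices.  A multistart strategy over a (lam, Gamma_r) grid plus
seeded random starts guards against local minima; ties are broken toward
smaller lam.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .qens_model import (
    HBAR_UEV_PS,
    DEFAULT_ROTATION_RADIUS,
    ModelParams,
    ResolutionFunction,
    Spectrum,
    SpectrumGrid,
    Variant,
    debye_waller,
    binned_lorentzian,
    forward_model,
    rotational_eisf,
    sears_quasielastic_weights,
    translational_hwhm,
    _padded_axis,
    _padding_channels,
)

__all__ = ["QENSDataset", "FitConfig", "FitResult", "chi_square",
           "global_fit", "compare_variants", "fraction_series"]

SHAPE_NAMES = ("u2", "D_t", "lam", "Gamma_r")


@dataclass
class QENSDataset:
    """One measured (or synthetic) QENS surface at a single temperature."""

    grid: SpectrumGrid
    spectrum: Spectrum
    resolution: ResolutionFunction
    temperature: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spectrum.intensity.shape != (self.grid.n_q, self.grid.n_E):
            raise ValueError("spectrum shape does not match grid")
        if self.spectrum.error is None:
            raise ValueError("a QENS dataset requires per-point errors")
        if not np.array_equal(self.resolution.grid.E_values, self.grid.E_values) \
                or not np.array_equal(self.resolution.grid.q_values, self.grid.q_values):
            raise ValueError("resolution grid must be identical to the data grid")

    @property
    def n_points(self) -> int:
        return self.grid.n_q * self.grid.n_E


@dataclass
class FitConfig:
    """Optimizer settings for :func:`global_fit`.

    ``bounds`` maps parameter name to (lo, hi) for the shape parameters;
    amplitudes and backgrounds are constrained non-negative by the linear
    solver.  The multistart pool is the cartesian (lam, Gamma_r) grid plus
    ``multistart_count`` seeded random starts.
    """

    variant: Variant = "additive"
    bounds: dict = field(default_factory=lambda: {
        "u2": (0.0, 5.0),
        "D_t": (0.0, 1.0),
        "lam": (0.301, 2.0),
        "Gamma_r": (0.01, 50.0),
    })
    lam_starts: Sequence[float] = (1.0, 1.5, 2.0)
    gamma_r_starts: Sequence[float] = (0.2, 1.0, 5.0)
    multistart_count: int = 3
    seed: int = 0
    tol: float = 1e-10
    max_iter: int = 200
    b: float = DEFAULT_ROTATION_RADIUS

    def __post_init__(self) -> None:
        if self.multistart_count < 0:
            raise ValueError("multistart_count must be >= 0")
        for name in SHAPE_NAMES:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ValueError(f"empty bound interval for {name}")


@dataclass
class FitResult:
    """Best-fit parameters, uncertainties and goodness of fit."""

    params: ModelParams
    uncertainties: dict
    chi2: float
    chi2_reduced: float
    n_dof: int
    fractions: tuple[float, float, float]  # (f_t, f_r, f_i)
    fraction_errors: tuple[float, float, float]
    converged: bool
    variant: str
    temperature: float | None = None
    warnings: list = field(default_factory=list)
    seed: int | None = None

    def report(self) -> str:
        """Plain key=value fit report."""
        lines = [f"variant={self.variant}",
                 f"converged={self.converged}",
                 f"chi2={self.chi2:.8g}",
                 f"chi2_reduced={self.chi2_reduced:.8g}",
                 f"n_dof={self.n_dof}"]
        if self.temperature is not None:
            lines.append(f"temperature_K={self.temperature:g}")
        if self.seed is not None:
            lines.append(f"seed={self.seed}")
        for name in ("u2", "A_i", "A_t", "A_r", "D_t", "lam", "Gamma_r"):
            err = self.uncertainties.get(name, float("nan"))
            lines.append(f"{name}={getattr(self.params, name):.8g} +- {err:.3g}")
        lines.append(f"D_R_per_ps={self.params.Gamma_r / HBAR_UEV_PS:.8g}")
        for iq, kv in enumerate(self.params.k):
            lines.append(f"k_{iq}={kv:.8g}")
        ft, fr, fi = self.fractions
        et, er, ei = self.fraction_errors
        lines += [f"f_t={ft:.6g} +- {et:.3g}",
                  f"f_r={fr:.6g} +- {er:.3g}",
                  f"f_i={fi:.6g} +- {ei:.3g}"]
        for w in self.warnings:
            lines.append(f"warning={w}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def chi_square(dataset: QENSDataset, params: ModelParams,
               variant: Variant = "additive") -> float:
    """Sum over all (q, E) points of (S_exp - S_model)^2 / sigma^2."""
    model = forward_model(params, dataset.grid, dataset.resolution, variant)
    r = (dataset.spectrum.intensity - model.intensity) / dataset.spectrum.error
    return float(np.sum(r * r))


# ---------------------------------------------------------------------------
# separable linear structure
# ---------------------------------------------------------------------------

def _design_columns(shape: np.ndarray, dataset: QENSDataset,
                    variant: Variant, b: float, l_max: int = 5):
    """Weighted design matrix columns for (A_i, A_t, A_r, k_0..k_{nq-1}).

    At fixed shape parameters the model is linear in the amplitudes and the
    per-q backgrounds; each column is the model surface produced by a unit
    value of that coefficient, divided by sigma.
    """
    u2, D_t, lam, Gamma_r = shape
    grid, res = dataset.grid, dataset.resolution
    E, dE = grid.E_values, grid.dE
    pad = _padding_channels(res)
    E_ext = _padded_axis(E, dE, pad)
    crop = slice(pad, pad + grid.n_E)
    dw = debye_waller(grid.q_values, u2)
    ls = np.arange(1, l_max + 1)
    rot_hwhms = ls * (ls + 1) * Gamma_r

    n_q, n_E = grid.n_q, grid.n_E
    n_lin = 3 + n_q
    A = np.zeros((n_q, n_E, n_lin))
    for iq, q in enumerate(grid.q_values):
        R = res.profiles[iq]
        eisf = float(rotational_eisf(q, b))
        weights = sears_quasielastic_weights(q, b, l_max)
        gamma_t = float(translational_hwhm(q, D_t, lam)) if D_t > 0 else 0.0

        if gamma_t > 0.0:
            trans_line = np.convolve(binned_lorentzian(E_ext, gamma_t, dE), R,
                                     mode="same")[crop] * dE
        else:
            trans_line = R.copy()
        rot_quasi = np.zeros_like(E_ext)
        if variant == "additive" or gamma_t == 0.0:
            rot_elastic = eisf * R
            for w, g in zip(weights, rot_hwhms):
                rot_quasi += w * binned_lorentzian(E_ext, g, dE)
        else:
            rot_elastic = eisf * trans_line
            for w, g in zip(weights, rot_hwhms):
                rot_quasi += w * binned_lorentzian(E_ext, g + gamma_t, dE)
        rot_line = rot_elastic + np.convolve(rot_quasi, R, mode="same")[crop] * dE

        A[iq, :, 0] = dw[iq] * R            # A_i column
        A[iq, :, 1] = dw[iq] * trans_line   # A_t column
        A[iq, :, 2] = dw[iq] * rot_line     # A_r column
        A[iq, :, 3 + iq] = 1.0              # k(q) column
    sigma = dataset.spectrum.error
    return (A / sigma[:, :, None]).reshape(-1, n_lin)


def _profiled_residuals(shape: np.ndarray, dataset: QENSDataset,
                        variant: Variant, b: float):
    """Weighted residuals after solving the non-negative linear subproblem."""
    Aw = _design_columns(shape, dataset, variant, b)
    yw = (dataset.spectrum.intensity / dataset.spectrum.error).ravel()
    coef, _ = nnls(Aw, yw)
    return Aw @ coef - yw, coef


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

def _random_starts(config: FitConfig, rng: np.random.Generator) -> list:
    starts = []
    for _ in range(config.multistart_count):
        u2 = rng.uniform(0.0, 0.5)
        D_t = 10.0 ** rng.uniform(-3, -1)
        lam = rng.uniform(config.bounds["lam"][0], config.bounds["lam"][1])
        g_lo, g_hi = config.bounds["Gamma_r"]
        Gamma_r = 10.0 ** rng.uniform(np.log10(max(g_lo, 1e-3)),
                                      np.log10(min(g_hi, 20.0)))
        starts.append(np.array([u2, D_t, lam, Gamma_r]))
    return starts


def global_fit(dataset: QENSDataset, config: FitConfig | None = None,
               extra_starts: Sequence[np.ndarray] | None = None) -> FitResult:
    """Fit the model globally over the full (q, E) surface.

    The shape parameters (<u^2>, D_t, lam, Gamma_r) are shared across all q;
    amplitudes are shared too, while the flat background is free per q.
    Fractions are reported as A_x / (A_i + A_t + A_r); uncertainties come
    from the local quadratic approximation of chi^2 at the optimum.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)

    lo = np.array([config.bounds[n][0] for n in SHAPE_NAMES])
    hi = np.array([config.bounds[n][1] for n in SHAPE_NAMES])

    starts = [np.array([0.05, 0.01, lam, g])
              for lam, g in itertools.product(config.lam_starts,
                                              config.gamma_r_starts)]
    starts += _random_starts(config, rng)
    if extra_starts is not None:
        starts += [np.asarray(s, dtype=float) for s in extra_starts]

    best = None
    any_converged = False
    for x0 in starts:
        x0c = np.clip(x0, lo, hi)
        try:
            sol = least_squares(
                lambda x: _profiled_residuals(x, dataset, config.variant, config.b)[0],
                x0c, bounds=(lo, hi), method="trf",
                xtol=config.tol, ftol=config.tol, gtol=config.tol,
                max_nfev=config.max_iter * (len(SHAPE_NAMES) + 1))
        except Exception:
            continue
        chi2 = 2.0 * sol.cost
        any_converged = any_converged or sol.success
        if best is None or chi2 < best[0] - 1e-9 * max(best[0], 1.0) or (
                abs(chi2 - best[0]) <= 1e-9 * max(best[0], 1.0)
                and sol.x[2] < best[1].x[2]):
            best = (chi2, sol)

    if best is None:
        raise RuntimeError(
            "global_fit: every multistart raised; check dataset errors and bounds")
    warnings: list[str] = []
    if not any_converged:
        warnings.append("no multistart converged")
    chi2_best, sol = best
    shape = sol.x
    _, coef = _profiled_residuals(shape, dataset, config.variant, config.b)

    n_q = dataset.grid.n_q
    params = ModelParams(u2=shape[0], A_i=coef[0], A_t=coef[1], A_r=coef[2],
                         D_t=shape[1], lam=shape[2], Gamma_r=shape[3],
                         k=coef[3:3 + n_q], b=config.b)

    # boundary / degeneracy diagnostics
    for name, value, (blo, bhi) in zip(SHAPE_NAMES, shape,
                                       [config.bounds[n] for n in SHAPE_NAMES]):
        span = bhi - blo
        if value - blo < 1e-6 * span or bhi - value < 1e-6 * span:
            warnings.append(f"parameter {name} at bound")
    res_fwhm = dataset.resolution.fwhm(0)
    if params.D_t > 0:
        gamma_min = float(translational_hwhm(dataset.grid.q_values[0],
                                             params.D_t, params.lam))
        if gamma_min < 0.05 * res_fwhm:
            warnings.append("translational width degenerate with elastic line")

    n_free = len(SHAPE_NAMES) + 3 + n_q
    n_dof = dataset.n_points - n_free
    uncertainties, cov_amp = _curvature_uncertainties(dataset, params, config.variant)

    total = params.amplitude_sum()
    if total > 0:
        fractions = params.fractions()
        fraction_errors = _fraction_errors(
            np.array([params.A_t, params.A_r, params.A_i]), cov_amp)
    else:
        fractions = (0.0, 0.0, 0.0)
        fraction_errors = (float("nan"),) * 3
        warnings.append("all amplitudes zero")

    return FitResult(params=params, uncertainties=uncertainties,
                     chi2=chi2_best, chi2_reduced=chi2_best / max(n_dof, 1),
                     n_dof=n_dof, fractions=fractions,
                     fraction_errors=fraction_errors,
                     converged=any_converged, variant=config.variant,
                     temperature=dataset.temperature, warnings=warnings,
                     seed=config.seed)


def _full_residuals(vec: np.ndarray, dataset: QENSDataset, variant: Variant,
                    b: float, n_q: int) -> np.ndarray:
    params = ModelParams(u2=max(vec[0], 0.0), A_i=max(vec[1], 0.0),
                         A_t=max(vec[2], 0.0), A_r=max(vec[3], 0.0),
                         D_t=max(vec[4], 0.0),
                         lam=min(max(vec[5], 1e-3), 2.0),
                         Gamma_r=max(vec[6], 1e-6),
                         k=vec[7:7 + n_q], b=b)
    model = forward_model(params, dataset.grid, dataset.resolution, variant)
    return ((model.intensity - dataset.spectrum.intensity)
            / dataset.spectrum.error).ravel()


def _curvature_uncertainties(dataset: QENSDataset, params: ModelParams,
                             variant: Variant):
    """Parameter errors from the Gauss-Newton curvature of chi^2 (delta
    chi^2 = 1 contour), via a numerical Jacobian of the weighted residuals
    with respect to every free parameter."""
    n_q = dataset.grid.n_q
    vec = np.concatenate([[params.u2, params.A_i, params.A_t, params.A_r,
                           params.D_t, params.lam, params.Gamma_r], params.k])
    names = ["u2", "A_i", "A_t", "A_r", "D_t", "lam", "Gamma_r"] + \
            [f"k_{i}" for i in range(n_q)]
    n = len(vec)
    r0 = _full_residuals(vec, dataset, variant, params.b, n_q)
    J = np.empty((r0.size, n))
    for j in range(n):
        h = 1e-5 * max(abs(vec[j]), 1e-3)
        vp, vm = vec.copy(), vec.copy()
        vp[j] = min(vp[j] + h, 2.0) if j == 5 else vp[j] + h
        vm[j] = max(vm[j] - h, 0.0)
        hj = vp[j] - vm[j]
        J[:, j] = (_full_residuals(vp, dataset, variant, params.b, n_q)
                   - _full_residuals(vm, dataset, variant, params.b, n_q)) / hj
    cov = np.linalg.pinv(J.T @ J)
    errs = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    uncertainties = dict(zip(names, errs))
    # covariance block of (A_t, A_r, A_i) for fraction error propagation
    idx = [2, 3, 1]
    cov_amp = cov[np.ix_(idx, idx)]
    return uncertainties, cov_amp


def _fraction_errors(amps_tri: np.ndarray, cov_amp: np.ndarray):
    """Delta-method errors of f_x = A_x / sum(A) given the (A_t, A_r, A_i)
    covariance block (same ordering)."""
    total = amps_tri.sum()
    errs = []
    for i in range(3):
        grad = -amps_tri / total ** 2
        grad[i] += 1.0 / total
        errs.append(float(np.sqrt(max(grad @ cov_amp @ grad, 0.0))))
    return tuple(errs)


# ---------------------------------------------------------------------------
# model comparison and temperature series
# ---------------------------------------------------------------------------

def compare_variants(dataset: QENSDataset, config: FitConfig | None = None):
    """Fit both model variants with identical starts and bounds.

    Returns (additive_result, convolved_result, chi2_ratio) where the ratio
    is chi2_convolved / chi2_additive.
    """
    config = config or FitConfig()
    results = {}
    for variant in ("additive", "convolved"):
        cfg = FitConfig(variant=variant, bounds=dict(config.bounds),
                        lam_starts=config.lam_starts,
                        gamma_r_starts=config.gamma_r_starts,
                        multistart_count=config.multistart_count,
                        seed=config.seed, tol=config.tol,
                        max_iter=config.max_iter, b=config.b)
        res = results[variant] = global_fit(dataset, cfg)
        if not res.converged:
            raise RuntimeError(f"{variant} fit failed to converge")
    ratio = results["convolved"].chi2 / results["additive"].chi2
    return results["additive"], results["convolved"], ratio


def fraction_series(results: Sequence[FitResult]) -> pd.DataFrame:
    """Tabulate (T, f_t, f_r, f_i) with uncertainties, sorted by temperature."""
    if len(results) == 0:
        raise ValueError("need at least one fit result")
    temps = [r.temperature for r in results]
    if any(t is None for t in temps):
        raise ValueError("every fit result needs a temperature")
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate temperatures in fraction series")
    rows = []
    for r in sorted(results, key=lambda r: r.temperature):
        ft, fr, fi = r.fractions
        et, er, ei = r.fraction_errors
        rows.append({"T": r.temperature, "f_t": ft, "f_r": fr, "f_i": fi,
                     "f_t_err": et, "f_r_err": er, "f_i_err": ei,
                     "chi2_reduced": r.chi2_reduced})
    return pd.DataFrame(rows)
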