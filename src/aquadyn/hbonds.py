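"""Hydrogen-bond detection and kinetics from molecular trajectories.

A donor-acceptor pair is hydrogen bonded when the D-A distance is below
3.5 angstrom and the D-H-A angle (vertex at the hydrogen) exceeds 150
degrees, for any hydrogen bonded to the donor.  From the boolean bond
history h(pair, frame) two correlation functions are formed:

* the *continuous* survival S_HB(t) = <h(0) H(t)> / <h>, where H(t) = 1
  only if the bond stayed intact at every frame in [0, t] — its 1/e time
  tau_HBC tracks fast bond breakage by librational/rotational motion;
* the *intermittent* correlation C_HB(t) = <h(0) h(t)> / <h>, which allows
  breaking and reforming — its 1/e time tau_HBI tracks the slower
  relaxation of the hydrogen-bond network.

Averages run over all pairs and all time origins; for each lag the
numerator and the normalization <h(0)> are accumulated over the same set
of origins, which guarantees values in [0, 1], a value of exactly 1 at lag
zero, and C_HB >= S_HB pointwise.  Correlations that do not reach 1/e
within the analysis window are extrapolated with a stretched-exponential
(KWW) fit.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["Topology", "Trajectory", "HBSeries", "CorrelationFunction",
           "RelaxationResult", "detect_hbonds", "hb_timeseries",
           "continuous_correlation", "intermittent_correlation",
           "relaxation_time", "fit_exponential_decay", "water_msd",
           "rate_series"]

DEFAULT_DISTANCE_CUTOFF = 3.5   # angstrom, D-A
DEFAULT_ANGLE_CUTOFF = 150.0    # degrees, D-H-A at the hydrogen


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Static atom classification: donors with their hydrogens, acceptors,
    water oxygens, and protein/water group tags."""

    labels: list
    donors: list          # (heavy_index, hydrogen_index) records
    acceptors: np.ndarray
    water_oxygens: np.ndarray
    groups: list          # "protein" | "water" per atom

    def __post_init__(self) -> None:
        self.acceptors = np.asarray(self.acceptors, dtype=int)
        self.water_oxygens = np.asarray(self.water_oxygens, dtype=int)
        for d, h in self.donors:
            if d == h:
                raise ValueError("donor hydrogen must differ from its heavy atom")

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    def donor_heavy_atoms(self) -> list:
        """Unique donor heavy atoms, each with its list of hydrogens."""
        seen: dict = {}
        for d, h in self.donors:
            seen.setdefault(d, []).append(h)
        return sorted(seen.items())


@dataclass
class Trajectory:
    """Cartesian frames (angstrom) at a fixed time step dt (ps); an optional
    orthorhombic box (three lengths) switches on minimum-image distances."""

    positions: np.ndarray   # (n_frames, n_atoms, 3)
    dt: float
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive lengths")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]


@dataclass
class HBSeries:
    """Boolean bond indicator per (D-A pair, frame)."""

    h: np.ndarray           # bool, (n_pairs, n_frames)
    dt: float
    pairs: list = field(default_factory=list)   # (donor_heavy, acceptor)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=bool)
        if self.h.ndim != 2 or self.h.shape[1] < 1:
            raise ValueError("h must be a (n_pairs, n_frames) matrix")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_pairs(self) -> int:
        return self.h.shape[0]

    @property
    def n_frames(self) -> int:
        return self.h.shape[1]


@dataclass
class CorrelationFunction:
    """Correlation values on a lag grid with per-lag origin sample counts."""

    lags: np.ndarray        # ps
    values: np.ndarray
    counts: np.ndarray      # (pair, origin) samples per lag

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)
        if abs(self.values[0] - 1.0) > 1e-12:
            raise ValueError("correlation at lag 0 must equal 1")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("correlation values must lie in [0, 1]")


@dataclass
class RelaxationResult:
    tau: float                       # ps, 1/e time
    method: str                      # direct-crossing | stretched-extrapolation
    beta: float | None = None        # KWW stretch exponent, when fitted
    amplitude: float | None = None
    tau_s: float | None = None       # KWW scale time, when fitted

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("relaxation time must be positive")
        if self.beta is not None and not (0 < self.beta <= 1):
            raise ValueError("stretch exponent must lie in (0, 1]")


# ---------------------------------------------------------------------------
# geometric detection
# ---------------------------------------------------------------------------

def _min_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def detect_hbonds(positions: np.ndarray, topology: Topology,
                  d_max: float = DEFAULT_DISTANCE_CUTOFF,
                  angle_min: float = DEFAULT_ANGLE_CUTOFF,
                  box: np.ndarray | None = None):
    """Evaluate the distance-angle criterion for one frame.

    Returns (pairs, bonded) where ``pairs`` lists the (donor_heavy,
    acceptor) combinations tracked (acceptor distinct from the donor and
    its hydrogens) and ``bonded`` is the boolean verdict per pair.
    """
    pos = np.asarray(positions, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
    cos_min = np.cos(np.deg2rad(angle_min))
    pairs: list[tuple[int, int]] = []
    bonded: list[bool] = []
    for d, hydrogens in topology.donor_heavy_atoms():
        acc = topology.acceptors[(topology.acceptors != d)
                                 & ~np.isin(topology.acceptors, hydrogens)]
        if acc.size == 0:
            continue
        dvec = _min_image(pos[acc] - pos[d], box)
        dist = np.linalg.norm(dvec, axis=1)
        if np.any(dist < 0.5):
            _warnings.warn("overlapping atoms (D-A distance < 0.5 angstrom)",
                           stacklevel=2)
        close = dist < d_max
        ok = np.zeros(acc.size, dtype=bool)
        for h in hydrogens:
            hd = _min_image(pos[d] - pos[h], box)
            ha = _min_image(pos[acc] - pos[h], box)
            nd = np.linalg.norm(hd)
            na = np.linalg.norm(ha, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (ha @ hd) / (na * nd)
            # angle > angle_min means cos(angle) < cos(angle_min)
            ok |= np.where(np.isfinite(cosang), cosang < cos_min, False)
        verdict = close & ok
        pairs.extend((d, int(a)) for a in acc)
        bonded.extend(bool(v) for v in verdict)
    return pairs, np.asarray(bonded, dtype=bool)


def hb_timeseries(traj: Trajectory, topology: Topology,
                  d_max: float = DEFAULT_DISTANCE_CUTOFF,
                  angle_min: float = DEFAULT_ANGLE_CUTOFF) -> HBSeries:
    """Apply :func:`detect_hbonds` to every frame."""
    pairs0, bonded0 = detect_hbonds(traj.positions[0], topology,
                                    d_max, angle_min, traj.box)
    if len(pairs0) == 0:
        raise ValueError("topology defines no donor-acceptor pairs")
    h = np.empty((len(pairs0), traj.n_frames), dtype=bool)
    h[:, 0] = bonded0
    for t in range(1, traj.n_frames):
        _, bonded = detect_hbonds(traj.positions[t], topology,
                                  d_max, angle_min, traj.box)
        h[:, t] = bonded
    return HBSeries(h=h, dt=traj.dt, pairs=pairs0)


# ---------------------------------------------------------------------------
# correlation functions
# ---------------------------------------------------------------------------

def _origin_normalization(h: np.ndarray, max_lag: int) -> np.ndarray:
    """d(tau) = number of bonded origins t0 <= n-1-tau, summed over pairs."""
    ones_prefix = np.cumsum(h.sum(axis=0))        # total ones up to frame i
    n = h.shape[1]
    return ones_prefix[n - 1 - np.arange(max_lag + 1)].astype(float)


def continuous_correlation(series: HBSeries, max_lag: int | None = None,
                           origin_stride: int = 1) -> CorrelationFunction:
    """Continuous bond survival S_HB(t).

    For each pair the lengths of maximal runs of consecutive bonded frames
    are histogrammed; a run of length m starting inside the origin window
    contributes to every lag tau < m.  ``origin_stride`` > 1 subsamples the
    origins (the default uses every frame).
    """
    h = series.h
    n = series.n_frames
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    if h.sum() == 0:
        raise ValueError("series contains no bonds; correlation undefined")

    if origin_stride == 1:
        # run length starting at each position, per pair (vectorized)
        num = np.zeros(max_lag + 1)
        for row in h:
            idx = np.flatnonzero(row)
            if idx.size == 0:
                continue
            # L[i] for bonded positions: distance to the end of the run
            breaks = np.flatnonzero(np.diff(idx) > 1)
            run_ends = np.append(idx[breaks], idx[-1])
            run_starts = np.insert(idx[breaks + 1], 0, idx[0])
            lengths = run_ends - run_starts + 1
            hist = np.bincount(lengths, minlength=max_lag + 2)
            cum = np.cumsum(hist[::-1])[::-1]       # runs with length >= m
            # positions whose bonded tail is >= tau+1: sum over runs of (m - tau)+
            tail = np.cumsum(cum[::-1])[::-1]       # tail[m0] = sum_runs (m - m0 + 1)+
            num += tail[1:max_lag + 2]
        den = _origin_normalization(h, max_lag)
        counts = h.shape[0] * (n - np.arange(max_lag + 1))
    else:
        origins = np.arange(0, n, origin_stride)
        num = np.zeros(max_lag + 1)
        den = np.zeros(max_lag + 1)
        counts = np.zeros(max_lag + 1, dtype=int)
        # tail run length per position
        L = np.zeros_like(h, dtype=int)
        L[:, -1] = h[:, -1]
        for i in range(n - 2, -1, -1):
            L[:, i] = np.where(h[:, i], L[:, i + 1] + 1, 0)
        for tau in range(max_lag + 1):
            valid = origins[origins <= n - 1 - tau]
            num[tau] = np.sum(L[:, valid] >= tau + 1)
            den[tau] = np.sum(h[:, valid])
            counts[tau] = h.shape[0] * valid.size

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    lags = np.arange(max_lag + 1) * series.dt
    return CorrelationFunction(lags=lags, values=values, counts=counts)


def intermittent_correlation(series: HBSeries, max_lag: int | None = None
                             ) -> CorrelationFunction:
    """Intermittent bond correlation C_HB(t), via FFT autocorrelation."""
    h = series.h
    n = series.n_frames
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    if h.sum() == 0:
        raise ValueError("series contains no bonds; correlation undefined")

    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    F = np.fft.rfft(h.astype(float), nfft, axis=1)
    acf = np.fft.irfft(F * np.conj(F), nfft, axis=1)[:, :max_lag + 1]
    num = np.maximum(np.round(acf.sum(axis=0)), 0.0)   # exact integer counts
    den = _origin_normalization(h, max_lag)
    counts = h.shape[0] * (n - np.arange(max_lag + 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    lags = np.arange(max_lag + 1) * series.dt
    return CorrelationFunction(lags=lags, values=values, counts=counts)


# ---------------------------------------------------------------------------
# relaxation times
# ---------------------------------------------------------------------------

_INV_E = float(np.exp(-1.0))


def relaxation_time(corr: CorrelationFunction, window_max: float = 4000.0,
                    fit_start_level: float = 0.95,
                    beta_bounds: tuple[float, float] = (0.2, 1.0)
                    ) -> RelaxationResult:
    """1/e relaxation time of a correlation function.

    If the curve crosses 1/e inside the window the time is interpolated
    linearly between the bracketing lags.  Otherwise the tail (from the
    first lag below ``fit_start_level``) is fitted with a stretched
    exponential A * exp(-(t/tau_s)^beta), weighted by the per-lag sample
    counts, and the analytic 1/e crossing of the fit is returned.
    """
    mask = corr.lags <= window_max
    t = corr.lags[mask]
    y = corr.values[mask]
    c = np.asarray(corr.counts, dtype=float)[mask]
    below = np.flatnonzero(y < _INV_E)
    if below.size > 0 and below[0] > 0:
        i = below[0]
        tau = float(np.interp(_INV_E, [y[i], y[i - 1]], [t[i], t[i - 1]]))
        return RelaxationResult(tau=tau, method="direct-crossing")

    start_candidates = np.flatnonzero(y < fit_start_level)
    if start_candidates.size == 0:
        raise RuntimeError("correlation shows no decay inside the window; "
                           "no 1/e time can be extracted")
    i0 = int(start_candidates[0])
    if t.size - i0 < 4:
        raise RuntimeError("too few tail points for a stretched-exponential fit")
    tt, yy, w = t[i0:], y[i0:], np.sqrt(np.maximum(c[i0:], 1.0))

    def resid(p):
        A, tau_s, beta = p
        return w * (A * np.exp(-(tt / tau_s) ** beta) - yy)

    p0 = np.array([min(max(y[i0], 0.5), 1.0), max(tt[-1], 1.0), 0.7])
    sol = least_squares(resid, p0,
                        bounds=([1e-6, 1e-6, beta_bounds[0]],
                                [2.0, 1e9, beta_bounds[1]]))
    A, tau_s, beta = sol.x
    if A <= _INV_E:
        raise RuntimeError(
            f"fitted stretched exponential never reaches 1/e (A={A:.3g})")
    tau = float(tau_s * (np.log(A) + 1.0) ** (1.0 / beta))
    return RelaxationResult(tau=tau, method="stretched-extrapolation",
                            beta=float(beta), amplitude=float(A),
                            tau_s=float(tau_s))


def fit_exponential_decay(corr: CorrelationFunction, baseline: bool = True,
                          window_max: float | None = None) -> dict:
    """Fit ``C(t) = c_inf + (A - c_inf) * exp(-rate * t)`` and return the
    decay rate; with ``baseline=False`` the plateau c_inf is fixed at 0.

    Useful for comparing measured correlation decays against kinetic rate
    constants (for a two-state process the intermittent correlation decays
    at k_on + k_off toward the equilibrium bonded fraction).
    """
    mask = np.ones(corr.lags.size, dtype=bool) if window_max is None \
        else corr.lags <= window_max
    t, y = corr.lags[mask], corr.values[mask]
    w = np.sqrt(np.maximum(np.asarray(corr.counts, dtype=float)[mask], 1.0))

    if baseline:
        def resid(p):
            c_inf, A, rate = p
            return w * (c_inf + (A - c_inf) * np.exp(-rate * t) - y)
        p0 = [max(y[-1], 1e-3), 1.0, 1.0 / max(t[-1] / 5.0, t[1])]
        lo, hi = [0.0, 0.0, 1e-12], [1.0, 2.0, np.inf]
    else:
        def resid(p):
            A, rate = p
            return w * (A * np.exp(-rate * t) - y)
        p0 = [1.0, 1.0 / max(t[-1] / 5.0, t[1])]
        lo, hi = [0.0, 1e-12], [2.0, np.inf]
    sol = least_squares(resid, p0, bounds=(lo, hi))
    out = {"rate": float(sol.x[-1]), "amplitude": float(sol.x[-2])}
    if baseline:
        out["plateau"] = float(sol.x[0])
    return out


# ---------------------------------------------------------------------------
# water mean-squared displacement
# ---------------------------------------------------------------------------

def unwrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping by accumulating minimum-image frame steps."""
    steps = np.diff(positions, axis=0)
    steps -= box * np.round(steps / box)
    out = np.empty_like(positions)
    out[0] = positions[0]
    out[1:] = positions[0] + np.cumsum(steps, axis=0)
    return out


def water_msd(traj: Trajectory, oxygen_indices: Sequence[int] | None = None,
              lag: float = 100.0) -> float:
    """Mean-squared displacement <|r(t0+lag) - r(t0)|^2> (angstrom^2) of the
    selected atoms over all time origins."""
    k = lag / traj.dt
    if abs(k - round(k)) > 1e-9:
        raise ValueError("lag must be a multiple of the frame interval")
    k = int(round(k))
    if k >= traj.n_frames:
        raise ValueError("lag exceeds the trajectory span")
    pos = traj.positions if oxygen_indices is None \
        else traj.positions[:, np.asarray(oxygen_indices, dtype=int), :]
    if traj.box is not None:
        pos = unwrap_positions(pos, traj.box)
    d = pos[k:] - pos[:-k] if k > 0 else np.zeros_like(pos)
    return float(np.mean(np.sum(d * d, axis=-1)))


def rate_series(records: Sequence[dict]) -> pd.DataFrame:
    """Summarize relaxation results over temperature.

    Each record may hold ``T``, ``tau_hbc``, ``tau_hbi`` and ``msd_100ps``;
    missing optional entries become NaN (written as missing markers).
    Rates are 1/tau in 1/ps.
    """
    rows = []
    for rec in records:
        row = {"T": rec["T"]}
        for key, out in (("tau_hbc", "rate_hbc"), ("tau_hbi", "rate_hbi")):
            tau = rec.get(key)
            row[out] = 1.0 / tau if tau else np.nan
        row["msd_100ps"] = rec.get("msd_100ps", np.nan)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("T").reset_index(drop=True)
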