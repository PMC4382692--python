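"""Ground-truth generators for every stage of the pipeline.

Each generator emulates the corresponding measurement at the conditions of
the neutron and simulation protocols this package analyzes: backscattering
spectra on q = 0.46-1.66 1/angstrom with 0.04 ueV channels over +-15.8 ueV
and a 0.7 ueV FWHM resolution; elastic scans with a mean-squared
displacement hinge near 240 K; two-state Markov bond histories as the
analytic oracle for the hydrogen-bond correlation functions; and
free-space multi-population water trajectories (immobile / rotor /
translator).  All randomness flows from explicit integer seeds, which are
recorded in the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .elastic import ElasticScan
from .hbonds import HBSeries, Topology, Trajectory
from .qens_fit import QENSDataset
from .qens_model import (
    DEFAULT_ROTATION_RADIUS,
    ModelParams,
    ResolutionFunction,
    Spectrum,
    SpectrumGrid,
    Variant,
    forward_model,
    lorentzian,
    profile_fwhm,
    symmetric_energy_grid,
)

__all__ = ["NoiseSpec", "PopulationSpec", "MarkovHBSpec", "MarkovOracle",
           "default_qens_grid", "default_qens_truth", "generate_resolution",
           "generate_qens_dataset", "hinge_msd_profile",
           "generate_elastic_scan", "generate_hb_markov_series",
           "generate_water_trajectory", "trajectory_from_bond_states"]

#: instrument constants of the emulated backscattering measurement
INSTRUMENT_Q_RANGE = (0.46, 1.66)     # 1/angstrom
INSTRUMENT_E_HALF_RANGE = 15.8        # ueV
INSTRUMENT_CHANNEL = 0.04             # ueV
INSTRUMENT_RESOLUTION_FWHM = 0.7      # ueV

WATER_HOH_ANGLE_DEG = 104.5


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Counting-like Gaussian noise: sigma = c * sqrt(max(S, floor)).

    The square-root scaling mimics Poisson counting statistics at the count
    levels of long acquisitions; the floor keeps sigma positive in the
    empty wings of the spectrum.
    """

    c: float = 0.02
    floor: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("relative noise scale must be non-negative")
        if self.floor <= 0:
            raise ValueError("noise floor must be positive")

    def sigma(self, intensity: np.ndarray) -> np.ndarray:
        return self.c * np.sqrt(np.maximum(intensity, self.floor))


@dataclass
class PopulationSpec:
    """Three-population water model: immobile, rotor and translator fractions."""

    fractions: tuple[float, float, float] = (0.4, 0.2, 0.4)  # (immobile, rotor, translator)
    D_t: float = 0.01           # angstrom^2/ps, translator diffusion
    D_R: float = 0.05           # 1/ps, rotor rotational diffusion
    jitter: float = 0.1         # angstrom, immobile harmonic jitter amplitude
    b: float = DEFAULT_ROTATION_RADIUS

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("population fractions must be non-negative and sum to 1")


@dataclass
class MarkovHBSpec:
    """Two-state bond kinetics: bonded -> broken at k_off, back at k_on."""

    k_off: float = 0.1          # 1/ps
    k_on: float = 0.02          # 1/ps
    n_pairs: int = 500
    n_frames: int = 4000
    dt: float = 1.0             # ps
    seed: int = 0
    init: Literal["equilibrium", "bonded"] = "equilibrium"

    def __post_init__(self) -> None:
        if self.k_off < 0 or self.k_on < 0:
            raise ValueError("rates must be non-negative")
        if self.n_pairs < 1 or self.n_frames < 1:
            raise ValueError("need at least one pair and one frame")
        if max(self.k_off, self.k_on) * self.dt > 0.5:
            raise ValueError("rate * dt too large for a faithful discretization")


@dataclass
class MarkovOracle:
    """Closed forms for the two-state chain realized by the generator.

    The chain is the *exact* frame-sampled continuous-time two-state
    process: with K = k_on + k_off, the per-step transition probabilities
    are ``p_step(bonded->broken) = (1 - p_eq)(1 - exp(-K dt))`` and
    ``p_step(broken->bonded) = p_eq (1 - exp(-K dt))`` (both equal to
    ``1 - exp(-k dt)`` to first order in dt).  The stationary bonded
    fraction is therefore exactly p_eq = k_on / K and the intermittent
    correlation is exactly ``p_eq + (1 - p_eq) exp(-K t)``.  The continuous
    survival observed at frame resolution decays per step as the
    bonded->bonded probability; its rate approaches k_off as dt -> 0 and
    differs from it by O(K dt) on a coarse grid.
    """

    k_off: float
    k_on: float
    dt: float

    @property
    def total_rate(self) -> float:
        return self.k_on + self.k_off

    @property
    def p_eq(self) -> float:
        return self.k_on / self.total_rate if self.total_rate > 0 else 1.0

    @property
    def p_step_off(self) -> float:
        """Per-step bonded -> broken probability."""
        return (1.0 - self.p_eq) * (1.0 - np.exp(-self.total_rate * self.dt))

    @property
    def p_step_on(self) -> float:
        """Per-step broken -> bonded probability."""
        return self.p_eq * (1.0 - np.exp(-self.total_rate * self.dt))

    @property
    def survival_rate(self) -> float:
        """Frame-resolution continuous-survival decay rate, 1/ps."""
        return -np.log(1.0 - self.p_step_off) / self.dt

    def survival(self, t) -> np.ndarray:
        """S_HB(t) of the frame-sampled chain: per-step survival compounded."""
        steps = np.asarray(t, dtype=float) / self.dt
        return (1.0 - self.p_step_off) ** steps

    def intermittent(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.p_eq + (1.0 - self.p_eq) * np.exp(-self.total_rate * t)


# ---------------------------------------------------------------------------
# QENS
# ---------------------------------------------------------------------------

def default_qens_grid(n_q: int = 10,
                      q_range: tuple[float, float] = INSTRUMENT_Q_RANGE,
                      half_range: float = INSTRUMENT_E_HALF_RANGE,
                      channel: float = INSTRUMENT_CHANNEL) -> SpectrumGrid:
    """The emulated instrument grid: n_q wavenumbers, symmetric E window."""
    return SpectrumGrid(q_values=np.linspace(*q_range, n_q),
                        E_values=symmetric_energy_grid(half_range, channel))


def default_qens_truth(n_q: int = 10) -> ModelParams:
    """Reference ground-truth parameter set for recovery studies.

    Amplitudes 0.5 / 0.3 / 0.2 (immobile / translational / rotational),
    D_t = 0.01 angstrom^lam/ps with lam = 1.6, Gamma_r = 0.5 ueV.  The
    vibrational amplitude (0.1 angstrom^2) and the flat background (1e-3)
    are modest values typical of a hydrated powder well below the elastic
    peak intensity.
    """
    return ModelParams(u2=0.1, A_i=0.5, A_t=0.3, A_r=0.2, D_t=0.01, lam=1.6,
                       Gamma_r=0.5, k=np.full(n_q, 1e-3))


def generate_resolution(grid: SpectrumGrid,
                        fwhm: float = INSTRUMENT_RESOLUTION_FWHM,
                        shape: Literal["gaussian", "pseudo-voigt"] = "gaussian",
                        lorentz_weight: float = 0.3) -> ResolutionFunction:
    """Unit-area resolution profile of the requested FWHM, one copy per q."""
    if grid.dE >= fwhm / 4:
        raise ValueError("energy grid too coarse to resolve the resolution "
                         f"function (need dE < fwhm/4 = {fwhm / 4:g})")
    E = grid.E_values
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gauss = np.exp(-0.5 * (E / sigma) ** 2)
    if shape == "gaussian":
        profile = gauss
    elif shape == "pseudo-voigt":
        profile = (1 - lorentz_weight) * gauss / (sigma * np.sqrt(2 * np.pi)) \
            + lorentz_weight * lorentzian(E, fwhm / 2.0)
    else:
        raise ValueError(f"unknown resolution shape: {shape!r}")
    profile = profile / (profile.sum() * grid.dE)
    res = ResolutionFunction(grid=grid,
                             profiles=np.tile(profile, (grid.n_q, 1)))
    achieved = profile_fwhm(E, profile)
    if abs(achieved - fwhm) > grid.dE:
        raise ValueError("constructed resolution FWHM off by more than one channel")
    return res


def generate_qens_dataset(params: ModelParams, grid: SpectrumGrid,
                          resolution: ResolutionFunction,
                          noise: NoiseSpec | None = None,
                          variant: Variant = "additive",
                          temperature: float = 300.0,
                          label: str = "synthetic") -> QENSDataset:
    """Forward-model surface plus seeded counting-like Gaussian noise.

    The noise sigma surface is stored as the dataset's errors and the full
    ground truth (parameters, seed, variant) in its metadata.
    """
    noise = noise or NoiseSpec()
    model = forward_model(params, grid, resolution, variant)
    sigma = noise.sigma(model.intensity)
    if noise.c > 0:
        rng = np.random.default_rng(noise.seed)
        intensity = model.intensity + rng.standard_normal(sigma.shape) * sigma
        error = sigma
    else:
        intensity = model.intensity.copy()
        error = np.ones_like(intensity)
    meta = {"sample": label, "variant": variant, "seed": noise.seed,
            "noise_c": noise.c, "noise_floor": noise.floor,
            "truth": params.as_dict(), "energy_window_ueV": float(grid.E_values[-1])}
    return QENSDataset(grid=grid, spectrum=Spectrum(intensity, error),
                       resolution=resolution, temperature=temperature,
                       metadata=meta)


# ---------------------------------------------------------------------------
# elastic scans
# ---------------------------------------------------------------------------

def hinge_msd_profile(msd0: float = 0.0, slope_low: float = 0.0,
                      T_star: float = 240.0, slope_high: float = 0.004
                      ) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-linear <u^2>(T) with a slope change (hinge) at T_star.

    The default emulates the onset of large-amplitude motions: flat below
    the hinge, 0.004 angstrom^2/K above it.
    """
    def profile(T):
        T = np.asarray(T, dtype=float)
        rel = T - T.flat[0]
        return msd0 + slope_low * rel + np.where(
            T > T_star, (slope_high - slope_low) * (T - T_star), 0.0)
    return profile


def generate_elastic_scan(msd_profile: Callable[[np.ndarray], np.ndarray],
                          temperatures: np.ndarray, q_values: np.ndarray,
                          noise_c: float = 0.01, seed: int = 0,
                          label: str = "synthetic") -> ElasticScan:
    """I(q, T) = exp(-q^2 <u^2>(T)) * (1 + noise), normalized at the lowest T.

    ``msd_profile`` gives the MSD relative to the base temperature (so it
    should vanish at the first temperature for a properly normalized scan).
    Errors are the multiplicative noise level times the intensity.
    """
    T = np.asarray(temperatures, dtype=float)
    q = np.asarray(q_values, dtype=float)
    u2 = np.asarray(msd_profile(T), dtype=float)
    if np.any(u2 < 0):
        raise ValueError("msd profile must be non-negative")
    clean = np.exp(-np.outer(u2, q ** 2))
    rng = np.random.default_rng(seed)
    intensity = clean * (1.0 + noise_c * rng.standard_normal(clean.shape)) \
        if noise_c > 0 else clean
    error = np.maximum(noise_c, 1e-6) * clean
    return ElasticScan(temperatures=T, q_values=q, intensity=intensity,
                       error=error,
                       metadata={"sample": label, "seed": seed, "noise_c": noise_c})


# ---------------------------------------------------------------------------
# Markov hydrogen-bond series
# ---------------------------------------------------------------------------

def generate_hb_markov_series(spec: MarkovHBSpec) -> tuple[HBSeries, MarkovOracle]:
    """Independent two-state chains per pair, the exact frame-sampled
    continuous-time process (see :class:`MarkovOracle`); initial states from
    equilibrium (or all bonded when no re-formation is possible)."""
    rng = np.random.default_rng(spec.seed)
    oracle = MarkovOracle(k_off=spec.k_off, k_on=spec.k_on, dt=spec.dt)
    p_off = oracle.p_step_off if oracle.total_rate > 0 else 0.0
    p_on = oracle.p_step_on if oracle.total_rate > 0 else 0.0

    if spec.init == "bonded" or spec.k_on + spec.k_off == 0 or spec.k_on == 0:
        state = np.ones(spec.n_pairs, dtype=bool)
    else:
        state = rng.random(spec.n_pairs) < oracle.p_eq
    h = np.empty((spec.n_pairs, spec.n_frames), dtype=bool)
    h[:, 0] = state
    u = rng.random((spec.n_pairs, spec.n_frames - 1))
    for t in range(1, spec.n_frames):
        flip = np.where(state, u[:, t - 1] < p_off, u[:, t - 1] < p_on)
        state = state ^ flip
        h[:, t] = state
    return HBSeries(h=h, dt=spec.dt), oracle


def trajectory_from_bond_states(states: np.ndarray, dt: float = 1.0
                                ) -> tuple[Trajectory, Topology]:
    """Build a three-atom geometry series realizing prescribed bond states.

    Atom 0 is a donor oxygen, atom 1 its hydrogen, atom 2 an acceptor
    oxygen.  When ``states[t]`` is true the acceptor sits collinear at a
    D-A distance of 2.8 angstrom (angle 180 degrees); otherwise it is moved
    to 5.0 angstrom, outside the distance cutoff.
    """
    states = np.asarray(states, dtype=bool)
    n = states.size
    pos = np.zeros((n, 3, 3))
    pos[:, 1, 0] = 0.98                                  # hydrogen along +x
    pos[:, 2, 0] = np.where(states, 2.8, 5.0)            # acceptor
    topo = Topology(labels=["O", "H", "O"], donors=[(0, 1)], acceptors=[2],
                    water_oxygens=[0, 2], groups=["water"] * 3)
    return Trajectory(positions=pos, dt=dt), topo


# ---------------------------------------------------------------------------
# water trajectories
# ---------------------------------------------------------------------------

def _water_template(b: float) -> np.ndarray:
    """O at origin, two H at radius b separated by the water angle."""
    half = np.deg2rad(WATER_HOH_ANGLE_DEG) / 2.0
    return np.array([[0.0, 0.0, 0.0],
                     [b * np.sin(half), 0.0, b * np.cos(half)],
                     [-b * np.sin(half), 0.0, b * np.cos(half)]])


def _rotation_matrices(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices for unit axes and angles (vectorized)."""
    x, y, z = axes[:, 0], axes[:, 1], axes[:, 2]
    c, s = np.cos(angles), np.sin(angles)
    C = 1.0 - c
    R = np.empty((axes.shape[0], 3, 3))
    R[:, 0, 0] = c + x * x * C
    R[:, 0, 1] = x * y * C - z * s
    R[:, 0, 2] = x * z * C + y * s
    R[:, 1, 0] = y * x * C + z * s
    R[:, 1, 1] = c + y * y * C
    R[:, 1, 2] = y * z * C - x * s
    R[:, 2, 0] = z * x * C - y * s
    R[:, 2, 1] = z * y * C + x * s
    R[:, 2, 2] = c + z * z * C
    return R


def generate_water_trajectory(pop: PopulationSpec, n_waters: int = 100,
                              n_frames: int = 200, dt: float = 1.0,
                              box: np.ndarray | None = None, seed: int = 0
                              ) -> tuple[Trajectory, Topology, dict]:
    """Free-space multi-population water trajectory.

    Immobile waters jitter harmonically (independent Gaussian displacements
    of the whole molecule about a fixed site); rotors keep their oxygen
    fixed while the rigid H-O-H frame performs rotational Brownian motion
    (random-axis rotations of angle variance 2 D_R dt per step); translators
    are rigid molecules on 3D Brownian walks with diffusion coefficient D_t.
    Returns the trajectory, a matching topology (every oxygen is acceptor +
    donor of its two hydrogens) and the ground-truth population assignment.
    """
    rng = np.random.default_rng(seed)
    f = np.asarray(pop.fractions, dtype=float)
    counts = np.floor(f * n_waters).astype(int)
    while counts.sum() < n_waters:     # distribute rounding remainders
        counts[int(np.argmax(f * n_waters - counts))] += 1
    assignment = np.repeat(np.array(["immobile", "rotor", "translator"]), counts)

    spacing = 8.0
    side = int(np.ceil(n_waters ** (1 / 3)))
    sites = spacing * np.stack(np.meshgrid(*[np.arange(side)] * 3),
                               axis=-1).reshape(-1, 3)[:n_waters]
    template = _water_template(pop.b)

    n_atoms = 3 * n_waters
    pos = np.empty((n_frames, n_atoms, 3))
    # initial random molecular orientations
    orient = np.tile(template, (n_waters, 1, 1))
    axes0 = rng.standard_normal((n_waters, 3))
    axes0 /= np.linalg.norm(axes0, axis=1, keepdims=True)
    orient = np.einsum("nij,nkj->nki",
                       _rotation_matrices(axes0, rng.uniform(0, np.pi, n_waters)),
                       orient)

    centers = sites.copy()
    sigma_step = np.sqrt(2.0 * pop.D_t * dt)
    sigma_angle = np.sqrt(2.0 * pop.D_R * dt)
    imm = assignment == "immobile"
    rot = assignment == "rotor"
    trn = assignment == "translator"

    for t in range(n_frames):
        if t > 0:
            centers[trn] += sigma_step * rng.standard_normal((trn.sum(), 3))
            if rot.any():
                axes = rng.standard_normal((rot.sum(), 3))
                axes /= np.linalg.norm(axes, axis=1, keepdims=True)
                angles = sigma_angle * rng.standard_normal(rot.sum())
                orient[rot] = np.einsum("nij,nkj->nki",
                                        _rotation_matrices(axes, angles),
                                        orient[rot])
        frame_centers = centers.copy()
        if imm.any():
            frame_centers[imm] = sites[imm] + pop.jitter * \
                rng.standard_normal((imm.sum(), 3))
        pos[t] = (frame_centers[:, None, :] + orient).reshape(n_atoms, 3)

    labels, groups, donors, acceptors, oxygens = [], [], [], [], []
    for i in range(n_waters):
        o, h1, h2 = 3 * i, 3 * i + 1, 3 * i + 2
        labels += ["O", "H", "H"]
        groups += ["water"] * 3
        donors += [(o, h1), (o, h2)]
        acceptors.append(o)
        oxygens.append(o)
    topo = Topology(labels=labels, donors=donors, acceptors=acceptors,
                    water_oxygens=oxygens, groups=groups)
    truth = {"assignment": assignment, "seed": seed,
             "D_t": pop.D_t, "D_R": pop.D_R, "jitter": pop.jitter, "b": pop.b}
    return Trajectory(positions=pos, dt=dt, box=box), topo, truth
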