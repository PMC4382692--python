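"""File formats and preprocessing.

All formats are plain tab-separated text with ``#``-commented headers that
record the provenance (sample, seeds, parameters) needed to regenerate the
file.  Spectra are stored as blocks of (q, E, S, sigma) rows; elastic scans
as T-by-q tables with a companion error table in the same file; correlation
functions as (lag, value, count) columns.  Trajectories are standard XYZ
frames (read and written through MDAnalysis) with a tab-separated topology
sidecar declaring donors, hydrogens, acceptors and water oxygens.

Preprocessing mirrors the reduction applied to backscattering data:
re-binning onto wider energy channels (inverse-variance weighted) and
normalization of each q slice to the energy-integrated area of a
low-temperature reference measurement.  The incoherent cross-section
budget utility apportions the total incoherent scattering between
hydration water and (partially H/D exchanged) protein.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .elastic import ElasticScan
from .hbonds import CorrelationFunction, Topology, Trajectory
from .qens_fit import QENSDataset
from .qens_model import ResolutionFunction, Spectrum, SpectrumGrid

__all__ = ["CompositionRecord", "write_spectrum", "read_spectrum",
           "write_resolution", "read_resolution", "write_elastic_scan",
           "read_elastic_scan", "write_correlation", "read_correlation",
           "write_trajectory", "read_trajectory", "write_topology",
           "read_topology", "rebin_energy", "normalize_to_lowT",
           "incoherent_budget"]

SIGMA_INC_H = 80.27   # barn, incoherent cross section of 1H
SIGMA_INC_D = 2.05    # barn, incoherent cross section of 2H


# ---------------------------------------------------------------------------
# spectrum files
# ---------------------------------------------------------------------------

def _write_header(fh, kind: str, metadata: dict) -> None:
    fh.write(f"# aquadyn {kind} v1\n")
    for key, value in metadata.items():
        fh.write(f"# {key}: {value}\n")


def _read_header(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    return meta


def write_spectrum(path, grid: SpectrumGrid, spectrum: Spectrum,
                   metadata: dict | None = None) -> None:
    """Columnar (q, E, S, sigma) text file, one block per q."""
    path = Path(path)
    with path.open("w") as fh:
        _write_header(fh, "spectrum", metadata or {})
        fh.write("# columns: q E S sigma\n")
        err = spectrum.error if spectrum.error is not None \
            else np.zeros_like(spectrum.intensity)
        for iq, q in enumerate(grid.q_values):
            for iE, E in enumerate(grid.E_values):
                fh.write(f"{q:.9g}\t{E:.9g}\t{spectrum.intensity[iq, iE]:.9g}"
                         f"\t{err[iq, iE]:.9g}\n")


def read_spectrum(path, require_errors: bool = True):
    """Read a spectrum file back into (grid, Spectrum, metadata)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = _read_header([l for l in lines if l.startswith("#")])
    body = [l for l in lines if l and not l.startswith("#")]
    if not body:
        raise ValueError(f"{path}: no data rows")
    data = np.array([[float(v) for v in l.split("\t")] for l in body])
    if data.shape[1] < 4:
        raise ValueError(f"{path}: sigma column missing (4 columns required)")
    q_all, E_all, S_all, sig_all = data.T
    q_values, q_index = np.unique(q_all, return_inverse=True)
    n_q = q_values.size
    E_first = E_all[q_index == 0]
    if E_first.size == 0:
        raise ValueError(f"{path}: empty q block")
    dE = np.diff(E_first)
    if dE.size and np.max(np.abs(dE - dE[0])) > 1e-9 * abs(dE[0]):
        bad = int(np.argmax(np.abs(dE - dE[0])))
        raise ValueError(f"{path}: non-uniform E spacing near row {bad + 1} "
                         f"of the first q block")
    intensity = np.empty((n_q, E_first.size))
    error = np.empty_like(intensity)
    for iq in range(n_q):
        sel = q_index == iq
        if np.count_nonzero(sel) != E_first.size:
            raise ValueError(f"{path}: q block {iq} has inconsistent length")
        order = np.argsort(E_all[sel])
        intensity[iq] = S_all[sel][order]
        error[iq] = sig_all[sel][order]
    grid = SpectrumGrid(q_values=q_values, E_values=np.sort(E_first))
    if require_errors and np.any(error <= 0):
        raise ValueError(f"{path}: non-positive sigma; errors are mandatory")
    spec = Spectrum(intensity=intensity,
                    error=error if np.all(error > 0) else None)
    return grid, spec, meta


def write_resolution(path, resolution: ResolutionFunction,
                     metadata: dict | None = None) -> None:
    write_spectrum(path, resolution.grid,
                   Spectrum(intensity=resolution.profiles), metadata)


def read_resolution(path) -> ResolutionFunction:
    grid, spec, _ = read_spectrum(path, require_errors=False)
    # re-normalize: printed precision perturbs the unit area slightly
    areas = spec.intensity.sum(axis=1) * grid.dE
    return ResolutionFunction(grid=grid, profiles=spec.intensity / areas[:, None])


# ---------------------------------------------------------------------------
# elastic scans
# ---------------------------------------------------------------------------

def write_elastic_scan(path, scan: ElasticScan) -> None:
    """T-by-q intensity table plus a companion error table, one file."""
    path = Path(path)
    header = "T\t" + "\t".join(f"{q:.9g}" for q in scan.q_values)
    with path.open("w") as fh:
        _write_header(fh, "elastic-scan", scan.metadata)
        fh.write("# section: intensity\n" + header + "\n")
        for it, T in enumerate(scan.temperatures):
            fh.write(f"{T:.9g}\t" + "\t".join(f"{v:.9g}" for v in scan.intensity[it]) + "\n")
        fh.write("# section: errors\n" + header + "\n")
        for it, T in enumerate(scan.temperatures):
            fh.write(f"{T:.9g}\t" + "\t".join(f"{v:.9g}" for v in scan.error[it]) + "\n")


def read_elastic_scan(path) -> ElasticScan:
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = _read_header([l for l in lines if l.startswith("#")
                         and "section:" not in l])
    sections: dict[str, list[str]] = {}
    current = None
    for line in lines:
        if line.startswith("# section:"):
            current = line.split(":", 1)[1].strip()
            sections[current] = []
        elif current is not None and line and not line.startswith("#"):
            sections[current].append(line)
    if "intensity" not in sections or "errors" not in sections:
        raise ValueError(f"{path}: intensity/errors sections missing")

    def parse(block):
        df = pd.read_csv(_io.StringIO("\n".join(block)), sep="\t")
        T = df["T"].to_numpy(dtype=float)
        q = np.array([float(c) for c in df.columns[1:]])
        return T, q, df.iloc[:, 1:].to_numpy(dtype=float)

    T, q, intensity = parse(sections["intensity"])
    _, _, error = parse(sections["errors"])
    return ElasticScan(temperatures=T, q_values=q, intensity=intensity,
                       error=error, metadata=meta)


# ---------------------------------------------------------------------------
# correlation functions
# ---------------------------------------------------------------------------

def write_correlation(path, corr: CorrelationFunction,
                      metadata: dict | None = None) -> None:
    with Path(path).open("w") as fh:
        _write_header(fh, "correlation", metadata or {})
        fh.write("lag_ps\tvalue\tcount\n")
        for lag, v, c in zip(corr.lags, corr.values, corr.counts):
            fh.write(f"{lag:.9g}\t{v:.9g}\t{int(c)}\n")


def read_correlation(path) -> CorrelationFunction:
    df = pd.read_csv(path, sep="\t", comment="#")
    return CorrelationFunction(lags=df["lag_ps"].to_numpy(),
                               values=df["value"].to_numpy(),
                               counts=df["count"].to_numpy())


# ---------------------------------------------------------------------------
# trajectories and topologies
# ---------------------------------------------------------------------------

def write_trajectory(path, traj: Trajectory, labels: list | None = None) -> None:
    """Standard XYZ frames; the comment line records frame index and dt."""
    n_atoms = traj.n_atoms
    labels = labels or ["X"] * n_atoms
    with Path(path).open("w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"{n_atoms}\nframe {t} dt_ps={traj.dt:g}\n")
            for a in range(n_atoms):
                x, y, z = traj.positions[t, a]
                fh.write(f"{labels[a]} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory(path, dt: float | None = None,
                    box: np.ndarray | None = None) -> Trajectory:
    """Read XYZ frames through MDAnalysis; dt defaults to the value stamped
    in the comment line (1 ps when absent)."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    frames = np.array([u.trajectory.ts.positions.copy()
                       for _ in u.trajectory], dtype=float)
    if dt is None:
        dt = 1.0
        first_comment = Path(path).read_text().splitlines()[1]
        for token in first_comment.split():
            if token.startswith("dt_ps="):
                dt = float(token.split("=", 1)[1])
    return Trajectory(positions=frames, dt=dt, box=box)


def write_topology(path, topo: Topology) -> None:
    """Tab-separated sidecar: index, label, group, role."""
    hydrogen_parent = {h: d for d, h in topo.donors}
    donor_heavy = {d for d, _ in topo.donors}
    acceptors = set(int(a) for a in topo.acceptors)
    oxygens = set(int(o) for o in topo.water_oxygens)
    with Path(path).open("w") as fh:
        fh.write("# aquadyn topology v1\nindex\tlabel\tgroup\troles\n")
        for i, (label, group) in enumerate(zip(topo.labels, topo.groups)):
            roles = []
            if i in donor_heavy:
                roles.append("donor_heavy")
            if i in hydrogen_parent:
                roles.append(f"donor_hydrogen:{hydrogen_parent[i]}")
            if i in acceptors:
                roles.append("acceptor")
            if i in oxygens:
                roles.append("water_oxygen")
            fh.write(f"{i}\t{label}\t{group}\t{','.join(roles) or '-'}\n")


def read_topology(path) -> Topology:
    df = pd.read_csv(path, sep="\t", comment="#")
    labels = df["label"].tolist()
    groups = df["group"].tolist()
    donors, acceptors, oxygens = [], [], []
    for _, row in df.iterrows():
        for role in str(row["roles"]).split(","):
            role = role.strip()
            if role.startswith("donor_hydrogen:"):
                donors.append((int(role.split(":")[1]), int(row["index"])))
            elif role == "acceptor":
                acceptors.append(int(row["index"]))
            elif role == "water_oxygen":
                oxygens.append(int(row["index"]))
    return Topology(labels=labels, donors=sorted(donors),
                    acceptors=np.array(sorted(acceptors), dtype=int),
                    water_oxygens=np.array(sorted(oxygens), dtype=int),
                    groups=groups)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def rebin_energy(grid: SpectrumGrid, spectrum: Spectrum,
                 channel: float = 0.04):
    """Re-bin onto wider energy channels.

    Intensities are averaged per bin with inverse-variance weights and the
    errors combined as 1/sqrt(sum 1/sigma^2).  The bin width must be an
    integer multiple of the native spacing; edge channels are trimmed
    symmetrically so the output grid stays symmetric about E = 0.
    """
    dE = grid.dE
    if channel < dE * (1 - 1e-9):
        raise ValueError("requested channel is smaller than the native spacing")
    m = int(round(channel / dE))
    if abs(channel - m * dE) > 1e-9 * dE:
        raise ValueError("channel must be an integer multiple of the native spacing")
    if m == 1:
        return grid, spectrum
    n_E = grid.n_E
    n_bins = n_E // m
    if n_bins % 2 == 0:
        n_bins -= 1                      # keep a central bin at E = 0
    used = n_bins * m
    start = (n_E - used) // 2
    sl = slice(start, start + used)

    E = grid.E_values[sl].reshape(n_bins, m)
    S = spectrum.intensity[:, sl].reshape(grid.n_q, n_bins, m)
    if spectrum.error is not None:
        w = 1.0 / spectrum.error[:, sl].reshape(grid.n_q, n_bins, m) ** 2
        new_S = (S * w).sum(axis=2) / w.sum(axis=2)
        new_err = 1.0 / np.sqrt(w.sum(axis=2))
    else:
        new_S = S.mean(axis=2)
        new_err = None
    new_grid = SpectrumGrid(q_values=grid.q_values, E_values=E.mean(axis=1))
    return new_grid, Spectrum(intensity=new_S, error=new_err)


def normalize_to_lowT(grid: SpectrumGrid, spectrum: Spectrum,
                      reference: Spectrum) -> Spectrum:
    """Divide each q slice by the energy-integrated area of the reference
    (low-temperature) measurement at that q, propagating errors."""
    if reference.intensity.shape != spectrum.intensity.shape:
        raise ValueError("reference must be on the same grid")
    areas = reference.intensity.sum(axis=1) * grid.dE
    if np.any(areas <= 0):
        raise ValueError("reference area vanishes for some q")
    norm = spectrum.intensity / areas[:, None]
    err = None
    if spectrum.error is not None:
        err = spectrum.error / areas[:, None]
        if reference.error is not None:
            area_err = np.sqrt((reference.error ** 2).sum(axis=1)) * grid.dE
            err = np.sqrt(err ** 2 +
                          (norm * (area_err / areas)[:, None]) ** 2)
    return Spectrum(intensity=norm, error=err)


# ---------------------------------------------------------------------------
# incoherent cross-section budget
# ---------------------------------------------------------------------------

@dataclass
class CompositionRecord:
    """Hydrogen/deuterium inventory of a perdeuterated protein sample.

    ``protein_exchangeable_D`` are the labile deuterons that can swap with
    hydration-water protons; ``protein_nonexchangeable_D`` stay deuterated.
    Cross sections are incoherent, in barn.
    """

    protein_exchangeable_D: float
    protein_nonexchangeable_D: float
    protein_H: float = 0.0
    sigma_H: float = SIGMA_INC_H
    sigma_D: float = SIGMA_INC_D

    def __post_init__(self) -> None:
        if min(self.protein_exchangeable_D, self.protein_nonexchangeable_D,
               self.protein_H) < 0:
            raise ValueError("atom counts must be non-negative")
        if self.sigma_H <= 0 or self.sigma_D <= 0:
            raise ValueError("cross sections must be positive")


def incoherent_budget(composition: CompositionRecord, waters_per_protein: float,
                      exchange_fraction_complete: float = 1.0
                      ) -> tuple[float, float]:
    """Fraction of the total incoherent cross-section from water vs protein.

    The stated fraction of exchangeable protein deuterons is swapped for
    water protons (mass-balanced: the displaced deuterons end up in the
    water).  Returns (water_fraction, protein_fraction), summing to 1.
    """
    if not 0 <= exchange_fraction_complete <= 1:
        raise ValueError("exchange fraction must lie in [0, 1]")
    exchanged = exchange_fraction_complete * composition.protein_exchangeable_D
    protein_H = composition.protein_H + exchanged
    protein_D = (composition.protein_exchangeable_D - exchanged
                 + composition.protein_nonexchangeable_D)
    water_H = 2.0 * waters_per_protein - exchanged
    if water_H < 0:
        raise ValueError("more exchanged deuterons than water hydrogens")
    water_D = exchanged
    water = water_H * composition.sigma_H + water_D * composition.sigma_D
    protein = protein_H * composition.sigma_H + protein_D * composition.sigma_D
    total = water + protein
    if total <= 0:
        raise ValueError("composition carries no incoherent cross-section")
    return water / total, protein / total
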