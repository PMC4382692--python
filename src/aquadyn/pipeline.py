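"""Declarative pipeline runner.

A YAML (or dict) config names a run directory and an ordered list of
stages; every stage logs its parameters and seeds to ``run.log`` and
writes its tables into the run directory.  Two chains are supported:

* QENS: ``simulate_qens`` -> ``preprocess`` -> ``fit`` -> ``report``
* trajectories: ``simulate_hb_markov`` / ``simulate_trajectory`` ->
  ``hbonds`` / ``msd`` -> ``report``; plus ``elastic`` for elastic scans.

File references are validated before any stage runs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from . import io as aio
from . import synthetic as syn
from .elastic import msd_difference, msd_from_elastic, transition_temperature
from .hbonds import (continuous_correlation, intermittent_correlation,
                     rate_series, relaxation_time, water_msd)
from .qens_fit import FitConfig, QENSDataset, global_fit
from .qens_model import ModelParams

__all__ = ["run_pipeline", "validate_config"]

logger = logging.getLogger("aquadyn.pipeline")

KNOWN_STAGES = ("simulate_qens", "preprocess", "fit", "elastic",
                "simulate_hb_markov", "hbonds", "msd", "report")


class PipelineError(RuntimeError):
    pass


def validate_config(config: dict, base: Path) -> None:
    if "stages" not in config or not config["stages"]:
        raise PipelineError("config must name at least one stage")
    for stage in config["stages"]:
        name = stage.get("stage")
        if name not in KNOWN_STAGES:
            raise PipelineError(f"unknown stage: {name!r}")
        for key, value in stage.items():
            if key.endswith("_file") and key != "out_file":
                path = (base / value) if not Path(value).is_absolute() else Path(value)
                if not path.exists():
                    raise PipelineError(f"stage {name}: missing input file {value}")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, run_dir=None) -> dict:
    """Execute the configured stages in order; returns a result bundle."""
    cfg = _load_config(config)
    base = Path(cfg.get("base_dir", "."))
    run_dir = Path(run_dir or cfg.get("run_dir", "aquadyn_run"))
    validate_config(cfg, base)
    run_dir.mkdir(parents=True, exist_ok=True)

    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    state: dict = {"run_dir": run_dir}
    try:
        for stage in cfg["stages"]:
            name = stage["stage"]
            logger.info("stage=%s params=%s", name,
                        {k: v for k, v in stage.items() if k != "stage"})
            _STAGES[name](stage, state, base)
    except Exception as exc:
        logger.error("stage failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return state


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _resolve(base: Path, value: str) -> Path:
    p = Path(value)
    return p if p.is_absolute() else base / p


def _stage_simulate_qens(stage: dict, state: dict, base: Path) -> None:
    n_q = int(stage.get("n_q", 10))
    grid = syn.default_qens_grid(n_q=n_q)
    resolution = syn.generate_resolution(grid)
    truth = ModelParams.from_dict(stage["truth"]) if "truth" in stage \
        else syn.default_qens_truth(n_q=n_q)
    noise = syn.NoiseSpec(c=float(stage.get("noise_c", 0.02)),
                          seed=int(stage.get("seed", 0)))
    dataset = syn.generate_qens_dataset(
        truth, grid, resolution, noise,
        variant=stage.get("variant", "additive"),
        temperature=float(stage.get("temperature", 300.0)))
    state["dataset"] = dataset
    out = state["run_dir"] / stage.get("out_file", "spectrum.tsv")
    aio.write_spectrum(out, grid, dataset.spectrum, dataset.metadata)
    logger.info("wrote %s (seed=%d)", out, noise.seed)


def _stage_preprocess(stage: dict, state: dict, base: Path) -> None:
    dataset: QENSDataset = state["dataset"]
    grid, spec = dataset.grid, dataset.spectrum
    if "rebin_channel" in stage:
        grid, spec = aio.rebin_energy(grid, spec,
                                      channel=float(stage["rebin_channel"]))
        resolution = syn.generate_resolution(grid)
        state["dataset"] = QENSDataset(grid=grid, spectrum=spec,
                                       resolution=resolution,
                                       temperature=dataset.temperature,
                                       metadata=dataset.metadata)
        logger.info("rebinned to %g ueV channels", float(stage["rebin_channel"]))


def _stage_fit(stage: dict, state: dict, base: Path) -> None:
    if "spectrum_file" in stage:
        grid, spec, meta = aio.read_spectrum(_resolve(base, stage["spectrum_file"]))
        resolution = syn.generate_resolution(grid)
        dataset = QENSDataset(grid=grid, spectrum=spec, resolution=resolution,
                              temperature=float(meta.get("temperature", 300.0)),
                              metadata=meta)
    else:
        dataset = state["dataset"]
    cfg = FitConfig(variant=stage.get("variant", "additive"),
                    seed=int(stage.get("seed", 0)),
                    multistart_count=int(stage.get("multistart_count", 3)))
    result = global_fit(dataset, cfg)
    state["fit_result"] = result
    out = state["run_dir"] / stage.get("out_file", "fit_report.txt")
    text = result.report()
    truth = dataset.metadata.get("truth")
    if truth is not None:
        tp = ModelParams.from_dict(truth) if isinstance(truth, dict) else None
        if tp is not None:
            ft, fr, fi = tp.fractions()
            text += (f"\ntruth_f_t={ft:.6g}\ntruth_f_r={fr:.6g}"
                     f"\ntruth_f_i={fi:.6g}")
    out.write_text(text + "\n")
    logger.info("chi2_reduced=%.4f fractions=%s", result.chi2_reduced,
                result.fractions)


def _stage_elastic(stage: dict, state: dict, base: Path) -> None:
    if "scan_file" in stage:
        hydrated = aio.read_elastic_scan(_resolve(base, stage["scan_file"]))
        dry = aio.read_elastic_scan(_resolve(base, stage["dry_scan_file"])) \
            if "dry_scan_file" in stage else None
    else:
        T = np.arange(*stage.get("T_range", (20.0, 310.0, 10.0)))
        q = np.linspace(0.46, 1.4, int(stage.get("n_q", 10)))
        seed = int(stage.get("seed", 0))
        profile = syn.hinge_msd_profile(
            T_star=float(stage.get("T_star", 240.0)),
            slope_low=float(stage.get("slope_low", 0.001)),
            slope_high=float(stage.get("slope_high", 0.005)))
        hydrated = syn.generate_elastic_scan(profile, T, q, seed=seed)
        dry = syn.generate_elastic_scan(
            syn.hinge_msd_profile(T_star=1e9, slope_low=0.001, slope_high=0.001),
            T, q, seed=seed + 1)
    msd_h = msd_from_elastic(hydrated)
    rows = {"T": msd_h.temperatures, "msd_hydrated": msd_h.msd,
            "msd_hydrated_err": msd_h.error}
    if dry is not None:
        msd_d = msd_from_elastic(dry)
        diff = msd_difference(msd_h, msd_d)
        result = transition_temperature(diff)
        rows.update({"msd_dry": msd_d.msd, "delta_msd": diff.msd})
        state["transition"] = result
        logger.info("transition detected=%s T_d=%s", result.detected,
                    result.temperature)
    import pandas as pd
    out = state["run_dir"] / stage.get("out_file", "msd.tsv")
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    state["msd_table"] = rows


def _stage_simulate_hb_markov(stage: dict, state: dict, base: Path) -> None:
    spec = syn.MarkovHBSpec(
        k_off=float(stage.get("k_off", 0.1)),
        k_on=float(stage.get("k_on", 0.02)),
        n_pairs=int(stage.get("n_pairs", 500)),
        n_frames=int(stage.get("n_frames", 4000)),
        dt=float(stage.get("dt", 1.0)),
        seed=int(stage.get("seed", 0)))
    series, oracle = syn.generate_hb_markov_series(spec)
    state["hb_series"], state["hb_oracle"] = series, oracle
    logger.info("markov series: %d pairs x %d frames, seed=%d",
                spec.n_pairs, spec.n_frames, spec.seed)


def _stage_hbonds(stage: dict, state: dict, base: Path) -> None:
    if "trajectory_file" in stage:
        traj = aio.read_trajectory(_resolve(base, stage["trajectory_file"]))
        topo = aio.read_topology(_resolve(base, stage["topology_file"]))
        from .hbonds import hb_timeseries
        series = hb_timeseries(traj, topo)
    else:
        series = state["hb_series"]
    max_lag = stage.get("max_lag")
    S = continuous_correlation(series, max_lag=max_lag)
    C = intermittent_correlation(series, max_lag=max_lag)
    tau_c = relaxation_time(S)
    tau_i = relaxation_time(C)
    state["tau_hbc"], state["tau_hbi"] = tau_c, tau_i
    meta = {"dt_ps": series.dt, "n_pairs": series.n_pairs}
    aio.write_correlation(state["run_dir"] / "s_hb.tsv", S, meta)
    aio.write_correlation(state["run_dir"] / "c_hb.tsv", C, meta)
    lines = [f"tau_hbc_ps={tau_c.tau:.6g} method={tau_c.method}",
             f"tau_hbi_ps={tau_i.tau:.6g} method={tau_i.method}"]
    oracle = state.get("hb_oracle")
    if oracle is not None:
        lines += [f"oracle_k_off={oracle.k_off:g}",
                  f"oracle_k_on={oracle.k_on:g}",
                  f"oracle_p_eq={oracle.p_eq:.6g}"]
    (state["run_dir"] / "hb_times.txt").write_text("\n".join(lines) + "\n")
    logger.info("tau_hbc=%.4g ps, tau_hbi=%.4g ps", tau_c.tau, tau_i.tau)


def _stage_msd(stage: dict, state: dict, base: Path) -> None:
    if "trajectory_file" in stage:
        traj = aio.read_trajectory(_resolve(base, stage["trajectory_file"]))
        topo = aio.read_topology(_resolve(base, stage["topology_file"]))
    else:
        pop = syn.PopulationSpec()
        traj, topo, _ = syn.generate_water_trajectory(
            pop, n_waters=int(stage.get("n_waters", 100)),
            n_frames=int(stage.get("n_frames", 201)),
            seed=int(stage.get("seed", 0)))
    lag = float(stage.get("lag", 100.0))
    msd = water_msd(traj, topo.water_oxygens, lag=lag)
    state["water_msd"] = msd
    (state["run_dir"] / "water_msd.txt").write_text(
        f"lag_ps={lag:g}\nmsd_A2={msd:.6g}\n")
    logger.info("water MSD(%g ps) = %.4g A^2", lag, msd)


def _stage_report(stage: dict, state: dict, base: Path) -> None:
    records = []
    rec = {"T": float(stage.get("temperature", 300.0))}
    if "tau_hbc" in state:
        rec["tau_hbc"] = state["tau_hbc"].tau
    if "tau_hbi" in state:
        rec["tau_hbi"] = state["tau_hbi"].tau
    if "water_msd" in state:
        rec["msd_100ps"] = state["water_msd"]
    records.append(rec)
    table = rate_series(records)
    out = state["run_dir"] / stage.get("out_file", "rates.tsv")
    table.to_csv(out, sep="\t", index=False, na_rep="NA")
    state["rate_table"] = table


_STAGES = {
    "simulate_qens": _stage_simulate_qens,
    "preprocess": _stage_preprocess,
    "fit": _stage_fit,
    "elastic": _stage_elastic,
    "simulate_hb_markov": _stage_simulate_hb_markov,
    "hbonds": _stage_hbonds,
    "msd": _stage_msd,
    "report": _stage_report,
}
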