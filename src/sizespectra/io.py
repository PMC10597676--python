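"""Run orchestration and tabular I/O.

Each run writes a small directory of CSVs (annual biomass, era-mean
spectra, diagnostics) plus its resolved config; an experiment sweeps whole
sets, collects per-run metrics, and emits the control vs trait-resolved
percentage contrasts.  All floats are written at 10 significant digits so
re-running an identical spec reproduces byte-identical tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ExperimentSet, ModelConfig, build_control_set, build_fg_set, \
    build_feeding_only_set
from .core import CommunityState, Simulation, SimulationResult, run_simulation
from .metrics import MetricsResult, compare_sets, evaluate_run, summarize_set

log = logging.getLogger("sizespectra")

FLOAT_FMT = "%.10g"

#: The headline contrast metrics, treatment vs control.
CONTRAST_METRICS = ("total_biomass", "production", "inv_cv", "pb_rate")


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        return ModelConfig.from_dict(yaml.safe_load(fh))


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_run_outputs(outdir, result: SimulationResult,
                      metrics: MetricsResult | None = None) -> Path:
    """Write biomass_annual.csv, spectrum_mean.csv, diagnostics.csv (+curves)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(result.config, outdir / "config.yaml")

    result.biomass_frame().to_csv(outdir / "biomass_annual.csv",
                                  index=False, float_format=FLOAT_FMT)

    g = result.mean_state.grid
    rows = []
    for name, arr in result.mean_state.N.items():
        s = g.group_slices[name]
        for x, dens in zip(g.log10_centers[s], arr[s]):
            rows.append({"log10_mass": x, "group": name, "mean_density": dens})
    pd.DataFrame(rows).to_csv(outdir / "spectrum_mean.csv",
                              index=False, float_format=FLOAT_FMT)

    pd.DataFrame([result.diagnostics]).to_csv(outdir / "diagnostics.csv",
                                              index=False, float_format=FLOAT_FMT)

    if metrics is not None:
        for fname, curves in (("curves_rtp.csv", metrics.rtp),
                              ("curves_ppmr.csv", metrics.realised_ppmr)):
            rows = [{"log10_mass": x, "group": n, "value": v}
                    for n, (xs, vs) in curves.items() for x, v in zip(xs, vs)]
            pd.DataFrame(rows).to_csv(outdir / fname, index=False,
                                      float_format=FLOAT_FMT)
    return outdir


def read_run_dir(path):
    """Rebuild (config, era-mean state, annual total biomass) from a run dir."""
    path = Path(path)
    config = load_config(path / "config.yaml")
    sim = Simulation(config)
    spec = pd.read_csv(path / "spectrum_mean.csv")
    N = {}
    for name, sub in spec.groupby("group"):
        arr = np.zeros(sim.grid.n_bins)
        s = sim.grid.group_slices[name]
        arr[s] = sub.sort_values("log10_mass")["mean_density"].to_numpy()
        N[name] = arr
    state = CommunityState(time=float(config.years), grid=sim.grid, N=N,
                           phyto=sim.phyto, phyto_density=sim.phyto_density)
    bio = pd.read_csv(path / "biomass_annual.csv")
    total = bio.groupby("year")["biomass"].sum().sort_index().to_numpy()
    return config, sim, state, total


def run_set(expset: ExperimentSet, outdir=None, curves: bool = False):
    """Run every config of a set; returns (metrics list, manifest rows).

    A failed run is logged, recorded in the manifest and excluded from the
    metrics, so set summaries are computed on the survivors.
    """
    results, manifest = [], []
    for cfg in expset.configs:
        row = {"set": expset.name, "label": cfg.label,
               **{f"sweep_{k}": v for k, v in cfg.sweep_coords.items()},
               "config_hash": cfg.content_hash()}
        try:
            sim = Simulation(cfg)
            res = run_simulation(cfg, sim=sim)
            m = evaluate_run(res, sim=sim, curves=curves)
            if outdir is not None:
                rdir = Path(outdir) / expset.name / cfg.label
                write_run_outputs(rdir, res, m if curves else None)
                row["path"] = str(rdir)
            row["status"] = "ok"
            results.append(m)
        except Exception as exc:  # noqa: BLE001 - survivors still summarized
            log.warning("run %s failed: %s", cfg.label, exc)
            row["status"] = f"failed: {exc}"
        manifest.append(row)
    return results, manifest


def _metrics_frame(metrics, set_name):
    rows = []
    for m in metrics:
        row = {"set": set_name, "label": m.label,
               **{f"sweep_{k}": v for k, v in m.sweep_coords.items()},
               **m.scalars()}
        rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(base: ModelConfig, outdir=None,
                   include_feeding_only: bool = False,
                   write_runs: bool = False) -> dict:
    """The full control vs trait-resolved experiment.

    Runs the 3-config control set and the 27-config feeding+growth set
    (optionally also the 27-config feeding-only set), evaluates per-run
    metrics, and reports the percent change of the F+G medians relative to
    control for biomass, production, stability (1/CV) and turnover rate
    (P/B).  Writes metrics_per_run.csv, metrics_set_summary.csv,
    comparison.csv and manifest.csv when `outdir` is given.
    """
    sets = {"control": build_control_set(base),
            "feeding_growth": build_fg_set(base)}
    if include_feeding_only:
        sets["feeding_only"] = build_feeding_only_set(base)

    all_metrics, manifest = {}, []
    for name, es in sets.items():
        log.info("running set %s (%d configs)", name, len(es.configs))
        ms, man = run_set(es, outdir=outdir if write_runs else None)
        all_metrics[name] = ms
        manifest.extend(man)
        n_fail = sum(1 for r in man if r["status"] != "ok")
        if n_fail:
            log.warning("set %s: %d of %d runs failed; summaries use the "
                        "survivors", name, n_fail, len(es.configs))

    summaries = {n: summarize_set(ms) for n, ms in all_metrics.items()}
    comparisons = {n: compare_sets(summaries["control"], summaries[n])
                   for n in all_metrics if n != "control"}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_run = pd.concat([_metrics_frame(ms, n)
                             for n, ms in all_metrics.items()],
                            ignore_index=True)
        per_run.to_csv(outdir / "metrics_per_run.csv", index=False,
                       float_format=FLOAT_FMT)
        srows = [{"set": n, "metric": m, **v}
                 for n, s in summaries.items() for m, v in s.items()]
        pd.DataFrame(srows).to_csv(outdir / "metrics_set_summary.csv",
                                   index=False, float_format=FLOAT_FMT)
        crows = [{"treatment": n, "metric": m, "pct_change_vs_control": v}
                 for n, c in comparisons.items() for m, v in c.items()]
        pd.DataFrame(crows).to_csv(outdir / "comparison.csv", index=False,
                                   float_format=FLOAT_FMT)
        pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False,
                                      float_format=FLOAT_FMT)

    return {"metrics": all_metrics, "summaries": summaries,
            "comparisons": comparisons, "manifest": manifest}
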