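"""End-to-end orchestration: configuration, dataset I/O and staged runs."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, decoding, encoding, roc, synth
from . import task as T
from .population import BinnedPopulation

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults follow the study's stated parameters."""

    seed: int = 0
    preset: str | None = "paper_like"
    input_dir: str | None = None          # instead of a preset
    outdir: str = "pmdarith_out"
    n_cells: int | None = None
    bin_width_ms: int = 100
    alpha_regression: float = 0.01
    alpha_permutation: float = 0.05
    n_perm: int = 1000
    cv_folds: int = 10
    min_trials_per_condition: int = 10
    decode_bins: int | None = None        # None = all 24
    exclude_extremes: bool = False

    def __post_init__(self) -> None:
        for a in (self.alpha_regression, self.alpha_permutation):
            if not 0 < a < 1:
                raise ValueError("significance levels must be in (0, 1)")
        if T.DEFAULT_TIMELINE.concern_duration_ms % self.bin_width_ms:
            raise ValueError("bin width must divide the 2400-ms concern period")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_dataset(input_dir: str | Path) -> synth.SyntheticDataset:
    """Load a dataset written by :meth:`synth.SyntheticDataset.write`."""
    d = Path(input_dir)
    for name in ("trials.csv", "population.h5"):
        if not (d / name).exists():
            raise FileNotFoundError(
                f"{d / name} not found: run the simulate stage (or point "
                f"--input at a dataset directory) first")
    raw_path = d / "trials_raw.csv"
    raw = T.read_trials(raw_path) if raw_path.exists() else T.read_trials(d / "trials.csv")
    pop = BinnedPopulation.load(d / "population.h5")
    gt_path = d / "ground_truth.csv"
    gt = pd.read_csv(gt_path) if gt_path.exists() else pd.DataFrame()
    ipop_path = d / "instructed_population.h5"
    ipop = BinnedPopulation.load(ipop_path) if ipop_path.exists() else None
    return synth.SyntheticDataset(
        preset="loaded", raw_trials=raw, trials=pop.trials, pop=pop,
        ground_truth=gt, profiles=[],
        instructed_raw=None,
        instructed_trials=ipop.trials if ipop is not None else None,
        instructed_pop=ipop,
    )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def behavior_stage(ds: synth.SyntheticDataset, cfg: PipelineConfig) -> dict:
    trials = ds.raw_trials
    num = trials[trials["task"] == T.TASK_NUMERICAL]
    mat = behavior.selection_rates(num, by="target")
    perf = behavior.performance_vs_chance(num, chance=0.25)
    fits = behavior.fit_gaussian_tuning(mat)
    size = behavior.size_effect_regression(fits)
    labelled = ds.trials
    rt = behavior.rt_congruency_contrast(labelled)
    return {
        "selection_rates": mat, "performance": perf,
        "gaussian_fits": fits, "size_effect": size, "rt_contrast": rt,
        "summary": {
            "all_targets_above_chance": bool((perf["p"] < 0.01).all()),
            "size_effect_slope": size["slope"], "size_effect_p": size["p"],
        },
    }


def encoding_stage(ds: synth.SyntheticDataset, cfg: PipelineConfig) -> dict:
    reg = encoding.binwise_regression(ds.pop, alpha=cfg.alpha_regression)
    hist = encoding.build_coding_history(reg)
    candidates = hist.per_period[:, list(hist.periods).index("preop"),
                                 list(hist.factors).index("arithmetic")]
    if ds.instructed_pop is not None:
        ireg = encoding.regress_instruction(ds.instructed_pop,
                                            alpha=cfg.alpha_regression)
        selective, unevaluable = encoding.instructed_task_filter(candidates, ireg)
    else:
        selective, unevaluable = candidates, np.zeros_like(candidates)
    table, counts = encoding.categorize_cells(hist, selective)
    tracking = encoding.period_selectivity_tracking(hist, selective)
    return {"regression": reg, "history": hist, "selective": selective,
            "unevaluable": unevaluable, "categories": table,
            "counts": counts, "tracking": tracking}


def roc_stage(ds: synth.SyntheticDataset, enc: dict, cfg: PipelineConfig) -> dict:
    selective = np.asarray(enc["selective"], bool)
    cells = np.flatnonzero(selective) if selective.any() else np.arange(ds.pop.n_cells)
    traj = roc.roc_trajectories(ds.pop, cells=cells)
    relvar = {f: roc.relative_variance(traj, f)
              for f in ("arithmetic", "hand", "step")}
    coders = roc.select_simultaneous_coders(
        ds.pop, cells, n_perm=cfg.n_perm, alpha=cfg.alpha_permutation,
        seed=cfg.seed)
    quad = roc.quadrant_fraction_timecourse(coders, traj)
    return {"trajectories": traj, "relative_variance": relvar,
            "coders": coders, "quadrants": quad}


def decoding_stage(ds: synth.SyntheticDataset, cfg: PipelineConfig,
                   cells: np.ndarray | None = None) -> dict:
    pp = decoding.build_pseudopopulation(
        ds.pop, cells=cells, min_per_condition=cfg.min_trials_per_condition,
        seed=cfg.seed)
    bins = (np.linspace(0, pp.n_bins - 1, cfg.decode_bins).astype(int)
            if cfg.decode_bins else None)
    out = {}
    for system in ("arithmetic", "hand"):
        grid = decoding.crosstemporal_decode(pp, system, folds=cfg.cv_folds,
                                             seed=cfg.seed, bins=bins)
        grid = decoding.permutation_significance(
            pp, grid, n_perm=cfg.n_perm, alpha=cfg.alpha_permutation,
            seed=cfg.seed)
        out[system] = grid
    xop = decoding.cross_operation_decode(pp, "arithmetic", "hand",
                                          folds=cfg.cv_folds, seed=cfg.seed,
                                          bins=bins)
    xop = decoding.permutation_significance(pp, xop, n_perm=cfg.n_perm,
                                            alpha=cfg.alpha_permutation,
                                            seed=cfg.seed)
    out["cross_operation"] = xop
    out["cross_operation_summary"] = decoding.prospective_retrospective_summary(xop)
    return out


def _write_grid(grid, outdir: Path, name: str) -> list[str]:
    files = []
    np.savetxt(outdir / f"{name}_accuracy.csv", grid.accuracy, delimiter=",")
    files.append(f"{name}_accuracy.csv")
    if grid.mask is not None:
        np.savetxt(outdir / f"{name}_mask.csv", grid.mask.astype(int),
                   fmt="%d", delimiter=",")
        files.append(f"{name}_mask.csv")
    return files


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write all stage outputs plus a run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(cfg), "version": __version__,
                "stages": {}, "files": []}
    results: dict = {}
    t_all = time.time()

    def stage(name, fn):
        t0 = time.time()
        try:
            results[name] = fn()
        except Exception as e:  # noqa: BLE001 - stage-named reporting
            manifest["stages"][name] = {"status": "failed", "error": str(e)}
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, default=_json_default))
            raise StageError(name, e) from e
        manifest["stages"][name] = {"status": "ok",
                                    "seconds": round(time.time() - t0, 3)}

    if cfg.input_dir:
        stage("load", lambda: load_dataset(cfg.input_dir))
        ds = results["load"]
    else:
        stage("simulate", lambda: synth.make_fixture_dataset(
            cfg.preset, seed=cfg.seed, n_cells=cfg.n_cells, outdir=outdir / "data"))
        ds = results["simulate"]
        manifest["files"] += [f"data/{f}" for f in ds.write(outdir / "data").values()]

    stage("behavior", lambda: behavior_stage(ds, cfg))
    stage("encoding", lambda: encoding_stage(ds, cfg))
    stage("roc", lambda: roc_stage(ds, results["encoding"], cfg))
    stage("decoding", lambda: decoding_stage(ds, cfg))

    # -- persist stage outputs ----------------------------------------------
    beh = results["behavior"]
    beh["performance"].to_csv(outdir / "behavior_performance.csv", index=False)
    beh["gaussian_fits"].table.to_csv(outdir / "behavior_gaussian_fits.csv", index=False)
    beh["rt_contrast"].to_csv(outdir / "behavior_rt_contrast.csv", index=False)
    manifest["files"] += ["behavior_performance.csv", "behavior_gaussian_fits.csv",
                          "behavior_rt_contrast.csv"]
    enc = results["encoding"]
    enc["categories"].to_csv(outdir / "cell_categories.csv", index=False)
    manifest["files"].append("cell_categories.csv")
    rocres = results["roc"]
    rocres["trajectories"].to_frame().to_csv(outdir / "roc_trajectories.csv",
                                             index=False)
    rocres["coders"].to_csv(outdir / "simultaneous_coders.csv", index=False)
    manifest["files"] += ["roc_trajectories.csv", "simultaneous_coders.csv"]
    dec = results["decoding"]
    for name in ("arithmetic", "hand", "cross_operation"):
        manifest["files"] += _write_grid(dec[name], outdir, f"decode_{name}")

    tracking = enc["tracking"]
    no_pop_effects = (
        enc["counts"].get("arithmetic_selective", enc["counts"]["arithmetic_related"]) == 0
    )
    summary = {
        "behavior": beh["summary"],
        "cell_counts": enc["counts"],
        "exclusive_arithmetic": {k: v for k, v in tracking.items()
                                 if k != "discordant"},
        "quadrant_summary": rocres["quadrants"].summary,
        "cross_operation": dec["cross_operation_summary"].as_dict(),
        "flags": {"no_significant_population_effects": bool(no_pop_effects)},
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=_json_default))
    manifest["files"].append("summary.json")
    manifest["seconds_total"] = round(time.time() - t_all, 3)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default))
    manifest["files"].append("manifest.json")
    results["summary"] = summary
    results["manifest"] = manifest
    return results
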