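"""End-to-end orchestration: simulate -> dmt -> dmc-merge -> overlap ->
annotate -> timing, with a machine-readable report.

The run directory is append-only: config, per-stage outputs, stage counts
and a manifest of output hashes, so a rerun with the same seed/config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from methylkin import context as ctx
from methylkin import merging, overlap, tiling, timing
from methylkin.constants import DEFAULTS
from methylkin.intervals import merge_bookended
from methylkin.io import write_regions
from methylkin.simulate import SimulationConfig, simulate_annotation, \
    simulate_chip_track, simulate_developmental_tracks, simulate_methylomes
from methylkin.stats import proportion


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Simulation parameters plus every analysis threshold."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "methylkin_run"
    tile_size: int = DEFAULTS["tile_size"]
    min_cpgs: int = DEFAULTS["min_cpgs"]
    min_cov: int = DEFAULTS["min_cov"]
    min_diff: float = DEFAULTS["min_diff"]
    q_threshold: float = DEFAULTS["q_threshold"]
    gap: int = DEFAULTS["gap"]
    flank: int = DEFAULTS["flank"]
    fold_threshold: float = DEFAULTS["fold_threshold"]
    background_n: int = DEFAULTS["background_n"]
    method: str = "logistic"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["cohorts"] = list(d["sim"]["cohorts"])
        d["sim"]["timepoints"] = list(d["sim"]["timepoints"])
        d["sim"]["young_subfamilies"] = list(d["sim"]["young_subfamilies"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; see module docstring."""
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "stages": {}}
    results: dict = {}

    def stage(name, fn):
        try:
            results[name] = fn()
        except Exception as exc:  # abort with stage name and cause
            raise PipelineError(name, exc) from exc

    stage("simulate", lambda: _stage_simulate(config))
    stage("dmt", lambda: _stage_dmt(config, results["simulate"], report))
    stage("dmc_merge", lambda: _stage_dmc(config, results["simulate"], report))
    stage("overlap", lambda: _stage_overlap(config, results, report))
    stage("annotate", lambda: _stage_annotate(config, results, report))
    stage("timing", lambda: _stage_timing(config, results, report))
    stage("report_files", lambda: _stage_report(config, report))
    return {**results, "report": report}


def _stage_simulate(config: RunConfig):
    annotation, truth = simulate_annotation(config.sim)
    methylomes = simulate_methylomes(annotation, truth, config.sim)
    tracks = simulate_developmental_tracks(annotation, truth, config.sim)
    chip = simulate_chip_track(annotation, truth, config.sim)
    with open(os.path.join(config.outdir, "config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    return {"annotation": annotation, "truth": truth,
            "methylomes": methylomes, "tracks": tracks, "chip": chip}


def _stage_dmt(config: RunConfig, sim, report):
    out = {}
    for cohort, groups in sim["methylomes"].items():
        res = tiling.dmt_workflow(
            groups["control"], groups["mutant"], tile_size=config.tile_size,
            min_cpgs=config.min_cpgs, min_cov=config.min_cov,
            min_diff=config.min_diff, q_threshold=config.q_threshold,
            method=config.method)
        dmts = res["dmts"]
        hypo = int((dmts["direction"] == "hypo").sum()) if len(dmts) else 0
        report["stages"][f"dmt_{cohort}"] = {
            "tiles_built": res["tile_data"].n_tiles,
            "tiles_tested": int((res["tiles"]["status"] == "tested").sum()),
            "n_dmts": int(len(dmts)),
            "n_hypo": hypo,
            "n_hyper": int(len(dmts)) - hypo,
            "magnitude_bins": tiling.magnitude_histogram(dmts),
        }
        write_regions(res["tiles"], os.path.join(
            config.outdir, f"tiles_{cohort}.tsv"), format="tsv")
        write_regions(dmts, os.path.join(
            config.outdir, f"dmts_{cohort}.tsv"), format="tsv")
        out[cohort] = res
    return out


def _stage_dmc(config: RunConfig, sim, report):
    out = {}
    for cohort, groups in sim["methylomes"].items():
        tested, dmcs = merging.call_dmcs(
            groups["control"], groups["mutant"], min_cov=config.min_cov,
            min_diff=config.min_diff, q_threshold=config.q_threshold,
            method=config.method)
        hypo = dmcs[dmcs["direction"] == "hypo"] if len(dmcs) else dmcs
        dmrs, singles = merging.merge_dmcs(hypo, gap=config.gap,
                                           direction="hypo")
        report["stages"][f"dmc_{cohort}"] = {
            "cpgs_tested": int(len(tested)),
            "n_dmcs": int(len(dmcs)),
            "n_hypo_dmcs": int(len(hypo)),
            "n_dmrs": int(len(dmrs)),
            "n_singles": int(len(singles)),
            "size_classes": {k: v for k, v in merging.size_classes(dmrs).items()
                             if k != "sizes"},
        }
        write_regions(dmrs, os.path.join(config.outdir, f"dmrs_{cohort}.bed"),
                      format="bed")
        write_regions(singles, os.path.join(
            config.outdir, f"singles_{cohort}.tsv"), format="tsv")
        out[cohort] = {"tested": tested, "dmcs": dmcs, "dmrs": dmrs,
                       "singles": singles}
    return out


def _hypo_tiles(dmt_result) -> pd.DataFrame:
    dmts = dmt_result["dmts"]
    if len(dmts) == 0:
        return dmts
    return dmts[dmts["direction"] == "hypo"]


def _stage_overlap(config: RunConfig, results, report):
    cohorts = list(results["simulate"]["methylomes"])
    out = {}
    if len(cohorts) >= 2:
        a, b = cohorts[0], cohorts[1]
        tiles = overlap.intersect_tiles(
            _hypo_tiles(results["dmt"][a]), _hypo_tiles(results["dmt"][b]),
            tile_size=config.tile_size)
        tiles.pop("shared_keys", None)
        regions = overlap.overlap_dmr_sets(results["dmc_merge"][a]["dmrs"],
                                           results["dmc_merge"][b]["dmrs"])
        out["tiles"] = tiles
        out["regions"] = regions["summary"]
        report["stages"]["overlap"] = {"tiles": tiles,
                                       "regions": regions["summary"]}
    if len(cohorts) >= 3:
        tw = overlap.three_way(
            _hypo_tiles(results["dmt"][cohorts[0]]),
            _hypo_tiles(results["dmt"][cohorts[1]]),
            _hypo_tiles(results["dmt"][cohorts[2]]),
            tile_size=config.tile_size)
        out["three_way"] = tw
        report["stages"]["overlap_three_way"] = tw
    return out


def _stage_annotate(config: RunConfig, results, report):
    sim = results["simulate"]
    annotation = sim["annotation"]
    cohort = list(sim["methylomes"])[0]
    dmrs = results["dmc_merge"][cohort]["dmrs"]
    tiles = results["dmt"][cohort]["tiles"]
    background = merge_bookended(tiles[["chrom", "start", "end"]])
    out = {
        "elements": ctx.element_distribution(dmrs, annotation.genes),
        "cgi": ctx.cgi_distribution(dmrs, annotation.cgis),
    }
    if annotation.repeats:
        comp = ctx.repeat_composition(dmrs, annotation.repeats, background)
        young = ctx.young_line_overlap(dmrs, annotation.repeats, background,
                                       config.sim.young_subfamilies)
        out["repeat_fg"] = comp["fg_counts"]
        out["repeat_bg"] = comp.get("bg_counts")
        out["young_line"] = {
            "fg_count": young.fg_count, "fg_total": young.fg_total,
            "bg_count": young.bg_count, "bg_total": young.bg_total,
            "fold": young.fold, "chi2": young.chi2, "p": young.p}
    report["stages"]["annotate"] = _jsonable(out)
    return {"background": background, **out}


def _stage_timing(config: RunConfig, results, report):
    sim = results["simulate"]
    cohort = list(sim["methylomes"])[0]
    dmrs = results["dmc_merge"][cohort]["dmrs"]
    tracks = sim["tracks"]
    timepoints = config.sim.timepoints
    bins = timing.bin_genome(sim["annotation"].chrom_sizes)
    n_bg = min(config.background_n, len(bins))
    background = timing.sample_background(bins, n=n_bg, seed=config.sim.seed)
    out = {}
    if len(dmrs):
        traj = timing.trajectory_matrix(dmrs, tracks, timepoints=timepoints)
        labels = timing.classify_timing_matrix(traj)
        out["dmr_trajectory_mean"] = traj.mean().round(2).to_dict()
        out["dmr_timing"] = labels.value_counts().to_dict()
    bg_traj = timing.trajectory_matrix(background, tracks, timepoints=timepoints)
    out["background_trajectory_mean"] = bg_traj.mean().round(2).to_dict()
    e16 = timepoints[1]
    chip = sim["chip"][e16]
    if len(dmrs):
        prof = timing.joint_profile(dmrs, tracks[e16], chip["reads"],
                                    chip["library_size"])
        out["e16_joint_mean"] = {"meth": float(np.nanmean(prof["meth"])) if len(prof) else None,
                                 "rpkm": float(prof["rpkm"].mean()) if len(prof) else None}
        bg_rpkm = timing.rpkm(background, chip["reads"], chip["library_size"])
        out["e16_background_rpkm"] = float(bg_rpkm.mean())
    report["stages"]["timing"] = _jsonable(out)
    return out


def _stage_report(config: RunConfig, report):
    path = os.path.join(config.outdir, "report.json")
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    txt = format_report(report)
    with open(os.path.join(config.outdir, "report.txt"), "w") as fh:
        fh.write(txt)
    return {"path": path}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_report(run_dir) -> dict:
    path = os.path.join(run_dir, "report.json")
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"incomplete run: missing report.json under {run_dir}")
    with open(path) as fh:
        return json.load(fh)


def format_report(report: dict) -> str:
    """Human-readable stage summary; percentages recomputed from counts."""
    lines = [f"methylkin run (config {report.get('config_hash', '?')})", ""]
    stages = report.get("stages", {})
    for name in sorted(stages):
        lines.append(f"[{name}]")
        entry = stages[name]
        for key, val in entry.items():
            lines.append(f"  {key}: {val}")
        if name.startswith("dmt_"):
            total = entry.get("n_dmts", 0)
            if total:
                lines.append(
                    f"  pct_hypo: {proportion(entry['n_hypo'], total)}")
        lines.append("")
    return "\n".join(lines)
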