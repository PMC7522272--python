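"""End-to-end pipeline: simulate -> segment -> analyze -> score-nba -> stats.

Every stage writes plain-text/TIFF artifacts into the output directory; the
manifest lists each file with a SHA-256 content hash so that a fixed
config + seed reproduces byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
import numpy as np
import pandas as pd

from . import nba as nba_mod
from . import segmentation as seg
from . import stats as st
from . import synthetic as syn
from . import waveform as wf
from .errors import OPWFError
from .io import (
    PipelineConfig,
    read_frame_sequence,
    read_series_dataset,
    write_frame_sequence,
    write_longitudinal_dataset,
    write_masks,
    write_nba_table,
    write_pwf_table,
    write_series_dataset,
)

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_segment",
    "stage_analyze",
    "stage_score_nba",
    "stage_stats",
]

log = logging.getLogger("opwf")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def stage_simulate(config: PipelineConfig) -> list[Path]:
    out = config.out_dir
    study = config.study
    dataset = syn.simulate_longitudinal_study(study)
    records, truth = write_longitudinal_dataset(
        dataset, out / "records.csv", out / "ground_truth.csv"
    )
    seq, masks = syn.simulate_frame_sequence(
        study,
        syn.DEFAULT_REGION_TEMPLATES["MV"],
        syn.DEFAULT_REGION_TEMPLATES["MT"],
        seed=study.seed,
    )
    tif, sidecar = write_frame_sequence(seq, out / "stack.tif")
    truth_mask = write_masks(masks, out / "ground_truth_mask.tif")
    return [records, truth, tif, sidecar, truth_mask]


def stage_segment(config: PipelineConfig) -> list[Path]:
    out = config.out_dir
    analysis = config.analysis
    seq = read_frame_sequence(config.in_path or out / "stack.tif")
    rect = analysis.roi_rect()
    if rect is not None:
        seq = seg.crop_roi(seq, rect)
    masks = seg.segment_vessel_tissue(
        seq.mean_map(), method=analysis.segmentation_method, quantile_q=analysis.quantile_q
    )
    mask_path = write_masks(masks, out / "masks.tif")
    series = seg.extract_region_waveforms(seq, masks)
    frames = np.arange(seq.n_frames)
    rows = [
        pd.DataFrame(
            {
                "rabbit_id": "R01",
                "day": 0,
                "is_baseline": True,
                "region": region,
                "frame_index": frames,
                "time_s": seq.times,
                "mbr": values,
            }
        )
        for region, values in series.items()
    ]
    series_path = write_series_dataset(pd.concat(rows, ignore_index=True), out / "series.csv")
    return [mask_path, series_path]


def stage_analyze(config: PipelineConfig) -> list[Path]:
    out = config.out_dir
    df = read_series_dataset(out / "series.csv")
    results = []
    for (rabbit, day, region), group in df.groupby(["rabbit_id", "day", "region"]):
        group = group.sort_values("frame_index")
        dt = np.diff(group["time_s"].to_numpy())
        frame_rate = 1.0 / float(np.median(dt))
        try:
            cycle = wf.synchronize_cycles(
                group["mbr"].to_numpy(), frame_rate, n_out=config.analysis.n_frames
            )
            params = wf.compute_pwf(cycle)
        except OPWFError as exc:
            raise OPWFError(
                f"analyze failed for {rabbit}/day {day}/{region}: {exc}"
            ) from exc
        results.append({"rabbit_id": rabbit, "day": day, "region": region, **params.as_dict()})
    return [write_pwf_table(pd.DataFrame(results), out / "pwf.csv")]


def stage_score_nba(config: PipelineConfig) -> list[Path]:
    out = config.out_dir
    records = pd.read_csv(out / "records.csv")
    sessions = records.drop_duplicates(["rabbit_id", "day", "session"])
    rows = []
    for _, rec in sessions.iterrows():
        item_record = nba_mod.nba_items_from_total(int(rec["nba_total"]))
        rows.append(
            {
                "rabbit_id": rec["rabbit_id"],
                "day": int(rec["day"]),
                "session": int(rec["session"]),
                **item_record.items(),
                "is_dead": item_record.is_dead,
                "total": nba_mod.score_nba(item_record),
            }
        )
    return [write_nba_table(pd.DataFrame(rows), out / "nba.csv")]


def stage_stats(config: PipelineConfig) -> list[Path]:
    out = config.out_dir
    analysis = config.analysis
    records = pd.read_csv(out / "records.csv")
    results = []
    phases: dict[str, dict[str, str]] = {}
    for region in ("MA", "MV", "MT"):
        region_df = records[records["region"] == region]
        post = region_df[~region_df["is_baseline"]]
        # correlation of each parameter with the NBA score
        for parameter in st.PHASE_PARAMS:
            corr = st.correlate(
                region_df[parameter], region_df["nba_total"], force_method="spearman"
            )
            results.append(
                {
                    "test": "correlation_nba",
                    "region": region,
                    "parameter": parameter,
                    "statistic": corr.r,
                    "p": corr.p_value,
                    "method": corr.method,
                }
            )
            # repeated-measures test across post-surgery days
            matrix = post.pivot_table(
                index="rabbit_id", columns="day", values=parameter
            ).to_numpy()
            rm = st.rm_test(matrix)
            results.append(
                {
                    "test": "rm_over_days",
                    "region": region,
                    "parameter": parameter,
                    "statistic": rm.statistic,
                    "p": rm.p_value,
                    "method": rm.method,
                }
            )
        phases[region] = {}
        for name, window in (("vrp_window", analysis.vrp_window), ("vep_window", analysis.vep_window)):
            trends = st.trend_summaries(records, region, window)
            label = st.classify_phase(trends, alpha=analysis.alpha)
            phases[region][name] = {
                "window": list(window),
                "label": label.value,
                "slopes": {p: trends[p].slope for p in st.PHASE_PARAMS},
            }
    results_path = out / "stats_results.csv"
    pd.DataFrame(results).to_csv(results_path, index=False)
    phase_path = out / "phase.json"
    phase_path.write_text(json.dumps(phases, indent=2))
    return [results_path, phase_path]


STAGES = (
    ("simulate", stage_simulate),
    ("segment", stage_segment),
    ("analyze", stage_analyze),
    ("score-nba", stage_score_nba),
    ("stats", stage_stats),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the artifact manifest.

    The manifest maps each stage to its output files and SHA-256 hashes;
    it is also written to ``<out_dir>/manifest.json``.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    for name, stage in STAGES:
        start = time.perf_counter()
        try:
            paths = stage(config)
        except OPWFError as exc:
            raise OPWFError(f"stage {name!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - start
        log.info("stage %s finished in %.2fs (%d files)", name, elapsed, len(paths))
        manifest["stages"][name] = [
            {"path": str(Path(p).relative_to(config.out_dir)), "sha256": _sha256(p)}
            for p in paths
        ]
    (config.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
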