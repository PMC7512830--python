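"""End-to-end analysis: recording -> entropy series -> scalogram -> events."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .connectivity import FCGBSequence, build_fcgb_sequence
from .entropy import NESeries, ne_series
from .events import MatchResult, detect_high_power_regions, match_events
from .graphs import GraphMetricsRow, metrics_series
from .io import AnalysisConfig, EEGRecording, EventTable
from .preprocess import WaveletBandSpec, threshold_correct
from .tfr import Scalogram, ne_scalogram

__all__ = ["PipelineResult", "run_pipeline", "write_outputs"]


@dataclass
class PipelineResult:
    ne: NESeries
    scalogram: Scalogram
    regions: list
    matches: Optional[MatchResult]
    sequence: FCGBSequence
    metrics: Optional[List[GraphMetricsRow]] = None


def run_pipeline(
    rec: EEGRecording,
    cfg: Optional[AnalysisConfig] = None,
    events: Optional[EventTable] = None,
    preprocess: bool = True,
    band_spec: Optional[WaveletBandSpec] = None,
    compute_classical: bool = False,
) -> PipelineResult:
    """Run the full network-entropy analysis on one recording.

    With ``preprocess`` the recording is first band-selected and
    artifact-thresholded (two-pass mean + 2*std rule on the retained
    band's coefficients).  Classical graph metrics are optional — they are
    the comparison baseline, not part of the entropy path.
    """
    cfg = cfg or AnalysisConfig()
    if preprocess:
        spec = band_spec or WaveletBandSpec(wavelet_name=cfg.wavelet_name)
        rec = threshold_correct(rec, spec, use_abs=cfg.threshold_abs)
    seq = build_fcgb_sequence(rec, cfg)
    ne = ne_series(seq)
    sc = ne_scalogram(ne, cfg)
    regions = detect_high_power_regions(
        sc,
        percentile=cfg.detect_percentile,
        band=None if cfg.envelope_band == "interest" else (0.0, np.inf),
        centerline=cfg.centerline,
    )
    matches = match_events(regions, events) if events is not None else None
    metrics = None
    if compute_classical:
        metrics = metrics_series(
            seq, step=cfg.binarize_step, min_step=cfg.binarize_min_step
        )
    return PipelineResult(
        ne=ne, scalogram=sc, regions=regions, matches=matches,
        sequence=seq, metrics=metrics,
    )


def metrics_frame(rows: List[GraphMetricsRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.epoch_time_s, r.clustering, r.char_path_length,
             r.global_efficiency, r.vulnerability, r.threshold_T)
            for r in rows
        ],
        columns=["epoch_time_s", "clustering", "char_path_length",
                 "global_efficiency", "vulnerability", "threshold_T"],
    )


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write the standard result tables under ``out_dir``.

    ne_series.csv, scalogram.npy + scalogram_axes.csv, regions.csv, and —
    when events were supplied — matches.csv and summary.json; metrics.csv
    when classical metrics were computed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"epoch_time_s": result.ne.epoch_times, "ne_bits": result.ne.values}
    ).to_csv(out / "ne_series.csv", index=False)
    np.save(out / "scalogram.npy", result.scalogram.power)
    pd.DataFrame(
        {"scale": result.scalogram.scales, "freq_hz": result.scalogram.freqs_hz}
    ).to_csv(out / "scalogram_axes.csv", index=False)
    pd.DataFrame(
        [
            (r.t_start_s, r.t_end_s, r.centerline_s, r.peak_power)
            for r in result.regions
        ],
        columns=["t_start_s", "t_end_s", "centerline_s", "peak_power"],
    ).to_csv(out / "regions.csv", index=False)
    if result.matches is not None:
        result.matches.rows.to_csv(out / "matches.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(result.matches.summary, fh, indent=2)
    if result.metrics is not None:
        metrics_frame(result.metrics).to_csv(out / "metrics.csv", index=False)
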