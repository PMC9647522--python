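"""End-to-end analysis: segment -> ROIs -> traces -> tracks -> events.

``analyze_movie`` runs the full measurement chain on a matched RI/TMRM
stack pair; ``simulate_and_analyze`` runs it on a simulated scenario, and
``run_cohort`` repeats that over seeded replicate movies of one condition,
returning tidy event / trace tables alongside the generator's ground truth
so recovery can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import quantify, segmentation, simkit, stats_report, track_events
from .stacks_io import FrameStack


@dataclass
class AnalysisParams:
    """Tunable parameters of the analysis chain, with assay defaults."""

    prob_threshold: float = 0.5
    min_object_px: int = segmentation.DEFAULT_MIN_OBJECT_PX
    min_roi_px: int = quantify.DEFAULT_MIN_ROI_PX
    roi_dilation_px: int = 0
    baseline_window: tuple[int, int] | None = None  # default: all pre-drug frames
    fccp_window_frames: int = quantify.DEFAULT_FCCP_WINDOW_FRAMES
    onset_drop: float = track_events.DEFAULT_ONSET_DROP
    onset_sustain: int = track_events.DEFAULT_SUSTAIN_FRAMES
    onset_search_end: int | None = None  # default: FCCP anchor frame when known
    area_floor_fraction: float = track_events.DEFAULT_AREA_FLOOR_FRACTION
    perm_sustain: int = track_events.DEFAULT_SUSTAIN_FRAMES
    min_iou: float = track_events.DEFAULT_MIN_IOU
    gap_frames: int = track_events.DEFAULT_GAP_FRAMES
    terminal_window: int = stats_report.DEFAULT_TERMINAL_WINDOW


@dataclass
class MovieResult:
    condition: str | None
    mask_stack: segmentation.MitoMaskStack
    roi_set: quantify.ROISet
    traces: list[quantify.Trace]
    tracks: list[track_events.OrganelleTrack]
    events: list[track_events.EventRecord]
    params: AnalysisParams

    def events_frame(self) -> pd.DataFrame:
        return track_events.events_to_frame(self.events, condition=self.condition)

    def traces_frame(self) -> pd.DataFrame:
        return quantify.traces_to_frame(self.traces, condition=self.condition)

    def remaining_area_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.traces:
            if tr.area_fraction is None or "zero_baseline_area" in tr.flags:
                continue
            rows.append(
                dict(
                    roi_id=tr.roi_id,
                    condition=self.condition,
                    remaining_area=stats_report.remaining_area(
                        tr.area_fraction, self.params.terminal_window
                    ),
                )
            )
        return pd.DataFrame(rows, columns=["roi_id", "condition", "remaining_area"])


def analyze_movie(
    ri_stack: FrameStack,
    tmrm_stack: FrameStack,
    params: AnalysisParams | None = None,
    classifier: segmentation.PixelClassifier | None = None,
    condition: str | None = None,
    fccp_anchor_frame: int | None = None,
) -> MovieResult:
    """Run the full measurement chain on one movie."""
    if ri_stack.n_frames != tmrm_stack.n_frames:
        raise ValueError(
            f"channel length mismatch: RI has {ri_stack.n_frames} frames, "
            f"TMRM has {tmrm_stack.n_frames}"
        )
    p = params or AnalysisParams()
    n_frames = ri_stack.n_frames

    mask_stack = segmentation.segment_stack(
        ri_stack, classifier=classifier, threshold=p.prob_threshold, min_object_px=p.min_object_px
    )
    roi_set = quantify.define_rois(
        tmrm_stack, p.baseline_window, min_roi_px=p.min_roi_px, dilation_px=p.roi_dilation_px
    )
    fccp_window = (n_frames - p.fccp_window_frames, n_frames)
    traces = quantify.build_traces(mask_stack, tmrm_stack, roi_set, p.baseline_window, fccp_window)
    tracks = track_events.track_organelles(mask_stack, min_iou=p.min_iou, gap_frames=p.gap_frames)
    search_end = p.onset_search_end if p.onset_search_end is not None else fccp_anchor_frame
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ROI-match warnings surface via record counts
        events = track_events.summarize_events(
            tracks,
            traces,
            roi_set,
            frame_interval=ri_stack.frame_interval,
            drug_frame=ri_stack.drug_frame,
            n_frames=n_frames,
            onset_drop=p.onset_drop,
            onset_sustain=p.onset_sustain,
            onset_search_end=search_end,
            area_floor_fraction=p.area_floor_fraction,
            perm_sustain=p.perm_sustain,
        )
    return MovieResult(
        condition=condition,
        mask_stack=mask_stack,
        roi_set=roi_set,
        traces=traces,
        tracks=tracks,
        events=events,
        params=p,
    )


def simulate_and_analyze(
    scenario: simkit.Scenario,
    params: AnalysisParams | None = None,
    classifier: segmentation.PixelClassifier | None = None,
) -> tuple[MovieResult, simkit.GroundTruth]:
    ri, tmrm, gt = simkit.simulate_experiment(scenario)
    result = analyze_movie(
        ri,
        tmrm,
        params=params,
        classifier=classifier,
        condition=scenario.condition,
        fccp_anchor_frame=scenario.fccp_frame,
    )
    return result, gt


@dataclass
class CohortResult:
    condition: str
    events: pd.DataFrame  # all movies, with a movie column
    remaining_area: pd.DataFrame
    ground_truth: pd.DataFrame
    n_movies: int


def cohort_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic per-movie seeds derived from one base seed (< 2^31)."""
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_cohort(
    condition: str,
    n_movies: int,
    base_seed: int = 0,
    n_mito: int = 10,
    params: AnalysisParams | None = None,
    overrides: dict | None = None,
) -> CohortResult:
    """Simulate and analyze ``n_movies`` seeded replicates of one condition."""
    ev_frames, ra_frames, gt_frames = [], [], []
    for m, seed in enumerate(cohort_seeds(base_seed, n_movies)):
        scenario = simkit.make_scenario(condition, n_mito=n_mito, seed=seed, overrides=overrides)
        result, gt = simulate_and_analyze(scenario, params=params)
        ev = result.events_frame()
        ev.insert(0, "movie", m)
        ev_frames.append(ev)
        ra = result.remaining_area_frame()
        ra.insert(0, "movie", m)
        ra_frames.append(ra)
        gtf = gt.to_frame()
        gtf.insert(0, "movie", m)
        gt_frames.append(gtf)
    return CohortResult(
        condition=condition,
        events=pd.concat(ev_frames, ignore_index=True),
        remaining_area=pd.concat(ra_frames, ignore_index=True),
        ground_truth=pd.concat(gt_frames, ignore_index=True),
        n_movies=n_movies,
    )
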