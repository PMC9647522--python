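"""Functional ROIs from baseline TMRM and per-ROI area / intensity traces.

ROIs are defined once, from the time-averaged TMRM image over a baseline
window that precedes drug addition — regions whose mitochondria hold a
membrane potential at the start of the recording — and stay fixed for the
whole movie. Two traces are extracted per ROI:

* ``area_fraction`` — mitochondrion-mask area inside the ROI, divided by
  its baseline-window mean (1 at baseline; a permeabilization event drives
  it toward 0);
* ``tmrm_raw`` / ``tmrm_norm`` — mean TMRM intensity, normalized to the
  anchor provided by the terminal FCCP addition:

      F_norm(t) = (F(t) - mean_fccp) / (mean_baseline - mean_fccp)

so every normalizable trace has baseline mean exactly 1 and FCCP-window
mean exactly 0, and F_norm is invariant under positive rescaling of the
raw intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels

from .segmentation import MitoMaskStack, _robust_sd
from .stacks_io import FrameStack

DEFAULT_MIN_ROI_PX = 10
DEFAULT_FCCP_WINDOW_FRAMES = 3
DEFAULT_NORM_FLOOR_MULT = 3.0


class NormalizationError(ValueError):
    """Raised when baseline and FCCP levels are too close to normalize."""


@dataclass
class ROISet:
    label_map: np.ndarray  # (H, W) int, 0 = none, labels contiguous from 1
    roi_ids: tuple[int, ...]
    source_window: tuple[int, int]
    min_roi_px: int

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)


@dataclass
class Trace:
    """Per-ROI time series on the movie's time base."""

    roi_id: int
    times: np.ndarray
    area_fraction: np.ndarray | None
    tmrm_raw: np.ndarray
    tmrm_norm: np.ndarray | None = None
    valid: bool = True
    flags: list[str] = field(default_factory=list)


def _resolve_baseline(stack: FrameStack, baseline_window: tuple[int, int] | None) -> tuple[int, int]:
    bw = baseline_window if baseline_window is not None else (0, stack.drug_frame)
    lo, hi = bw
    if not (0 <= lo < hi <= stack.n_frames):
        raise ValueError(f"baseline window {bw} is empty or out of range")
    if hi > stack.drug_frame:
        raise ValueError(f"baseline window {bw} overlaps the drug-addition frame {stack.drug_frame}")
    return (lo, hi)


def define_rois(
    tmrm_stack: FrameStack,
    baseline_window: tuple[int, int] | None = None,
    min_roi_px: int = DEFAULT_MIN_ROI_PX,
    dilation_px: int = 0,
) -> ROISet:
    """Threshold the time-averaged baseline TMRM image into labeled ROIs.

    Otsu's criterion with a robust noise floor, 8-connected labeling, and a
    size filter; an all-background channel yields an empty ROISet with a
    warning. ``dilation_px`` pads ROI boundaries outward without merging.
    """
    bw = _resolve_baseline(tmrm_stack, baseline_window)
    base = np.asarray(tmrm_stack.pixels[bw[0]:bw[1]], dtype=float).mean(axis=0)
    if np.ptp(base) == 0:
        warnings.warn("constant baseline TMRM image: no ROIs found", stacklevel=2)
        return ROISet(np.zeros(base.shape, int), (), bw, min_roi_px)
    resid = base - np.median(base)
    thr = max(threshold_otsu(resid), DEFAULT_NORM_FLOOR_MULT * _robust_sd(resid))
    mask = remove_small_objects(resid >= thr, connectivity=2, max_size=min_roi_px - 1)
    if not mask.any():
        warnings.warn("no ROIs above threshold in baseline TMRM image", stacklevel=2)
        return ROISet(np.zeros(base.shape, int), (), bw, min_roi_px)
    labels = cc_label(mask, connectivity=2)
    if dilation_px > 0:
        labels = expand_labels(labels, distance=dilation_px)
    ids = tuple(range(1, labels.max() + 1))
    return ROISet(label_map=labels, roi_ids=ids, source_window=bw, min_roi_px=min_roi_px)


def area_trace(
    mask_stack: MitoMaskStack,
    roi_set: ROISet,
    baseline_window: tuple[int, int],
) -> tuple[dict[int, np.ndarray], dict[int, bool]]:
    """Per-ROI mask area per frame, divided by its baseline-window mean.

    Returns (fractions, valid); an ROI whose baseline area is zero is
    flagged invalid (its fraction array is all-NaN) and must be excluded
    from downstream statistics.
    """
    masks = mask_stack.masks
    if masks.shape[1:] != roi_set.label_map.shape:
        raise ValueError("mask stack and ROI label map shapes differ")
    ids = list(roi_set.roi_ids)
    counts = np.stack(
        [ndi.sum_labels(masks[t].astype(float), roi_set.label_map, index=ids) for t in range(masks.shape[0])]
    )  # (T, n_rois)
    lo, hi = baseline_window
    base = counts[lo:hi].mean(axis=0)
    fractions: dict[int, np.ndarray] = {}
    valid: dict[int, bool] = {}
    for j, roi in enumerate(ids):
        if base[j] <= 0:
            fractions[roi] = np.full(masks.shape[0], np.nan)
            valid[roi] = False
        else:
            fractions[roi] = counts[:, j] / base[j]
            valid[roi] = True
    return fractions, valid


def tmrm_trace(tmrm_stack: FrameStack, roi_set: ROISet) -> dict[int, np.ndarray]:
    """Arithmetic mean of TMRM intensities over each ROI's pixels, per frame."""
    frames = np.asarray(tmrm_stack.pixels, dtype=float)
    if frames.shape[1:] != roi_set.label_map.shape:
        raise ValueError("TMRM stack and ROI label map shapes differ")
    ids = list(roi_set.roi_ids)
    means = np.stack(
        [ndi.mean(frames[t], labels=roi_set.label_map, index=ids) for t in range(frames.shape[0])]
    )
    return {roi: means[:, j] for j, roi in enumerate(ids)}


def normalize_tmrm(
    values: np.ndarray,
    baseline_window: tuple[int, int],
    fccp_window: tuple[int, int],
    floor_sd_mult: float = DEFAULT_NORM_FLOOR_MULT,
) -> np.ndarray:
    """FCCP-anchored normalization of a raw TMRM trace.

    Raises NormalizationError when the baseline-to-FCCP span is below
    ``floor_sd_mult`` times the trace noise (estimated from baseline
    first differences), i.e. when there is no potential to normalize to.
    """
    values = np.asarray(values, dtype=float)
    b0, b1 = baseline_window
    f0, f1 = fccp_window
    if not (0 <= b0 < b1 <= len(values) and 0 <= f0 < f1 <= len(values)):
        raise ValueError("normalization windows out of range")
    if max(b0, f0) < min(b1, f1):
        raise ValueError("baseline and FCCP windows overlap")
    f_base = values[b0:b1].mean()
    f_fccp = values[f0:f1].mean()
    span = f_base - f_fccp
    base_seg = values[b0:b1]
    noise_sd = float(np.std(np.diff(base_seg)) / np.sqrt(2.0)) if len(base_seg) > 2 else 0.0
    if span <= floor_sd_mult * noise_sd or span <= 0:
        raise NormalizationError(
            f"baseline-FCCP span {span:.3g} below floor ({floor_sd_mult} x noise sd {noise_sd:.3g})"
        )
    return (values - f_fccp) / span


def build_traces(
    mask_stack: MitoMaskStack,
    tmrm_stack: FrameStack,
    roi_set: ROISet,
    baseline_window: tuple[int, int] | None = None,
    fccp_window: tuple[int, int] | None = None,
) -> list[Trace]:
    """Assemble area and (normalized) TMRM traces for every ROI.

    Default windows: baseline = all frames before drug addition, FCCP = the
    last three frames. Non-normalizable or zero-baseline-area ROIs are
    returned flagged invalid rather than dropped, so the caller can report
    them.
    """
    bw = _resolve_baseline(tmrm_stack, baseline_window)
    if fccp_window is None:
        fccp_window = (tmrm_stack.n_frames - DEFAULT_FCCP_WINDOW_FRAMES, tmrm_stack.n_frames)
    fractions, area_valid = area_trace(mask_stack, roi_set, bw)
    raw = tmrm_trace(tmrm_stack, roi_set)
    times = tmrm_stack.times()
    traces = []
    for roi in roi_set.roi_ids:
        flags: list[str] = []
        norm = None
        try:
            norm = normalize_tmrm(raw[roi], bw, fccp_window)
        except NormalizationError as exc:
            flags.append(f"non_normalizable: {exc}")
        if not area_valid[roi]:
            flags.append("zero_baseline_area")
        traces.append(
            Trace(
                roi_id=roi,
                times=times,
                area_fraction=fractions[roi],
                tmrm_raw=raw[roi],
                tmrm_norm=norm,
                valid=not flags,
                flags=flags,
            )
        )
    return traces


def traces_to_frame(traces: list[Trace], condition: str | None = None) -> pd.DataFrame:
    """Tidy export: one row per (roi, frame)."""
    rows = []
    for tr in traces:
        for k in range(len(tr.times)):
            rows.append(
                dict(
                    roi_id=tr.roi_id,
                    frame=k,
                    time_s=tr.times[k],
                    area_fraction=None if tr.area_fraction is None else tr.area_fraction[k],
                    tmrm_raw=tr.tmrm_raw[k],
                    tmrm_norm=None if tr.tmrm_norm is None else tr.tmrm_norm[k],
                    condition=condition,
                )
            )
    return pd.DataFrame(rows)
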