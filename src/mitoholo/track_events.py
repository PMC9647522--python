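"""Single-organelle tracking and event detection.

Connected components of the per-frame mitochondrion masks are linked
greedily frame-to-frame by maximal mask overlap (IoU), with centroid
distance and then lowest component label as tie-breaks. A track whose
component vanishes and stays vanished terminates as ``disappeared`` — the
RI-image signature of high-conductance permeabilization; a track whose
neighborhood still contains foreground that failed to link terminates as
``lost`` and is never counted as permeabilized.

Two rule-based detectors produce the per-organelle event times:

* depolarization onset — first frame at or after drug addition where the
  normalized TMRM trace falls below ``1 - onset_drop`` and stays below for
  ``sustain_frames`` consecutive frames;
* permeabilization — first frame where the tracked component's area falls
  below ``area_floor_fraction`` of its pre-drug mean, sustained through the
  track end or ``sustain_frames``.

Both rules are simple linear scans by construction, so an exhaustive
brute-force scan of the same rule is an exact oracle for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label, regionprops

from .quantify import ROISet, Trace
from .segmentation import MitoMaskStack

DEFAULT_MIN_IOU = 0.3
DEFAULT_GAP_FRAMES = 1
DEFAULT_ONSET_DROP = 0.1
DEFAULT_SUSTAIN_FRAMES = 3
DEFAULT_AREA_FLOOR_FRACTION = 0.2


@dataclass
class OrganelleTrack:
    track_id: int
    frames: np.ndarray  # frame indices where the component was seen
    centroids: np.ndarray  # (n, 2) row/col
    areas: np.ndarray  # pixels
    termination: str  # {"disappeared", "movie_end", "lost"}
    last_seen_frame: int
    first_pixels: tuple[np.ndarray, np.ndarray]  # component pixels at birth, for ROI matching


@dataclass
class EventRecord:
    track_id: int
    roi_id: int | None
    depol_onset_s: float | None
    perm_s: float | None
    residual_potential: float | None
    delay_s: float | None
    termination: str


class _Active:
    __slots__ = ("track_id", "frames", "centroids", "areas", "last_mask_idx", "misses", "first_pixels")

    def __init__(self, track_id, frame, centroid, area, mask_idx, pixels):
        self.track_id = track_id
        self.frames = [frame]
        self.centroids = [centroid]
        self.areas = [area]
        self.last_mask_idx = mask_idx  # flat pixel indices of last matched component
        self.misses = 0
        self.first_pixels = pixels


def track_organelles(
    mask_stack: MitoMaskStack,
    min_iou: float = DEFAULT_MIN_IOU,
    gap_frames: int = DEFAULT_GAP_FRAMES,
) -> list[OrganelleTrack]:
    """Greedy overlap linking of mask components across frames."""
    masks = np.asarray(mask_stack.masks)
    if masks.ndim != 3 or masks.shape[0] == 0:
        raise ValueError("mask stack must contain at least one frame")
    h, w = masks.shape[1:]
    active: list[_Active] = []
    done: list[OrganelleTrack] = []
    next_id = 0

    def finish(tr: _Active, termination: str) -> None:
        done.append(
            OrganelleTrack(
                track_id=tr.track_id,
                frames=np.asarray(tr.frames),
                centroids=np.asarray(tr.centroids, dtype=float),
                areas=np.asarray(tr.areas, dtype=float),
                termination=termination,
                last_seen_frame=tr.frames[-1],
                first_pixels=tr.first_pixels,
            )
        )

    for t in range(masks.shape[0]):
        lab = cc_label(masks[t], connectivity=2)
        props = regionprops(lab)
        comp_idx = {p.label: np.ravel_multi_index((p.coords[:, 0], p.coords[:, 1]), (h, w)) for p in props}
        comp_centroid = {p.label: p.centroid for p in props}
        comp_area = {p.label: p.area for p in props}

        # candidate links, scored by IoU with centroid/label tie-breaks
        candidates = []
        for tr in active:
            prev = tr.last_mask_idx
            prev_set = prev
            for p in props:
                idx = comp_idx[p.label]
                inter = np.intersect1d(prev_set, idx, assume_unique=True).size
                if inter == 0:
                    continue
                union = prev_set.size + idx.size - inter
                iou = inter / union
                if iou >= min_iou:
                    d = float(np.hypot(*(np.asarray(comp_centroid[p.label]) - tr.centroids[-1])))
                    candidates.append((-iou, d, p.label, tr.track_id, tr, p.label))
        candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))

        used_tracks, used_comps = set(), set()
        for neg_iou, d, _, _, tr, lbl in candidates:
            if tr.track_id in used_tracks or lbl in used_comps:
                continue
            used_tracks.add(tr.track_id)
            used_comps.add(lbl)
            tr.frames.append(t)
            tr.centroids.append(comp_centroid[lbl])
            tr.areas.append(comp_area[lbl])
            tr.last_mask_idx = comp_idx[lbl]
            tr.misses = 0

        still_active = []
        for tr in active:
            if tr.track_id in used_tracks:
                still_active.append(tr)
                continue
            tr.misses += 1
            if tr.misses > gap_frames:
                # vanished for good, or a linking failure with foreground nearby?
                rr, cc = np.unravel_index(tr.last_mask_idx, (h, w))
                r0, r1 = max(rr.min() - 2, 0), min(rr.max() + 3, h)
                c0, c1 = max(cc.min() - 2, 0), min(cc.max() + 3, w)
                finish(tr, "lost" if masks[t, r0:r1, c0:c1].any() else "disappeared")
            else:
                still_active.append(tr)
        active = still_active

        for p in props:
            if p.label in used_comps:
                continue
            pixels = (p.coords[:, 0].copy(), p.coords[:, 1].copy())
            active.append(
                _Active(next_id, t, p.centroid, p.area, comp_idx[p.label], pixels)
            )
            next_id += 1

    for tr in active:
        finish(tr, "movie_end")
    done.sort(key=lambda tr: tr.track_id)
    return done


def detect_depolarization_onset(
    tmrm_norm: np.ndarray,
    drug_frame: int,
    onset_drop: float = DEFAULT_ONSET_DROP,
    sustain_frames: int = DEFAULT_SUSTAIN_FRAMES,
    search_end: int | None = None,
) -> int | None:
    """First frame >= drug_frame where F_norm < 1 - onset_drop, sustained.

    ``search_end`` bounds the scan (exclusive); pass the terminal-FCCP
    anchor frame so the deliberate end-of-movie collapse is not scored as a
    drug-induced onset. Returns None when never satisfied.
    """
    f = np.asarray(tmrm_norm, dtype=float)
    end = len(f) if search_end is None else min(search_end, len(f))
    if end - drug_frame < sustain_frames:
        raise ValueError("trace shorter than the sustain window")
    thr = 1.0 - onset_drop
    below = f < thr
    for k in range(drug_frame, end - sustain_frames + 1):
        if below[k:k + sustain_frames].all():
            return k
    return None


def detect_permeabilization(
    track: OrganelleTrack,
    n_frames: int,
    drug_frame: int,
    area_floor_fraction: float = DEFAULT_AREA_FLOOR_FRACTION,
    sustain_frames: int = DEFAULT_SUSTAIN_FRAMES,
) -> int | None:
    """First frame where the tracked area collapses below the floor.

    The floor is ``area_floor_fraction`` times the track's pre-drug mean
    area; the collapse must be sustained for ``sustain_frames`` frames or
    through the end of the movie. Frames where the component was not seen
    count as zero area for a ``disappeared`` track. ``lost`` tracks return
    None (a linking failure is never scored as permeabilization).
    """
    pre = track.areas[track.frames < drug_frame]
    if pre.size == 0:
        raise ValueError(f"track {track.track_id} has no pre-drug frames")
    if track.termination == "lost":
        return None
    area = np.zeros(n_frames)
    area[track.frames] = track.areas
    if track.termination == "movie_end":
        pass  # zeros only at genuine gap frames
    floor = area_floor_fraction * pre.mean()
    below = area < floor
    start = max(drug_frame, int(track.frames[0]))
    for k in range(start, n_frames):
        w = below[k:k + sustain_frames]
        if w.all():  # truncated window at movie end counts as "through end"
            return k
    return None


def match_track_to_roi(track: OrganelleTrack, roi_set: ROISet) -> int | None:
    """ROI label under the majority of the track's birth-frame pixels."""
    rr, cc = track.first_pixels
    labels = roi_set.label_map[rr, cc]
    labels = labels[labels > 0]
    if labels.size == 0:
        return None
    vals, counts = np.unique(labels, return_counts=True)
    return int(vals[np.argmax(counts)])


def summarize_events(
    tracks: list[OrganelleTrack],
    traces: list[Trace],
    roi_set: ROISet,
    frame_interval: float,
    drug_frame: int,
    n_frames: int,
    onset_drop: float = DEFAULT_ONSET_DROP,
    onset_sustain: int = DEFAULT_SUSTAIN_FRAMES,
    onset_search_end: int | None = None,
    area_floor_fraction: float = DEFAULT_AREA_FLOOR_FRACTION,
    perm_sustain: int = DEFAULT_SUSTAIN_FRAMES,
) -> list[EventRecord]:
    """Per-organelle event records (the single-mitochondrion statistics).

    Only tracks that exist before drug addition are scored. The residual
    potential is the matched ROI's normalized TMRM at the permeabilization
    frame; the delay is (perm_frame - onset_frame) * frame_interval.
    Residual and delay are reported only when both events are present.
    """
    trace_by_roi = {tr.roi_id: tr for tr in traces}
    records: list[EventRecord] = []
    for track in tracks:
        if track.frames[0] >= drug_frame:
            continue  # born after treatment: not a baseline organelle
        roi = match_track_to_roi(track, roi_set)
        if roi is None or roi not in trace_by_roi:
            warnings.warn(f"track {track.track_id} matches no ROI; excluded", stacklevel=2)
            continue
        trace = trace_by_roi[roi]
        if trace.tmrm_norm is None:
            warnings.warn(f"track {track.track_id}: ROI {roi} non-normalizable; excluded", stacklevel=2)
            continue
        onset_f = detect_depolarization_onset(
            trace.tmrm_norm, drug_frame, onset_drop, onset_sustain, onset_search_end
        )
        perm_f = detect_permeabilization(
            track, n_frames, drug_frame, area_floor_fraction, perm_sustain
        )
        both = onset_f is not None and perm_f is not None
        records.append(
            EventRecord(
                track_id=track.track_id,
                roi_id=roi,
                depol_onset_s=None if onset_f is None else onset_f * frame_interval,
                perm_s=None if perm_f is None else perm_f * frame_interval,
                residual_potential=float(trace.tmrm_norm[perm_f]) if both else None,
                delay_s=(perm_f - onset_f) * frame_interval if both else None,
                termination=track.termination,
            )
        )
    return records


def events_to_frame(records: list[EventRecord], condition: str | None = None) -> pd.DataFrame:
    rows = [
        dict(
            track_id=r.track_id,
            roi_id=r.roi_id,
            condition=condition,
            onset_s=r.depol_onset_s,
            perm_s=r.perm_s,
            residual_potential=r.residual_potential,
            delay_s=r.delay_s,
            termination=r.termination,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "roi_id", "condition", "onset_s", "perm_s",
            "residual_potential", "delay_s", "termination",
        ],
    )
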