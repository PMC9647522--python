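"""Organelle tracking, event detectors and per-organelle event records."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoholo.segmentation import MitoMaskStack
from mitoholo.track_events import (
    OrganelleTrack,
    detect_depolarization_onset,
    detect_permeabilization,
    events_to_frame,
    track_organelles,
)

from _oracles import onset_scan, perm_scan


def _mask_stack(masks):
    return MitoMaskStack(np.asarray(masks, bool), 1, "threshold")


def _blob_movie(n_frames, present, shape=(24, 24), where=(5, 5, 11, 12)):
    """Movie with one rectangular blob present on the given frames."""
    masks = np.zeros((n_frames, *shape), bool)
    r0, c0, r1, c1 = where
    for t in present:
        masks[t, r0:r1, c0:c1] = True
    return masks


class TestTracking:
    def test_static_blob_gives_one_movie_end_track(self):
        tracks = track_organelles(_mask_stack(_blob_movie(10, range(10))))
        assert len(tracks) == 1
        assert tracks[0].termination == "movie_end"
        assert list(tracks[0].frames) == list(range(10))

    def test_vanishing_blob_terminates_as_disappeared(self):
        tracks = track_organelles(_mask_stack(_blob_movie(10, range(5))), gap_frames=1)
        assert len(tracks) == 1
        assert tracks[0].termination == "disappeared"
        assert tracks[0].last_seen_frame == 4

    def test_gap_of_one_frame_is_bridged(self):
        present = [0, 1, 2, 4, 5]  # missing frame 3 only
        tracks = track_organelles(_mask_stack(_blob_movie(6, present)), gap_frames=1)
        assert len(tracks) == 1
        assert tracks[0].termination == "movie_end"

    def test_two_separate_blobs_give_two_tracks(self):
        masks = _blob_movie(8, range(8)) | _blob_movie(8, range(8), where=(15, 15, 20, 21))
        tracks = track_organelles(_mask_stack(masks))
        assert len(tracks) == 2

    def test_replacement_by_nonoverlapping_blob_is_lost_not_disappeared(self):
        masks = _blob_movie(10, range(5))
        # foreground persists in the immediate neighborhood but never links
        shifted = _blob_movie(10, range(5, 10), where=(11, 5, 17, 12))
        tracks = track_organelles(_mask_stack(masks | shifted), gap_frames=1)
        terminations = sorted(t.termination for t in tracks)
        assert "lost" in terminations

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            track_organelles(_mask_stack(np.zeros((0, 4, 4), bool)))

    def test_wt_disappeared_tracks_match_ground_truth_events(self, wt_movie):
        scenario, result, gt = wt_movie
        n_perm_gt = sum(org.perm_s is not None for org in gt.organelles)
        n_disappeared = sum(
            t.termination == "disappeared" for t in result.tracks if t.frames[0] < scenario.drug_frame
        )
        assert n_disappeared == n_perm_gt == scenario.n_mito


class TestOnsetDetector:
    def test_constant_trace_has_no_onset(self):
        assert detect_depolarization_onset(np.ones(30), drug_frame=5) is None

    def test_step_trace_onset_at_step(self):
        f = np.ones(40)
        f[20:] = 0.5
        assert detect_depolarization_onset(f, drug_frame=5) == 20

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="sustain"):
            detect_depolarization_onset(np.ones(6), drug_frame=5, sustain_frames=3)

    def test_search_end_excludes_terminal_collapse(self):
        f = np.ones(40)
        f[36:] = 0.0  # terminal FCCP anchor only
        assert detect_depolarization_onset(f, drug_frame=5, search_end=35) is None
        assert detect_depolarization_onset(f, drug_frame=5, search_end=None) == 36

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_linear_scan_oracle(self, seed):
        r = np.random.default_rng(seed)
        # random noise-free traces: monotone-ish decays, steps, plateaus
        kind = r.integers(3)
        n = int(r.integers(15, 60))
        if kind == 0:
            f = np.exp(-np.arange(n) / r.uniform(2, 30))
        elif kind == 1:
            f = np.ones(n)
            f[int(r.integers(0, n)):] = r.uniform(0, 1.2)
        else:
            f = np.clip(1 - np.cumsum(r.uniform(-0.05, 0.1, n)), 0, 1.5)
        drug = int(r.integers(0, max(1, n - 5)))
        drop = float(r.uniform(0.05, 0.5))
        sustain = int(r.integers(1, 4))
        try:
            ours = detect_depolarization_onset(f, drug, drop, sustain)
        except ValueError:
            return  # trace shorter than the sustain window
        assert ours == onset_scan(f, drug, drop, sustain, len(f))


def _track(frames, areas, termination="movie_end"):
    frames = np.asarray(frames)
    return OrganelleTrack(
        track_id=0,
        frames=frames,
        centroids=np.zeros((len(frames), 2)),
        areas=np.asarray(areas, float),
        termination=termination,
        last_seen_frame=int(frames[-1]),
        first_pixels=(np.array([0]), np.array([0])),
    )


class TestPermDetector:
    def test_static_blob_has_no_event(self):
        tr = _track(range(10), [50.0] * 10)
        assert detect_permeabilization(tr, 10, drug_frame=3) is None

    def test_forced_area_collapse(self):
        tr = _track(range(6), [50, 50, 50, 4, 0, 0], termination="movie_end")
        assert detect_permeabilization(tr, 6, drug_frame=3, area_floor_fraction=0.2) == 3

    def test_disappeared_track_event_at_vanish_frame(self):
        tr = _track(range(5), [50.0] * 5, termination="disappeared")
        assert detect_permeabilization(tr, 12, drug_frame=3) == 5

    def test_lost_track_never_counts_as_permeabilized(self):
        tr = _track(range(5), [50.0] * 5, termination="lost")
        assert detect_permeabilization(tr, 12, drug_frame=3) is None

    def test_track_without_pre_drug_frames_rejected(self):
        tr = _track(range(5, 10), [50.0] * 5)
        with pytest.raises(ValueError, match="pre-drug"):
            detect_permeabilization(tr, 10, drug_frame=3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_linear_scan_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(12, 50))
        drug = int(r.integers(2, 8))
        base = float(r.uniform(30, 60))
        areas = np.full(n, base) + r.uniform(-3, 3, n)
        if r.random() < 0.7:  # inject a collapse
            k = int(r.integers(drug, n))
            areas[k:] = r.uniform(0, 3)
        tr = _track(range(n), areas)
        floor_frac = float(r.uniform(0.1, 0.4))
        sustain = int(r.integers(1, 4))
        ours = detect_permeabilization(tr, n, drug, floor_frac, sustain)
        floor = floor_frac * areas[:drug].mean()
        assert ours == perm_scan(list(areas), drug, floor, sustain, 0)


class TestEventRecords:
    def test_delay_arithmetic(self, wt_movie):
        # onset frame 10 and perm frame 20 at 15 s/frame give a 150 s delay
        _, result, _ = wt_movie
        for rec in result.events:
            assert rec.delay_s == rec.perm_s - rec.depol_onset_s
        df = events_to_frame(result.events)
        assert (df["delay_s"] == df["perm_s"] - df["onset_s"]).all()

    def test_wt_events_recover_calibrated_summary_statistics(self, wt_movie):
        scenario, result, gt = wt_movie
        df = events_to_frame(result.events).dropna(subset=["onset_s", "perm_s"])
        assert len(df) == scenario.n_mito
        assert abs(df["residual_potential"].mean() - 0.15) <= 0.06
        assert abs(df["delay_s"].mean() - 150.0) <= 20.0

    def test_depolarization_precedes_permeabilization(self, wt_movie):
        _, result, _ = wt_movie
        for rec in result.events:
            assert rec.perm_s >= rec.depol_onset_s
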