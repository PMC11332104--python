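"""Detector, merge/discard rules, selection, credibility and quality metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import stationary_recording
from gazebench.geometry import STUDY_GEOMETRY as G
from gazebench.preprocess import (
    Candidate,
    DetectionParams,
    credibility_filter,
    detect_fixation_candidates,
    postprocess_candidates,
    quality_report,
    select_analysis_fixations,
)
from gazebench.synthetic import GazeRecording, SyntheticCohortConfig, simulate_participant


# --- detection -------------------------------------------------------------


def test_single_stationary_cluster_yields_one_candidate_spanning_all():
    rec = stationary_recording([(900, 500, 600)], G)
    cands = detect_fixation_candidates(rec, G)
    assert len(cands) == 1
    c = cands[0]
    assert c.onset_ms == 0.0
    assert c.offset_ms == pytest.approx(600 / 60 * 1000.0)
    assert (c.x_px, c.y_px) == (900.0, 500.0)


def test_two_clusters_give_two_candidates_at_cluster_centers():
    # 5 dva apart horizontally = 192 px
    rec = stationary_recording([(800, 500, 300), (992, 500, 300)], G)
    cands = detect_fixation_candidates(rec, G)
    assert len(cands) == 2
    assert G.distance_dva(cands[0].x_px, cands[0].y_px, 800, 500) < 0.1
    assert G.distance_dva(cands[1].x_px, cands[1].y_px, 992, 500) < 0.1


def test_too_few_valid_samples_is_empty_not_error():
    rec = stationary_recording([(900, 500, 10)], G)
    rec.valid[:] = False
    rec.valid[4] = True
    assert detect_fixation_candidates(rec, G) == []


def test_unsorted_timestamps_raise():
    rec = stationary_recording([(900, 500, 10)], G)
    rec.t_ms = rec.t_ms[::-1].copy()
    with pytest.raises(ValueError, match="increasing"):
        detect_fixation_candidates(rec, G)


def test_zero_noise_candidate_onsets_match_ground_truth():
    cfg = SyntheticCohortConfig(noise_rms_dva=0.0, loss_run_prob=0.0, seed=21)
    rec, truth = simulate_participant(cfg, {"participant_id": "p0"}, 21)
    fix = postprocess_candidates(detect_fixation_candidates(rec, G), DetectionParams(), G)
    period = rec.sample_period_ms
    hits = 0
    for r in truth.itertuples():
        if any(
            abs(f.onset_ms - r.onset_ms) <= 2 * period
            and G.distance_dva(f.x_px, f.y_px, r.x_px, r.y_px) <= 0.5
            for f in fix
        ):
            hits += 1
    assert hits / len(truth) >= 0.95


def test_candidates_do_not_span_long_loss_runs():
    rec = stationary_recording([(900, 500, 300)], G)
    rec.valid[100:120] = False  # 333 ms gap
    cands = detect_fixation_candidates(rec, G)
    assert len(cands) == 2
    assert cands[1].onset_ms - cands[0].offset_ms > DetectionParams().max_gap_ms


# --- post-processing -------------------------------------------------------


def mk(onset, dur, x, y):
    return Candidate(onset_ms=onset, offset_ms=onset + dur, x_px=x, y_px=y, n_samples=int(dur // 16))


def test_short_candidate_is_discarded():
    assert postprocess_candidates([mk(0, 50, 900, 500)], geometry=G) == []


def test_sub_degree_neighbours_merge_into_one_fixation():
    # 0.5 dva apart = 19.2 px horizontally
    out = postprocess_candidates([mk(0, 200, 900, 500), mk(210, 200, 919.2, 500)], geometry=G)
    assert len(out) == 1
    f = out[0]
    assert f.duration_ms >= 400
    assert f.x_px == pytest.approx((900 + 919.2) / 2)  # equal durations
    assert f.onset_ms == 0 and f.offset_ms == 410


def test_distant_candidates_are_retained_unchanged():
    a, b = mk(0, 200, 900, 500), mk(260, 200, 900 + 3 * 38.4, 500)
    out = postprocess_candidates([a, b], geometry=G)
    assert [(f.onset_ms, f.x_px) for f in out] == [(0, 900), (260, 900 + 3 * 38.4)]


def test_merge_happens_before_duration_discard():
    """Two sub-60 ms pieces < 1 dva apart survive as one merged fixation."""
    out = postprocess_candidates([mk(0, 40, 900, 500), mk(45, 40, 910, 500)], geometry=G)
    assert len(out) == 1
    assert out[0].duration_ms == 85


def test_no_merge_across_long_gaps():
    params = DetectionParams()
    a, b = mk(0, 200, 900, 500), mk(200 + params.merge_max_gap_ms + 1, 200, 905, 500)
    assert len(postprocess_candidates([a, b], params, G)) == 2


def test_empty_in_empty_out_and_order_check():
    assert postprocess_candidates([], geometry=G) == []
    with pytest.raises(ValueError, match="ordered"):
        postprocess_candidates([mk(100, 200, 900, 500), mk(0, 50, 900, 500)], geometry=G)


def test_postprocess_is_idempotent(small_cohort, small_geometry):
    recordings, _ = small_cohort
    params = DetectionParams()
    for rec in recordings[:4]:
        once = postprocess_candidates(
            detect_fixation_candidates(rec, small_geometry, params), params, small_geometry
        )
        twice = postprocess_candidates(once, params, small_geometry)
        assert [(f.onset_ms, f.offset_ms, f.x_px, f.y_px) for f in once] == [
            (f.onset_ms, f.offset_ms, f.x_px, f.y_px) for f in twice
        ]


def test_raising_min_duration_never_adds_fixations(small_cohort, small_geometry):
    recordings, _ = small_cohort
    for rec in recordings[:4]:
        cands = detect_fixation_candidates(rec, small_geometry)
        counts = [
            len(postprocess_candidates(cands, DetectionParams(min_fixation_ms=ms), small_geometry))
            for ms in (40.0, 60.0, 100.0, 150.0)
        ]
        assert counts == sorted(counts, reverse=True)


# --- selection -------------------------------------------------------------


def seq_candidates(n, start_ms=0.0, x=900.0):
    return [mk(start_ms + i * 300, 250, x, 500) for i in range(n)]


def test_first_eighteen_after_viewing_onset_are_kept_and_reindexed():
    cands = seq_candidates(25, start_ms=-600.0)  # first two start before onset 0
    sel = select_analysis_fixations(cands, viewing_onset_ms=0.0, geometry=G)
    assert not sel.excluded
    assert len(sel.fixations) == 18
    assert list(sel.fixations["index"]) == list(range(1, 19))
    assert sel.fixations["onset_ms"].iloc[0] == 0.0  # third candidate


def test_seventeen_fixations_exclude_participant():
    sel = select_analysis_fixations(seq_candidates(17), geometry=G)
    assert sel.excluded
    assert "fewer than 18" in sel.reason


def test_offscreen_fixations_drop_before_the_count():
    cands = seq_candidates(18)
    cands[5] = mk(5 * 300, 250, 2000.0, 500)  # x = 2000 on a 1920 screen
    sel = select_analysis_fixations(cands, geometry=G)
    assert sel.excluded  # only 17 on-screen remain
    cands.append(mk(18 * 300, 250, 900, 500))
    sel = select_analysis_fixations(cands, geometry=G)
    assert not sel.excluded
    assert (sel.fixations["x_px"] < 1920).all()


# --- credibility and quality ----------------------------------------------


def lossy_recording(loss_s):
    rec = stationary_recording([(900, 500, 600)], G)
    rec.valid[100 : 100 + int(loss_s * 60)] = False
    return rec


def test_long_loss_run_is_ineligible_for_demographics():
    ok, reason = credibility_filter(lossy_recording(6.0), {"gender": "woman", "birth_year": 1990})
    assert not ok and "loss run" in reason


def test_clean_record_with_changed_defaults_is_eligible():
    rec = stationary_recording([(900, 500, 600)], G)
    ok, reason = credibility_filter(rec, {"gender": "woman", "birth_year": 1990})
    assert ok and reason == ""


def test_unchanged_defaults_are_ineligible():
    rec = stationary_recording([(900, 500, 600)], G)
    ok, reason = credibility_filter(rec, {"gender": "woman", "birth_year": 2000})
    assert not ok and "birth year" in reason
    ok, reason = credibility_filter(rec, {"gender": "nonbinary", "birth_year": 1990})
    assert not ok and "gender" in reason
    assert credibility_filter(rec, None) == (False, "missing")


def test_quality_report_zero_noise_and_no_loss():
    rec = stationary_recording([(900, 500, 600)], G)
    q = quality_report(rec, [mk(0, 5000, 900, 500)], G)
    assert q.precision_dva == 0.0
    assert q.loss_fraction == 0.0
    assert q.longest_loss_run_s == 0.0


def test_quality_precision_matches_gaussian_closed_form():
    """Per-axis SD s in dva gives RMS-S2S = 2s (E||delta||^2 = 4 s^2)."""
    s_dva = 0.4
    rec = stationary_recording(
        [(900, 500, 6000)], G, noise_sd_px=0.0, seed=3
    )
    rng = np.random.default_rng(3)
    rec.x_px = rec.x_px + rng.normal(0, s_dva * G.px_per_deg_x, len(rec.x_px))
    rec.y_px = rec.y_px + rng.normal(0, s_dva * G.px_per_deg_y, len(rec.y_px))
    q = quality_report(rec, [mk(0, 100_000, 900, 500)], G)
    assert q.precision_dva == pytest.approx(2 * s_dva, rel=0.05)


def test_quality_without_fixations_reports_missing_precision():
    rec = stationary_recording([(900, 500, 60)], G)
    q = quality_report(rec, [], G)
    assert np.isnan(q.precision_dva)
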