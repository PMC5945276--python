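import numpy as np
import pandas as pd
import pytest

from lacoresect.event_calling import (
    EventParams,
    LossParams,
    blind_and_randomize,
    call_event,
    call_gfp_loss,
    call_on_target,
    call_rad52_onset,
    photobleach_control,
    unblind,
)


class TestRad52Onset:
    def test_onset_at_start_of_first_sustained_run(self, trace_factory):
        tr = trace_factory([0] * 5, detected=[False, False, True, True, True], channel="mCherry")
        assert call_rad52_onset(tr) == 2

    def test_flicker_is_skipped_by_persistence(self, trace_factory):
        tr = trace_factory([0] * 5, detected=[False, True, False, True, True], channel="mCherry")
        assert call_rad52_onset(tr, persistence_frames=2) == 3

    def test_never_detected_gives_no_event(self, trace_factory):
        tr = trace_factory([0] * 5, detected=[False] * 5, channel="mCherry")
        assert call_rad52_onset(tr) is None


class TestGfpLoss:
    def test_step_to_noise_floor(self, trace_factory):
        inten = [100.0] * 17 + [0.5] * 8
        assert call_gfp_loss(trace_factory(inten, noise_sd=1.0)) == 17

    def test_single_frame_dip_is_not_loss(self, trace_factory):
        inten = [100.0] * 10 + [0.5] + [100.0] * 9 + [0.5] * 5
        assert call_gfp_loss(trace_factory(inten, noise_sd=1.0)) == 20

    def test_persistent_focus_is_censored(self, trace_factory):
        assert call_gfp_loss(trace_factory([100.0] * 30, noise_sd=1.0)) is None

    def test_censoring_consistency_under_window_extension(self, trace_factory):
        """An event censored in a short window completes in a longer one."""
        full = [100.0] * 12 + [0.2] * 8
        assert call_gfp_loss(trace_factory(full[:10], noise_sd=1.0)) is None
        assert call_gfp_loss(trace_factory(full, noise_sd=1.0)) == 12


class TestOnTarget:
    def close_and_far(self, trace_factory, rad52_centers, rad52_detected):
        gfp = trace_factory([100] * 5, centers=[(5, 10, 10)] * 5)
        rad = trace_factory(
            [50] * 5, detected=rad52_detected, centers=rad52_centers, channel="mCherry"
        )
        return gfp, rad

    def test_colocalized_three_frames_is_on_target(self, trace_factory):
        gfp, rad = self.close_and_far(
            trace_factory, [(5, 10.5, 10.0)] * 5, [False, True, True, True, False]
        )
        assert call_on_target(gfp, rad, max_dist_px=3.0, min_frames=2)

    def test_single_frame_colocalization_is_rejected(self, trace_factory):
        gfp, rad = self.close_and_far(
            trace_factory, [(5, 10.5, 10.0)] * 5, [False, False, True, False, False]
        )
        assert not call_on_target(gfp, rad, max_dist_px=3.0, min_frames=2)

    def test_distant_decoy_focus_is_rejected(self, trace_factory):
        gfp, rad = self.close_and_far(trace_factory, [(5, 22.0, 10.0)] * 5, [True] * 5)
        assert not call_on_target(gfp, rad, max_dist_px=3.0, min_frames=2)

    def test_mismatched_frame_grids_error(self, trace_factory):
        gfp = trace_factory([1] * 5)
        rad = trace_factory([1] * 7, channel="mCherry")
        with pytest.raises(ValueError):
            call_on_target(gfp, rad)


class TestCallEvent:
    def make_pair(self, trace_factory, gfp_inten, rad_detected):
        n = len(gfp_inten)
        gfp = trace_factory(gfp_inten, noise_sd=1.0, centers=[(5, 10, 10)] * n)
        rad = trace_factory(
            [50] * n, detected=rad_detected, centers=[(5, 10.3, 10)] * n, channel="mCherry"
        )
        return gfp, rad

    def test_duration_is_frame_difference_times_interval(self, trace_factory):
        gfp_inten = [100.0] * 12 + [0.1] * 8
        rad_detected = [False] * 4 + [True] * 16
        gfp, rad = self.make_pair(trace_factory, gfp_inten, rad_detected)
        ev = call_event(gfp, rad)
        assert ev is not None and not ev.censored
        assert ev.rad52_onset_frame == 4
        assert ev.gfp_loss_frame == 12
        assert ev.duration_min == pytest.approx((12 - 4) * 10.0)

    def test_persistent_gfp_yields_censored_event(self, trace_factory):
        gfp, rad = self.make_pair(trace_factory, [100.0] * 20, [False] * 5 + [True] * 15)
        ev = call_event(gfp, rad)
        assert ev is not None and ev.censored
        assert np.isnan(ev.duration_min)
        assert ev.observed_window_min == pytest.approx((19 - 5) * 10.0)

    def test_no_on_target_rad52_yields_no_event(self, trace_factory):
        gfp = trace_factory([100.0] * 10, noise_sd=1.0)
        rad = trace_factory([0.0] * 10, detected=[False] * 10, channel="mCherry")
        assert call_event(gfp, rad) is None


def test_called_durations_consistent_on_rendered_movie(small_cut_run):
    cfg, result = small_cut_run
    dt = cfg.simulation.frame_interval_min
    assert result.events, "expected events on rendered cut cells"
    for ev in result.events:
        if not ev.censored:
            assert ev.duration_min == pytest.approx((ev.gfp_loss_frame - ev.rad52_onset_frame) * dt)
            assert ev.duration_min > 0


class TestPhotobleachControl:
    def test_no_false_losses_passes(self, trace_factory):
        traces = [trace_factory([100.0] * 20, noise_sd=1.0) for _ in range(10)]
        rep = photobleach_control(traces)
        assert rep.n_false_loss == 0 and not rep.flagged

    def test_false_losses_flag_dataset(self, trace_factory):
        ok = [trace_factory([100.0] * 20, noise_sd=1.0) for _ in range(8)]
        lost = [trace_factory([100.0] * 10 + [0.1] * 10, noise_sd=1.0) for _ in range(2)]
        with pytest.warns(UserWarning, match="photobleach control failed"):
            rep = photobleach_control(ok + lost)
        assert rep.flagged and rep.false_loss_fraction == pytest.approx(0.2)

    def test_no_uncut_cells_skips_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            rep = photobleach_control([])
        assert rep.skipped


class TestBlinding:
    @pytest.fixture
    def manifest(self):
        return pd.DataFrame(
            {
                "field_id": [f"f{i}" for i in range(6)],
                "genotype": ["WT", "WT", "crb2d", "crb2d", "rev7d", "rev7d"],
                "path": [f"/data/f{i}.tif" for i in range(6)],
            }
        )

    def test_deterministic_permutation(self, manifest):
        b1, k1 = blind_and_randomize(manifest, seed=11)
        b2, k2 = blind_and_randomize(manifest, seed=11)
        assert b1.equals(b2) and k1.equals(k2)

    def test_round_trip_recovers_manifest(self, manifest):
        blinded, key = blind_and_randomize(manifest, seed=3)
        assert unblind(blinded, key)[manifest.columns.tolist()].equals(manifest)

    def test_identities_removed_and_ids_are_permutation(self, manifest):
        blinded, key = blind_and_randomize(manifest, seed=3)
        assert "field_id" not in blinded.columns and "genotype" not in blinded.columns
        assert sorted(blinded["blind_id"]) == [f"blind_{i + 1:04d}" for i in range(6)]
        assert blinded["contrast_min"].nunique() == 1
        assert blinded["contrast_max"].nunique() == 1

    def test_duplicate_ids_rejected(self, manifest):
        dup = pd.concat([manifest, manifest.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            blind_and_randomize(dup, seed=0)
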