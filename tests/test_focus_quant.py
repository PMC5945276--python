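import math

import numpy as np
import pytest

from lacoresect.focus_quant import (
    CylinderParams,
    DetectionParams,
    build_trace,
    detect_foci,
    localize_subpixel,
    measure_focus_intensity,
    traces_from_frame,
    traces_to_frame,
)
from lacoresect.simulate import _add_gaussian_blob
from lacoresect.stack import ImageStack


def as_stack(volume, **kw):
    """Wrap a (z, y, x) array as a single-frame single-channel stack."""
    data = np.asarray(volume, dtype=float)[None, None]
    return ImageStack(data=data, channel_names=("GFP",), **kw)


def brute_force_measurement(volume, center_zyx, params):
    """Independent voxel-by-voxel cylinder/shell sum (exhaustive membership)."""
    cz, cy, cx = center_zyx
    cyl_vals, shell_vals = [], []
    nz, ny, nx = volume.shape
    for z in range(nz):
        if abs(z - cz) > params.half_height_slices:
            continue
        for y in range(ny):
            for x in range(nx):
                r = math.hypot(y - cy, x - cx)
                if r <= params.radius_px:
                    cyl_vals.append(volume[z, y, x])
                elif params.shell_inner_px < r <= params.shell_outer_px:
                    shell_vals.append(volume[z, y, x])
    bg = float(np.median(shell_vals))
    return float(np.sum(cyl_vals)) - len(cyl_vals) * bg


def random_aperture(rng):
    return CylinderParams(
        radius_px=float(rng.uniform(1.2, 2.6)),
        half_height_slices=float(rng.uniform(1.0, 2.0)),
        shell_gap_px=float(rng.uniform(0.0, 1.0)),
        shell_width_px=float(rng.uniform(1.0, 2.0)),
    )


def test_cylinder_operator_matches_brute_force_on_random_arrays():
    rng = np.random.default_rng(0)
    for _ in range(20):
        vol = rng.uniform(0, 100, size=(rng.integers(5, 8), 13, 13))
        params = random_aperture(rng)
        center = (
            float(rng.uniform(2.0, vol.shape[0] - 3.0)),
            float(rng.uniform(5.5, 7.5)),
            float(rng.uniform(5.5, 7.5)),
        )
        got = measure_focus_intensity(as_stack(vol), "GFP", 0, center, params)
        want = brute_force_measurement(vol, center, params)
        assert got.integrated_intensity == pytest.approx(want, rel=1e-12, abs=1e-9)


def test_hand_built_array_example():
    rng = np.random.default_rng(5)
    vol = rng.uniform(0, 10, size=(5, 9, 9))
    params = CylinderParams(radius_px=2.0, half_height_slices=1.0, shell_gap_px=0.0, shell_width_px=1.5)
    got = measure_focus_intensity(as_stack(vol), "GFP", 0, (2.0, 4.0, 4.0), params)
    assert got.integrated_intensity == pytest.approx(
        brute_force_measurement(vol, (2.0, 4.0, 4.0), params), rel=1e-12
    )


def test_uniform_image_measures_zero():
    vol = np.full((7, 15, 15), 37.5)
    m = measure_focus_intensity(as_stack(vol), "GFP", 0, (3.0, 7.0, 7.0))
    assert m.integrated_intensity == pytest.approx(0.0, abs=1e-9)


def test_intensity_is_linear_and_offset_invariant():
    rng = np.random.default_rng(1)
    vol = rng.uniform(0, 50, size=(7, 17, 17))
    center = (3.0, 8.2, 7.9)
    base = measure_focus_intensity(as_stack(vol), "GFP", 0, center).integrated_intensity
    scaled = measure_focus_intensity(as_stack(3.0 * vol), "GFP", 0, center).integrated_intensity
    offset = measure_focus_intensity(as_stack(vol + 100.0), "GFP", 0, center).integrated_intensity
    assert scaled == pytest.approx(3.0 * base, rel=1e-9)
    assert offset == pytest.approx(base, abs=1e-6)


def test_whole_voxel_translation_preserves_measurement():
    rng = np.random.default_rng(2)
    vol = np.zeros((9, 21, 21))
    vol[2:7, 3:15, 3:15] = rng.uniform(0, 20, size=(5, 12, 12))
    c = (4.0, 8.0, 8.0)
    m1 = measure_focus_intensity(as_stack(vol), "GFP", 0, c).integrated_intensity
    shifted = np.roll(vol, shift=(1, 2, 3), axis=(0, 1, 2))
    m2 = measure_focus_intensity(
        as_stack(shifted), "GFP", 0, (c[0] + 1, c[1] + 2, c[2] + 3)
    ).integrated_intensity
    assert m2 == pytest.approx(m1, rel=1e-12)


def test_border_crossing_is_flagged_not_clipped():
    vol = np.ones((7, 15, 15))
    m = measure_focus_intensity(as_stack(vol), "GFP", 0, (3.0, 1.0, 7.0))
    assert not m.valid


def test_detect_empty_and_flat_volumes():
    assert detect_foci(as_stack(np.zeros((7, 20, 20))), "GFP", 0) == []
    assert detect_foci(as_stack(np.full((7, 20, 20), 5.0)), "GFP", 0) == []


def test_detect_single_and_double_noise_free_foci():
    vol = np.zeros((11, 30, 30))
    _add_gaussian_blob(vol, (5.0, 10.0, 10.0), (1.5, 1.1, 1.1), 5000.0)
    cands = detect_foci(as_stack(vol), "GFP", 0)
    assert len(cands) == 1
    assert abs(cands[0].z - 5) <= 1 and abs(cands[0].y - 10) <= 1 and abs(cands[0].x - 10) <= 1

    # second focus >= 4 psf sigma away resolves separately
    _add_gaussian_blob(vol, (5.0, 10.0, 20.0), (1.5, 1.1, 1.1), 5000.0)
    cands = detect_foci(as_stack(vol), "GFP", 0)
    assert len(cands) == 2


def test_subpixel_centroid_on_voxel_centered_spot():
    vol = np.zeros((11, 21, 21))
    _add_gaussian_blob(vol, (5.0, 10.0, 10.0), (1.5, 1.1, 1.1), 5000.0)
    center, low = localize_subpixel(as_stack(vol), "GFP", 0, (5, 10, 10))
    assert not low
    assert center[1] == pytest.approx(10.0, abs=0.05)
    assert center[2] == pytest.approx(10.0, abs=0.05)


def test_subpixel_centroid_recovers_fractional_offsets_at_snr_10():
    rng = np.random.default_rng(3)
    vol = np.zeros((11, 21, 21))
    _add_gaussian_blob(vol, (5.0, 10.3, 9.8), (1.5, 1.1, 1.1), 8000.0)
    noisy = rng.poisson(vol + 30.0).astype(float)
    center, low = localize_subpixel(as_stack(noisy), "GFP", 0, (5, 10, 10))
    assert not low
    assert center[1] == pytest.approx(10.3, abs=0.15)
    assert center[2] == pytest.approx(9.8, abs=0.15)


def test_uniform_window_returns_seed_low_confidence():
    vol = np.full((11, 21, 21), 12.0)
    center, low = localize_subpixel(as_stack(vol), "GFP", 0, (5, 10, 10))
    assert low
    assert center == (5.0, 10.0, 10.0)


def test_large_cylinder_captures_rendered_intensity_noise_free():
    vol = np.zeros((21, 31, 31))
    _add_gaussian_blob(vol, (10.0, 15.0, 15.0), (1.5, 1.1, 1.1), 5000.0)
    params = CylinderParams(radius_px=4.0, half_height_slices=6.0, shell_gap_px=1.0, shell_width_px=2.0)
    m = measure_focus_intensity(as_stack(vol), "GFP", 0, (10.0, 15.0, 15.0), params)
    assert m.integrated_intensity == pytest.approx(5000.0, rel=0.05)


def test_uncut_traces_track_gfp_but_never_mcherry(small_uncut_stack):
    cfg, stack, truth = small_uncut_stack
    r = truth.iloc[0]
    roi = (int(r.y0), int(r.y1), int(r.x0), int(r.x1))
    gfp = build_trace(stack, "GFP", roi, cfg.detection, cfg.cylinder, cell_id=r.cell_id)
    mch = build_trace(stack, "mCherry", roi, cfg.detection, cfg.cylinder, cell_id=r.cell_id)
    assert gfp.detected.all()
    assert not mch.detected.any()
    # GFP focus centered near truth
    assert np.allclose(gfp.centers[:, 1], r.focus_y, atol=1.0)


def test_cut_cell_trace_shows_plateau_then_decline(small_cut_run):
    cfg, result = small_cut_run
    truth = result.truth
    done = truth[truth.completes_in_window].iloc[0]
    gfp = next(
        t for t in result.traces if t.cell_id == done.cell_id and t.channel == "GFP"
    )
    inten = gfp.intensities
    early = inten[:3].mean()
    late_frame = int(done.gfp_loss_time_min / cfg.simulation.frame_interval_min) + 1
    assert early > 5 * gfp.noise_sds[0]
    assert inten[late_frame:].max() < 0.2 * early


def test_trace_table_round_trip(small_uncut_stack):
    cfg, stack, truth = small_uncut_stack
    r = truth.iloc[1]
    roi = (int(r.y0), int(r.y1), int(r.x0), int(r.x1))
    traces = [
        build_trace(stack, ch, roi, cfg.detection, cfg.cylinder, cell_id=str(r.cell_id), genotype="WT")
        for ch in ("GFP", "mCherry")
    ]
    df = traces_to_frame(traces)
    back = traces_from_frame(df)
    assert len(back) == 2
    for orig in traces:
        match = next(t for t in back if t.channel == orig.channel)
        assert np.allclose(match.intensities, orig.intensities)
        assert np.array_equal(match.detected, orig.detected)
        assert match.frame_interval_min == pytest.approx(orig.frame_interval_min)
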