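"""Segmentation chain: each step against brute-force oracles, then end-to-end."""

import numpy as np
import pytest

from conftest import disc_offsets, exhaustive_otsu, flood_fill_components
from shadowpipe.segment import (SegmentationParams, binarize_otsu,
                                detect_regions, dilate_disc, disc_footprint,
                                mask_frequent, pixel_frequency, remove_small,
                                segment_video)
from shadowpipe.synthgen import ObjectSpec, SceneSpec, generate_video


# --- binarization ---------------------------------------------------------


def test_otsu_two_level_image_dark_on_polarity():
    rng = np.random.default_rng(0)
    frame = np.full((50, 50), 0.9)
    obj = rng.random((50, 50)) < 0.05
    frame[obj] = 0.1
    binary = binarize_otsu(frame)
    assert np.array_equal(binary, obj)  # dark pixels on, background off
    t = exhaustive_otsu(frame)
    assert 0.1 < t < 0.9


def test_otsu_matches_exhaustive_search_on_noisy_frame():
    rng = np.random.default_rng(1)
    frame = np.clip(np.where(rng.random((40, 40)) < 0.2,
                             rng.normal(0.2, 0.05, (40, 40)),
                             rng.normal(0.8, 0.05, (40, 40))), 0, 1)
    binary = binarize_otsu(frame)
    assert np.array_equal(binary, frame < exhaustive_otsu(frame))


def test_otsu_constant_frame_all_zero(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="shadowpipe.segment"):
        out = binarize_otsu(np.full((10, 10), 0.5))
    assert not out.any()
    assert any("constant" in r.message for r in caplog.records)


def test_otsu_inversion_symmetry():
    frame = np.full((20, 20), 0.9)
    frame[5:10, 5:10] = 0.1
    fg = binarize_otsu(frame)
    inv_bg = binarize_otsu(1.0 - frame)  # dark-on rule on the inverted image
    assert np.array_equal(fg, ~inv_bg)


# --- frequency masking ----------------------------------------------------


def test_pixel_frequency_worked_example():
    stack = np.zeros((100, 4, 4), dtype=bool)
    stack[:75, 0, 0] = True
    freq = pixel_frequency(stack)
    assert freq[0, 0] == 0.75
    assert freq[1:].sum() == 0


def test_mask_frequent_worked_example_and_boundaries():
    stack = np.zeros((100, 4, 4), dtype=bool)
    stack[:75, 0, 0] = True
    # above the limit: removed everywhere
    assert not mask_frequent(stack, 0.6)[:, 0, 0].any()
    # at the default 0.8 the pixel is below the limit: untouched
    assert mask_frequent(stack, 0.8)[:, 0, 0].sum() == 75
    # "exceeds" is strict: frequency exactly 1 survives max_freq=1
    always = np.ones((10, 2, 2), dtype=bool)
    assert mask_frequent(always, 1.0).all()


def test_mask_frequent_complement_and_postcondition():
    rng = np.random.default_rng(2)
    stack = rng.random((30, 8, 8)) < 0.5
    assert np.allclose(pixel_frequency(~stack), 1 - pixel_frequency(stack))
    masked = mask_frequent(stack, 0.5)
    assert pixel_frequency(masked).max() <= 0.5
    # idempotent
    assert np.array_equal(mask_frequent(masked, 0.5), masked)


def test_mask_frequent_monotone_in_threshold():
    rng = np.random.default_rng(3)
    stack = rng.random((20, 10, 10)) < 0.6
    on_low = mask_frequent(stack, 0.3).sum()
    on_high = mask_frequent(stack, 0.9).sum()
    assert on_low <= on_high


# --- minimum area ---------------------------------------------------------


def test_remove_small_lone_pixel_and_exact_boundary():
    frame = np.zeros((20, 20), dtype=bool)
    frame[2, 2] = True  # lone pixel
    frame[10:13, 10:15] = True  # area 15
    out = remove_small(frame, 15)
    assert not out[2, 2]
    assert out[10:13, 10:15].all()  # area exactly min_area_px is kept


def test_remove_small_matches_flood_fill_oracle():
    rng = np.random.default_rng(4)
    for _ in range(5):
        frame = rng.random((64, 64)) < 0.3
        for conn in (4, 8):
            out = remove_small(frame, 10, connectivity=conn)
            expected = np.zeros_like(frame)
            for comp in flood_fill_components(frame, conn):
                if len(comp) >= 10:
                    for r, c in comp:
                        expected[r, c] = True
            assert np.array_equal(out, expected)


def test_remove_small_idempotent_and_shrinking():
    rng = np.random.default_rng(5)
    frame = rng.random((48, 48)) < 0.3
    once = remove_small(frame, 8)
    assert np.array_equal(remove_small(once, 8), once)
    assert not (once & ~frame).any()  # output subset of input


# --- dilation -------------------------------------------------------------


def test_disc_footprint_matches_enumeration():
    for r in (0, 1, 3, 5):
        fp = disc_footprint(r)
        offs = disc_offsets(r)
        assert fp.sum() == len(offs)
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                assert fp[dy + r, dx + r] == ((dy, dx) in offs)


def test_dilate_lone_pixel_radius5_area81():
    frame = np.zeros((30, 30), dtype=bool)
    frame[15, 15] = True
    out = dilate_disc(frame, 5)
    assert out.sum() == 81  # |{(dy,dx): dy^2+dx^2 <= 25}|


def test_dilate_radius0_identity_and_extensive():
    rng = np.random.default_rng(6)
    frame = rng.random((40, 40)) < 0.1
    assert np.array_equal(dilate_disc(frame, 0), frame)
    out = dilate_disc(frame, 3)
    assert (out & frame).sum() == frame.sum()  # contains input


def test_dilate_joins_pixels_8_apart_with_radius5():
    frame = np.zeros((30, 40), dtype=bool)
    frame[15, 10] = True
    frame[15, 18] = True
    out = dilate_disc(frame, 5)
    assert len(flood_fill_components(out, 8)) == 1


def test_dilation_composition_and_monotonicity():
    rng = np.random.default_rng(7)
    frame = rng.random((32, 32)) < 0.05
    composed = dilate_disc(dilate_disc(frame, 2), 3)
    single = dilate_disc(frame, 3)
    assert (composed & single).sum() == single.sum()  # composed superset


# --- region detection -----------------------------------------------------


def test_detect_regions_empty_and_rectangle():
    assert detect_regions(np.zeros((10, 10), dtype=bool)) == []
    frame = np.zeros((30, 40), dtype=bool)
    frame[10:13, 20:24] = True
    assert detect_regions(frame) == [((10, 20, 3, 4), 12)]


def test_detect_regions_matches_flood_fill_oracle():
    rng = np.random.default_rng(8)
    for _ in range(5):
        frame = rng.random((64, 64)) < 0.25
        for conn in (4, 8):
            got = detect_regions(frame, connectivity=conn)
            comps = flood_fill_components(frame, conn)
            assert len(got) == len(comps)
            exp = []
            for comp in comps:
                rows = [p[0] for p in comp]
                cols = [p[1] for p in comp]
                exp.append(((min(rows), min(cols),
                             max(rows) - min(rows) + 1,
                             max(cols) - min(cols) + 1), len(comp)))
            exp.sort(key=lambda reg: (reg[0][0], reg[0][1]))
            assert got == exp


# --- end-to-end -----------------------------------------------------------


def test_segment_video_recovers_object_and_masks_artifact(crossing_scene):
    spec, video, gt = crossing_scene
    params = SegmentationParams(min_area_px=15, dilation_radius=5)
    rois = segment_video(video, params)
    art = spec.artifacts[0]
    ar, ac, arad = art["center"][0], art["center"][1], art["radius"]
    rad = params.dilation_radius
    for fi, regs in enumerate(gt.per_frame):
        frois = [r for r in rois if r.frame_index == fi]
        for reg in regs:
            r0, c0, h, w = reg["bbox"]
            hits = [
                r for r in frois
                if r.bbox[0] <= r0 and r.bbox[1] <= c0
                and r.bbox[0] + r.bbox[2] >= r0 + h
                and r.bbox[1] + r.bbox[3] >= c0 + w
            ]
            assert hits, f"object missed in frame {fi}"
            rb = hits[0].bbox
            # ROI box within the GT box padded by the dilation radius
            assert rb[0] >= r0 - rad and rb[1] >= c0 - rad
            assert rb[0] + rb[2] <= r0 + h + rad and rb[1] + rb[3] <= c0 + w + rad
    for r in rois:  # no ROI overlaps the static artifact footprint
        rr0, cc0, h, w = r.bbox
        assert not (rr0 <= ar + arad and rr0 + h >= ar - arad
                    and cc0 <= ac + arad and cc0 + w >= ac - arad)


def test_segment_video_empty_scene_zero_rois():
    video, _ = generate_video(SceneSpec(n_frames=5))
    assert segment_video(video) == []


def test_gappy_object_rejoined_into_single_roi():
    """Fragments each above min area and within 2x dilation radius of each
    other come back as one ROI, not several."""
    img = np.full((64, 64), 0.9)
    # two 4x5 fragments separated by a 6-column gap (< 2*5)
    img[30:34, 20:25] = 0.2
    img[30:34, 31:36] = 0.2
    video = np.tile(img, (3, 1, 1))
    params = SegmentationParams(min_area_px=15, dilation_radius=5, max_freq=1.0)
    rois = segment_video(video, params)
    per_frame = {}
    for r in rois:
        per_frame.setdefault(r.frame_index, []).append(r)
    assert all(len(v) == 1 for v in per_frame.values())
    assert len(per_frame) == 3


def test_roi_crop_and_metadata_contract(crossing_scene):
    _, video, _ = crossing_scene
    rois = segment_video(video, SegmentationParams())
    assert rois
    for r in rois:
        r0, c0, h, w = r.bbox
        assert r.crop.shape == (h, w)
        assert r.original_size == (h, w)
        assert r.area_px <= h * w
        assert np.array_equal(r.crop, video.frames[r.frame_index,
                                                   r0:r0 + h, c0:c0 + w])


def test_min_area_monotonicity_in_roi_count(crossing_scene):
    _, video, _ = crossing_scene
    n_small = len(segment_video(video, SegmentationParams(min_area_px=5)))
    n_big = len(segment_video(video, SegmentationParams(min_area_px=40)))
    assert n_big <= n_small


def test_mismatched_frame_counts_error(crossing_scene):
    _, video, _ = crossing_scene
    with pytest.raises(ValueError, match="frame counts"):
        segment_video(video, flatfielded=video.frames[:-1])
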