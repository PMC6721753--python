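"""Detection: background estimation, segmentation rules, feature oracle."""

import math

import numpy as np
import pytest
from skimage.measure import regionprops

import evcounter as ev
from evcounter.detect import (
    SegmentationConfig,
    equivalent_radius,
    estimate_background,
    extract_features,
    segment_stack,
)


def test_constant_frame_background():
    frame = np.full((128, 128), 100.0)
    bg, sd = estimate_background(frame)
    assert np.allclose(bg, 100.0)
    assert sd == 0.0


def test_noise_sd_estimate():
    rng = np.random.default_rng(0)
    frame = 100.0 + rng.normal(0.0, 5.0, (256, 256))
    _, sd = estimate_background(frame)
    assert abs(sd - 5.0) < 0.5


def test_bright_spot_rejected_by_robust_background():
    frame = np.full((256, 256), 100.0)
    frame[100:106, 100:106] = 600.0
    bg, _ = estimate_background(frame)
    assert abs(bg[102, 102] - 100.0) < 1.0


def test_flat_frame_threshold_fallback():
    """Zero noise must not make everything foreground: threshold falls
    back to background + 1."""
    stack = np.full((1, 64, 64), 50.0)
    stack[0, 30:34, 30:34] = 60.0
    labels, _, sds = segment_stack(stack)
    assert sds[0] == 0.0
    assert labels.max() == 1


def _blob_frame(areas, value=50.0):
    """One channel with square/rect blobs of the given pixel areas."""
    frame = np.zeros((96, 96), dtype=float)
    shapes = {3: (1, 3), 4: (2, 2), 5: (1, 5), 9: (3, 3), 12: (3, 4),
              16: (4, 4), 25: (5, 5)}
    pos = 5
    for a in areas:
        h, w = shapes[a]
        frame[pos:pos + h, 10:10 + w] = value
        pos += h + 5
    return frame


def test_min_pixel_rule_is_strict():
    """Objects must be larger than four pixels: of blobs with 3, 4, 5 and
    9 pixels only the last two survive."""
    stack = _blob_frame([3, 4, 5, 9])[None]
    labels, _, _ = segment_stack(stack)
    assert labels.max() == 2


def test_blank_frames_give_no_objects():
    labels, _, _ = segment_stack(np.zeros((3, 64, 64)))
    assert labels.max() == 0
    table = extract_features(labels, np.zeros((3, 64, 64)),
                             ["a", "b", "c"], 0.64)
    assert len(table) == 0


def test_cross_channel_union_semantics():
    """Disjoint blobs in different channels are two objects; overlapping
    blobs are one."""
    disjoint = np.zeros((2, 64, 64))
    disjoint[0, 10:13, 10:13] = 50.0
    disjoint[1, 40:43, 40:43] = 50.0
    labels, _, _ = segment_stack(disjoint)
    assert labels.max() == 2

    overlapping = np.zeros((2, 64, 64))
    overlapping[0, 10:14, 10:14] = 50.0
    overlapping[1, 12:16, 12:16] = 50.0
    labels, _, _ = segment_stack(overlapping)
    assert labels.max() == 1


def test_threshold_monotonicity():
    """Raising threshold_k never increases the number of detections."""
    rng = np.random.default_rng(4)
    frame = 20.0 + rng.normal(0.0, 2.0, (256, 256))
    for i in range(30):
        r, c = rng.integers(10, 240, 2)
        frame[r:r + 4, c:c + 4] += rng.uniform(5.0, 200.0)
    counts = []
    for k in (2.0, 4.0, 6.0, 10.0, 20.0):
        labels, _, _ = segment_stack(frame[None], SegmentationConfig(threshold_k=k))
        counts.append(labels.max())
    assert counts == sorted(counts, reverse=True)
    assert counts[0] > 0


def test_border_policy():
    stack = np.zeros((1, 64, 64))
    stack[0, 0:4, 10:14] = 50.0    # touches the frame edge
    stack[0, 30:34, 30:34] = 50.0
    keep, _, _ = segment_stack(stack, SegmentationConfig(border_policy="keep"))
    excl, _, _ = segment_stack(stack, SegmentationConfig(border_policy="exclude"))
    assert keep.max() == 2
    assert excl.max() == 1


# ---------------------------------------------------------------------------
# Feature oracle: brute-force recomputation over each object's pixel set

def _brute_force_features(labels, stack, pixel_pitch):
    out = {}
    nrows, ncols = labels.shape
    for lid in np.unique(labels):
        if lid == 0:
            continue
        pix = [(int(r), int(c)) for r, c in np.argwhere(labels == lid)]
        pixset = set(pix)
        area = len(pix)
        perim = 0
        for r, c in pix:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if (r + dr, c + dc) not in pixset:
                    perim += 1
        cr = sum(r for r, _ in pix) / area
        cc = sum(c for _, c in pix) / area
        mu20 = sum((r - cr) ** 2 for r, _ in pix) / area
        mu02 = sum((c - cc) ** 2 for _, c in pix) / area
        mu11 = sum((r - cr) * (c - cc) for r, c in pix) / area
        lam = np.linalg.eigvalsh(np.array([[mu20, mu11], [mu11, mu02]]))
        ecc = math.sqrt(1.0 - max(lam[0], 0.0) / lam[1]) if lam[1] > 0 else 0.0
        feats = {"area_px": area, "size_um2": area * pixel_pitch ** 2,
                 "perimeter_px": perim, "eccentricity": ecc,
                 "roundness": 4 * math.pi * area / perim ** 2,
                 "equivalent_radius_um": math.sqrt(area * pixel_pitch ** 2 / math.pi),
                 "centroid_row": cr, "centroid_col": cc}
        for ci in range(stack.shape[0]):
            vals = [float(stack[ci, r, c]) for r, c in pix]
            mean = sum(vals) / area
            var = sum((v - mean) ** 2 for v in vals) / area
            feats[f"mean_{ci}"] = mean
            feats[f"max_{ci}"] = max(vals)
            feats[f"min_{ci}"] = min(vals)
            feats[f"std_{ci}"] = math.sqrt(var)
            feats[f"integrated_{ci}"] = mean * area
        out[int(lid)] = feats
    return out


def _random_label_scene(rng, shape=(220, 220), n_obj=120, n_ch=3):
    labels = np.zeros(shape, dtype=np.int32)
    for k in range(1, n_obj + 1):
        h, w = rng.integers(1, 9, 2)
        r, c = rng.integers(0, shape[0] - 9, 2)
        labels[r:r + h, c:c + w] = k
    stack = rng.normal(50.0, 20.0, (n_ch,) + shape)
    return labels, stack


def test_vectorized_features_match_brute_force():
    """Every feature from the vectorized path equals a per-object loop
    over the pixel set, to 1e-9 relative, on >=100 random objects."""
    rng = np.random.default_rng(12)
    labels, stack = _random_label_scene(rng)
    table = extract_features(labels, stack, ["c0", "c1", "c2"], 0.64)
    oracle = _brute_force_features(labels, stack, 0.64)
    assert len(table) >= 100
    assert set(table["label"]) == set(oracle)
    for _, row in table.iterrows():
        ref = oracle[int(row["label"])]
        for key, col in [("area_px", "area_px"), ("size_um2", "size_um2"),
                         ("perimeter_px", "perimeter_px"),
                         ("eccentricity", "eccentricity"),
                         ("roundness", "roundness"),
                         ("equivalent_radius_um", "equivalent_radius_um"),
                         ("centroid_row", "centroid_row"),
                         ("centroid_col", "centroid_col")]:
            assert row[col] == pytest.approx(ref[key], rel=1e-9, abs=1e-9)
        for ci, ch in enumerate(["c0", "c1", "c2"]):
            assert row[f"mean_intensity_{ch}"] == pytest.approx(ref[f"mean_{ci}"], rel=1e-9)
            assert row[f"max_intensity_{ch}"] == pytest.approx(ref[f"max_{ci}"], rel=1e-9)
            assert row[f"min_intensity_{ch}"] == pytest.approx(ref[f"min_{ci}"], rel=1e-9)
            assert row[f"std_intensity_{ch}"] == pytest.approx(ref[f"std_{ci}"], rel=1e-9, abs=1e-9)
            assert row[f"integrated_intensity_{ch}"] == pytest.approx(
                ref[f"integrated_{ci}"], rel=1e-9)


def test_eccentricity_matches_regionprops():
    """Cross-check against the standard fitted-ellipse eccentricity."""
    rng = np.random.default_rng(5)
    labels, _ = _random_label_scene(rng, n_obj=60)
    table = extract_features(labels, np.ones((1,) + labels.shape),
                             ["c"], 1.0).set_index("label")
    for rp in regionprops(labels):
        assert table.loc[rp.label, "eccentricity"] == pytest.approx(
            rp.eccentricity, abs=1e-7)


def _mask_to_features(mask, pixel_pitch=0.64):
    labels = mask.astype(np.int32)
    return extract_features(labels, mask[None].astype(float), ["c"], pixel_pitch)


def test_disc_has_low_eccentricity():
    yy, xx = np.mgrid[:64, :64]
    for r in (5, 8, 12):
        mask = ((yy - 32) ** 2 + (xx - 32) ** 2) <= r ** 2
        ecc = _mask_to_features(mask)["eccentricity"].iloc[0]
        assert ecc < 0.2


def test_two_to_one_ellipse_eccentricity():
    """A 2:1 axis-ratio ellipse has eccentricity sqrt(1-1/4) = 0.866 —
    above the 0.85 gate used for the EV and platelet classes."""
    yy, xx = np.mgrid[:120, :120]
    mask = ((xx - 60) / 40.0) ** 2 + ((yy - 60) / 20.0) ** 2 <= 1.0
    ecc = _mask_to_features(mask)["eccentricity"].iloc[0]
    assert ecc == pytest.approx(math.sqrt(1 - 0.25), abs=0.01)
    assert ecc > 0.85


def test_pixel_area_conversion():
    """25 px at 0.64 um/px is 10.24 um^2; conversion is exact per object."""
    mask = np.zeros((32, 32), dtype=bool)
    mask[5:10, 5:10] = True
    row = _mask_to_features(mask).iloc[0]
    assert row["size_um2"] == pytest.approx(25 * 0.64 ** 2)
    assert row["size_um2"] / row["area_px"] == pytest.approx(0.64 ** 2)


def test_equivalent_radius_of_minimum_area():
    """The 9 um^2 minimum detected area corresponds to a ~1.7 um radius."""
    assert equivalent_radius(9.0) == pytest.approx(1.7, abs=0.01)


def test_intensity_ordering_invariant(ideal_well):
    table = ideal_well["run"].features
    for ch in ("Hoechst", "CD45", "CD61", "CD235a", "extra"):
        assert (table[f"max_intensity_{ch}"] >= table[f"mean_intensity_{ch}"] - 1e-9).all()
        assert (table[f"mean_intensity_{ch}"] >= table[f"min_intensity_{ch}"] - 1e-9).all()
        assert (table[f"std_intensity_{ch}"] >= 0).all()
        assert np.allclose(table[f"integrated_intensity_{ch}"],
                           table[f"mean_intensity_{ch}"] * table["area_px"])
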