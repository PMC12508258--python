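"""Detection contracts: oracle equivalence, control calibration, maxima
counting, cell segmentation and classification."""

import dataclasses

import numpy as np
import pytest
from oracles import flood_fill_particles, prominence_maxima_count

from evquant import synthetic as syn
from evquant._utils import derive_seed
from evquant.detection import (
    CalibrationError,
    CellParams,
    DetectionParams,
    calibrate_threshold,
    classify_cell,
    count_maxima,
    detect_particles,
    segment_cells,
)
from conftest import random_test_images, render_controls


# ---------------------------------------------------------------------------
# detect_particles
# ---------------------------------------------------------------------------


def _mask_sets(particles):
    return {frozenset(map(tuple, p.pixel_coords)) for p in particles}


@pytest.mark.parametrize("idx", range(11))
def test_detect_matches_flood_fill_oracle(idx):
    """Threshold -> fill holes -> 8-connectivity -> size filter agrees
    exactly with an independent flood-fill implementation."""
    img = random_test_images()[idx]
    params = DetectionParams(threshold=4.0, separate_touching=False)
    got = _mask_sets(detect_particles(img, params))
    want = flood_fill_particles(img, 4.0, min_size=params.min_size_px)
    assert got == want


def test_blank_image_no_particles():
    assert detect_particles(np.zeros((32, 32)), DetectionParams(threshold=1.0)) == []
    with pytest.raises(ValueError):
        detect_particles(np.zeros((0, 0)), DetectionParams(threshold=1.0))


def test_size_filter_two_blobs_of_three():
    """Two 12-px blobs pass the 10-px minimum; a 5-px blob does not."""
    img = np.zeros((64, 64))
    img[5:9, 5:8] = 10.0    # 12 px
    img[30:34, 30:33] = 10.0  # 12 px
    img[50:51, 50:55] = 10.0  # 5 px
    parts = detect_particles(img, DetectionParams(threshold=5.0))
    assert len(parts) == 2
    assert sorted(p.area_px for p in parts) == [12, 12]


def test_fill_holes_ring_with_interior_hole():
    """A 12-px ring enclosing a 2-px hole fills to one 14-px particle."""
    img = np.zeros((16, 16))
    ring = [
        (2, 2), (2, 3), (2, 4), (2, 5),
        (3, 2), (3, 5),
        (4, 2), (4, 3), (4, 4), (4, 5),
        (5, 3), (5, 4),
    ]
    for y, x in ring:
        img[y, x] = 9.0
    assert img.sum() == 9.0 * 12  # ring is 12 px; hole at (3,3),(3,4)
    parts = detect_particles(img, DetectionParams(threshold=5.0, fill_holes=True))
    assert len(parts) == 1
    assert parts[0].area_px == 14
    off = detect_particles(img, DetectionParams(threshold=5.0, fill_holes=False))
    assert off[0].area_px == 12


def test_watershed_separates_touching_pair():
    """Two bright peaks in one merged component split into two particles."""
    yy, xx = np.mgrid[0:48, 0:48]
    img = 200 * np.exp(-((yy - 24) ** 2 + (xx - 16) ** 2) / 18.0)
    img += 200 * np.exp(-((yy - 24) ** 2 + (xx - 30) ** 2) / 18.0)
    # several small reference spots keep the median component area low
    for cx in (6, 42):
        img += 150 * np.exp(-((yy - 6) ** 2 + (xx - cx) ** 2) / 3.0)
    assert img[24, 23] > 20.0  # the two spots merge at this threshold
    on = detect_particles(img, DetectionParams(threshold=20.0))
    off = detect_particles(img, DetectionParams(threshold=20.0, separate_touching=False))
    assert len(on) == len(off) + 1


def test_masks_pairwise_disjoint(tsa_scene):
    parts = tsa_scene["particles"]
    seen = set()
    for p in parts:
        mask = set(map(tuple, p.pixel_coords))
        assert not (mask & seen)
        seen |= mask


def test_count_monotone_in_threshold(tsa_scene):
    img = tsa_scene["image"]
    base = tsa_scene["params"]
    thresholds = np.linspace(base.threshold, img.max() + 1, 12)
    counts = [
        len(detect_particles(img, dataclasses.replace(base, threshold=float(t))))
        for t in thresholds
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# calibrate_threshold
# ---------------------------------------------------------------------------


def test_calibrate_all_zero_control_returns_grid_minimum():
    z = np.zeros((64, 64))
    params = DetectionParams()
    thr = calibrate_threshold([z], params)
    assert thr == 0.0
    assert detect_particles(z, dataclasses.replace(params, threshold=thr)) == []


def test_calibrate_equal_blob_control_crosses_blob_intensity():
    """15 blobs at intensity 100: the threshold lands just above 100 and
    post-calibration control detections drop to zero."""
    img = np.zeros((128, 128))
    for i in range(15):
        y, x = 8 * (i // 4) + 4, 30 * (i % 4) + 4
        img[y : y + 4, x : x + 3] = 100.0
    params = DetectionParams()
    thr = calibrate_threshold([img], params)
    assert thr > 100.0
    assert len(detect_particles(img, dataclasses.replace(params, threshold=thr))) == 0
    # exhaustive scan: every threshold at or below 100 fails the criterion
    for t in (0.0, 50.0, 100.0):
        n = len(detect_particles(img, dataclasses.replace(params, threshold=t)))
        assert n == 0 or n >= params.max_control_detections


def test_calibrated_nsb_controls_stay_under_limit(field_config, tsa, optics):
    """Simulated EV-free controls: every calibration control yields fewer
    than the maximum allowed detections at the chosen threshold."""
    controls = render_controls(field_config, tsa, optics, master_seed=21, n=3)
    params = DetectionParams()
    thr = calibrate_threshold(controls, params)
    p2 = dataclasses.replace(params, threshold=thr)
    for im in controls:
        assert len(detect_particles(im, p2)) < params.max_control_detections


def test_calibrate_requires_controls():
    with pytest.raises(ValueError):
        calibrate_threshold([], DetectionParams())


def test_calibrate_sentinel_rescues_saturated_control():
    """A control whose every candidate quantile fails still calibrates: the
    sentinel just above the maximum yields zero detections."""
    rng = np.random.default_rng(0)
    img = rng.integers(40, 44, size=(64, 64)).astype(float)  # dense texture
    params = DetectionParams(min_size_px=1, max_control_detections=2)
    thr = calibrate_threshold([img], params)
    assert thr > img.max()
    assert detect_particles(img, dataclasses.replace(params, threshold=thr)) == []


# ---------------------------------------------------------------------------
# count_maxima
# ---------------------------------------------------------------------------


def test_count_maxima_constant_image_zero():
    assert count_maxima(np.full((32, 32), 7.0), 0.0) == 0


def test_count_maxima_two_peaks_tolerance():
    """Peaks of 200 over a 50-valley: both count at tolerance 100; at
    tolerance 300 they merge into at most one."""
    yy, xx = np.mgrid[0:40, 0:40]
    img = 200 * np.exp(-((yy - 20) ** 2 + (xx - 12) ** 2) / 31.0)
    img += 200 * np.exp(-((yy - 20) ** 2 + (xx - 28) ** 2) / 31.0)
    valley = img[20, 20]
    assert 30 < valley < 80  # saddle well below the peaks
    assert count_maxima(img, 100.0) == 2
    assert count_maxima(img, 300.0) <= 1


def test_count_maxima_zero_tolerance_counts_strict_local_maxima():
    rng = np.random.default_rng(0)
    img = rng.normal(size=(24, 24))
    got = count_maxima(img, 0.0)
    assert got == prominence_maxima_count(img, 0.0)


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("tol", [0.0, 1.0, 2.5])
def test_count_maxima_matches_prominence_oracle(seed, tol):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 8, size=(16, 16)).astype(float)
    assert count_maxima(img, tol) == prominence_maxima_count(img, tol)


def test_count_maxima_rejects_negative_tolerance():
    with pytest.raises(ValueError):
        count_maxima(np.zeros((4, 4)), -1.0)


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def test_segment_cells_no_dapi_no_cells():
    blank = np.zeros((64, 64))
    params = CellParams(membrane_channels=("STEAM",), wbc_channels=("CD45",))
    cells = segment_cells(blank, {"STEAM": blank, "CD45": blank}, params)
    assert cells == []


def test_segment_cells_missing_channel_errors():
    with pytest.raises(KeyError):
        segment_cells(np.zeros((16, 16)), {}, CellParams())


def test_completeness_is_positive_ring_fraction():
    """A membrane ring positive over 40% of its pixels gives completeness
    0.40 and survives the >30% rule; 20% coverage is excluded."""
    shape = (64, 64)
    dapi = np.where(_disk_mask(shape, 32, 32, 5), 100.0, 0.0)
    params = CellParams(
        membrane_channels=("STEAM",), wbc_channels=("CD45",),
        positivity_thresholds={"STEAM": 50.0, "CD45": 50.0},
    )
    zero = np.zeros(shape)
    rec0 = segment_cells(dapi, {"STEAM": zero, "CD45": zero}, params)[0]
    ring = rec0.ring_coords
    for frac, kept in ((0.40, True), (0.20, False)):
        marker = np.zeros(shape)
        n_pos = int(round(frac * len(ring)))
        marker[ring[:n_pos, 0], ring[:n_pos, 1]] = 200.0
        rec = segment_cells(dapi, {"STEAM": marker, "CD45": zero}, params)[0]
        assert rec.ring_positive_fraction["STEAM"] == pytest.approx(frac, abs=0.005)
        cls = classify_cell(rec, params)
        assert (cls == "CTC") is kept


def test_classification_rules():
    params = CellParams(
        membrane_channels=("STEAM",), wbc_channels=("CD45",),
    )
    from evquant.detection import CellRecord

    def rec(steam, cd45):
        r = CellRecord(
            id=0, nucleus_coords=np.zeros((1, 2), int),
            cell_coords=np.zeros((1, 2), int), ring_coords=np.zeros((1, 2), int),
            area_px=1, centroid=(0, 0), nuclear_contrast=1.0, nuclear_mean=50.0,
        )
        r.ring_positive_fraction = {"STEAM": steam, "CD45": cd45}
        return r

    assert classify_cell(rec(0.0, 0.0), params) == "excluded"
    assert classify_cell(rec(0.5, 0.0), params) == "CTC"
    assert classify_cell(rec(0.0, 0.5), params) == "WBC"
    double = rec(0.5, 0.6)
    assert classify_cell(double, params) == "excluded"
    assert double.double_positive


def test_cell_spike_in_classification_accuracy(optics):
    """Rendered 1:1 CTC:WBC mixture classified against ground truth with
    >= 95% accuracy; CTC nuclei come out larger than WBC nuclei."""
    cfg = syn.FieldConfig(
        fov_shape=(256, 256), ev_density=0.0, nsb_density=0.0,
        cells_per_fov=8.0, ctc_fraction=0.5,
    )
    stain = syn.tsa_default()
    dapi_stain = syn.StainMethod(name="DS", fluors_per_primary=3.0, label_efficiency=1.0)
    params = CellParams(
        membrane_channels=("STEAM",), wbc_channels=("CD45",),
        positivity_thresholds={"STEAM": 60.0, "CD45": 60.0},
    )
    total = correct = 0
    nuc_areas = {"CTC": [], "WBC": []}
    for k in range(4):
        field = syn.sample_field(cfg, derive_seed(31, "field", k))
        cells = field.of_kind("CELL")
        if not cells:
            continue
        dapi = syn.render_image(
            field, syn.simulate_staining(field, dapi_stain, "DAPI", derive_seed(31, "staining", k)),
            optics, derive_seed(31, "render", k), cell_region="nucleus",
        )
        imgs = {}
        for j, marker in enumerate(("STEAM", "CD45")):
            if any(marker in c.copies for c in cells):
                rates = syn.simulate_staining(
                    field, stain, marker, derive_seed(31, "staining", 10 * k + j)
                )
            else:  # single-class field this FOV
                rates = np.zeros(len(field.particles))
            imgs[marker] = syn.render_image(
                field, rates, optics, derive_seed(31, "render", 10 * k + j)
            )
        records = segment_cells(dapi, imgs, params)
        for rec_ in records:
            # match to nearest true cell
            d = [
                (rec_.centroid[0] - c.x) ** 2 + (rec_.centroid[1] - c.y) ** 2
                for c in cells
            ]
            truth = cells[int(np.argmin(d))]
            got = classify_cell(rec_, params)
            total += 1
            correct += got == truth.cell_class
            if got == truth.cell_class:
                nuc_areas[got].append(len(rec_.nucleus_coords))
    assert total >= 10
    assert correct / total >= 0.95
    assert np.mean(nuc_areas["CTC"]) > np.mean(nuc_areas["WBC"])
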