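"""Segmentation, skeleton taxonomy and the three stereological parameters."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.ndimage import convolve

from mitocohort import morphometry as mm
from mitocohort.morphometry import (
    MorphometryRecord,
    SegmentationError,
    SegmentationResult,
    analyze_cell,
    batch_morphometry,
    compute_stereology,
    qc_overlay,
    segment_cell,
    skeletonize_network,
)
from mitocohort.synthgen import (
    CellImage,
    ImageSimConfig,
    cell_mask,
    generate_network,
    rasterize_network,
    render_cell_image,
)

K8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def seg_of(mask):
    return SegmentationResult(np.ones_like(mask), mask.copy(), 0.0, 0.0)


def brute_taxonomy(sk):
    """Exhaustive per-pixel neighbour count and flood-fill fragment count."""
    counts = {0: 0, 1: 0, 2: 0, 3: 0}
    h, w = sk.shape
    for r, c in np.argwhere(sk):
        n = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and 0 <= r + dr < h and 0 <= c + dc < w and sk[r + dr, c + dc]:
                    n += 1
        counts[min(n, 3)] += 1
    seen = np.zeros_like(sk)
    frags = 0
    for r0, c0 in np.argwhere(sk):
        if seen[r0, c0]:
            continue
        frags += 1
        stack = [(r0, c0)]
        while stack:
            r, c = stack.pop()
            if seen[r, c]:
                continue
            seen[r, c] = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (dr or dc) and 0 <= rr < h and 0 <= cc < w and sk[rr, cc] and not seen[rr, cc]:
                        stack.append((rr, cc))
    return counts, frags


def test_line_taxonomy():
    mask = np.zeros((7, 9), bool)
    mask[3, 2:7] = True
    sk = skeletonize_network(seg_of(mask))
    assert (sk.n_ends, sk.n_through, sk.n_branch, sk.n_isolated) == (2, 3, 0, 0)
    assert sk.n_fragments == 1 and sk.total_length_px == 5


def test_diagonal_cross_taxonomy():
    """Centre pixel with four one-pixel diagonal arms: one branch pixel, four
    ends, one fragment, length five (8-connected neighbourhood)."""
    mask = np.zeros((7, 7), bool)
    mask[3, 3] = True
    for dr, dc in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
        mask[3 + dr, 3 + dc] = True
    sk = skeletonize_network(seg_of(mask))
    assert (sk.n_branch, sk.n_ends, sk.n_fragments, sk.total_length_px) == (1, 4, 1, 5)


def test_straight_plus_under_8_connectivity():
    # in an 8-connected neighbourhood every pixel of a one-pixel + touches
    # three others, so all five pixels classify as branch pixels
    mask = np.zeros((7, 7), bool)
    mask[3, 2:5] = True
    mask[2:5, 3] = True
    sk = skeletonize_network(seg_of(mask))
    assert sk.n_branch == 5 and sk.n_ends == 0 and sk.total_length_px == 5


def test_isolated_pixels_count_as_fragments():
    mask = np.zeros((9, 9), bool)
    mask[1, 1] = True
    mask[5, 5:8] = True
    sk = skeletonize_network(seg_of(mask))
    assert sk.n_isolated == 1 and sk.n_fragments == 2
    rec = compute_stereology(seg_of(mask), sk)
    assert rec.fragmentation == pytest.approx(2 / 4)


def test_taxonomy_matches_brute_force_on_random_masks():
    """Per-pixel classes and fragment counts equal an exhaustive oracle on 50
    random masks (class conservation holds by construction)."""
    rng = np.random.default_rng(42)
    for i in range(50):
        mask = rng.random((28, 28)) < 0.25
        if not mask.any():
            continue
        sk = skeletonize_network(seg_of(mask), prune_spurs_px=0)
        counts, frags = brute_taxonomy(sk.skeleton_mask)
        assert sk.n_isolated == counts[0]
        assert sk.n_ends == counts[1]
        assert sk.n_through == counts[2]
        assert sk.n_branch == counts[3]
        assert sk.n_fragments == frags
        assert sum(counts.values()) == sk.total_length_px


def test_thinning_idempotence():
    rng = np.random.default_rng(7)
    for i in range(20):
        mask = rng.random((30, 30)) < 0.3
        if not mask.any():
            continue
        sk1 = skeletonize_network(seg_of(mask), prune_spurs_px=0)
        sk2 = skeletonize_network(seg_of(sk1.skeleton_mask), prune_spurs_px=0)
        assert np.array_equal(sk1.skeleton_mask, sk2.skeleton_mask)


def test_fragmentation_monotone_in_edge_deletion():
    """Cutting a skeleton into more pieces at equal length raises fragmentation."""
    mask = np.zeros((9, 40), bool)
    mask[4, 2:38] = True
    one = compute_stereology(seg_of(mask), skeletonize_network(seg_of(mask)))
    cut = mask.copy()
    cut[4, 12] = cut[4, 25] = False
    # keep total length equal by adding two isolated pixels elsewhere
    cut[1, 2] = cut[1, 5] = True
    three = compute_stereology(seg_of(cut), skeletonize_network(seg_of(cut)))
    assert three.total_length_px == one.total_length_px
    assert three.fragmentation > one.fragmentation


def test_stereology_ratio_definitions():
    cellm = np.zeros((40, 40), bool)
    cellm[:25, :40] = True  # 1000 px
    netm = np.zeros((40, 40), bool)
    netm[2:4, 0:25] = True  # 50 px within the cell... use exactly 100
    netm[:, :] = False
    netm[2:6, 0:25] = True  # 100 px
    seg = SegmentationResult(cellm, netm & cellm, 0, 0)
    sk = skeletonize_network(seg)
    rec = compute_stereology(seg, sk)
    assert rec.vv_pct == pytest.approx(100 * netm.sum() / cellm.sum())
    line = np.zeros((9, 24), bool)
    line[4, 2:22] = True  # single 20 px line
    rec = compute_stereology(seg_of(line), skeletonize_network(seg_of(line)))
    assert rec.fragmentation == pytest.approx(0.05)
    assert rec.branching == 0.0


def test_noiseless_segmentation_recovers_raster_exactly(small_network, clean_cell):
    seg = segment_cell(clean_cell)
    raster = rasterize_network(small_network, clean_cell.mito_channel.shape, (90, 90))
    assert np.array_equal(seg.network_mask, raster)
    assert np.array_equal(
        seg.cell_mask,
        cell_mask(clean_cell.mito_channel.shape, (90, 90), small_network.cell_radius_px),
    )
    rec = analyze_cell(clean_cell)
    assert abs(rec.vv_pct - small_network.target_vv_pct) <= 1.0
    assert rec.n_fragments == small_network.n_fragments


def test_constant_image_fails_segmentation():
    img = CellImage(np.full((64, 64), 7.0), None, 0.05, "flat")
    with pytest.raises(SegmentationError):
        segment_cell(img)


def test_pure_noise_image_fails_segmentation():
    rng = np.random.default_rng(0)
    img = CellImage(rng.normal(10, 1, (64, 64)).clip(0), None, 0.05, "noise")
    with pytest.raises(SegmentationError):
        analyze_cell(img)


def test_blob_outside_cell_excluded():
    img = np.full((100, 100), 10.0)
    img[30:70, 30:70] = 60.0          # the cell
    img[45:55, 45:55] = 220.0         # in-cell network
    img[5:9, 5:9] = 220.0             # bright debris outside the cell
    seg = segment_cell(CellImage(img, None, 0.05, "blob"))
    assert not seg.network_mask[5:9, 5:9].any()
    assert seg.network_mask[46:54, 46:54].all()


def test_batch_reports_failures_and_is_deterministic(small_network, clean_cfg, noisy_cfg):
    imgs = [
        render_cell_image(small_network, replace(noisy_cfg, seed=s), cell_id=f"c{s}")
        for s in range(4)
    ]
    imgs.append(CellImage(np.full((64, 64), 3.0), None, 0.05, "broken"))
    records, failures = batch_morphometry(imgs, ["S1"] * 5)
    assert len(records) == 4
    assert len(failures) == 1 and failures.loc[0, "cell_id"] == "broken"
    records2, _ = batch_morphometry(imgs, ["S1"] * 5)
    pd.testing.assert_frame_equal(records, records2)


def test_qc_overlay_shapes_and_classes(clean_cell):
    seg = segment_cell(clean_cell)
    sk = skeletonize_network(seg)
    rgb = qc_overlay(seg, sk)
    assert rgb.shape == (*clean_cell.mito_channel.shape, 3)
    assert rgb.dtype == np.uint8
    # skeleton end pixels are painted red
    assert (rgb[..., 0] == 255).any()
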