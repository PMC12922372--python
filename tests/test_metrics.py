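"""Per-cell metrics against hand arithmetic, enumeration oracles, and
planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nctquant as nq
from nctquant import (
    MarkerSpec,
    SceneSpec,
    SegmentedCell,
    UndefinedMetric,
    generate_scene,
)

from conftest import disk_mask, make_image


def brute_force_mean(pixels, mask):
    """Enumeration oracle: sum pixel-by-pixel in raster order, divide."""
    vals = np.array([pixels[r, c] for r, c in np.argwhere(mask)])
    return vals.sum() / len(vals)


# ---------------------------------------------------------------------------
# mean-over-mask oracle equivalence


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_mask_mean_matches_enumeration_bitwise(seed):
    rng = np.random.default_rng(seed)
    shape = (rng.integers(5, 20), rng.integers(5, 20))
    pixels = rng.uniform(0, 1000, shape)
    mask = rng.random(shape) < 0.4
    if not mask.any():
        mask[0, 0] = True
    img = make_image(pixels)
    assert nq.mask_mean(img, mask) == brute_force_mean(pixels, mask)


# ---------------------------------------------------------------------------
# C/N and N/C ratios


def test_cn_ratio_uniform_image_is_one():
    cell = SegmentedCell(1, disk_mask((40, 40), (20, 20), 5), disk_mask((40, 40), (20, 20), 12))
    img = make_image(np.full((40, 40), 50.0))
    assert nq.cn_ratio(img, cell, background=0.0) == 1.0
    assert nq.nc_gradient(img, cell, background=0.0) == 1.0


def test_cn_ratio_hand_arithmetic():
    """5x5 toy: nucleus mean 10, cytosol mean 20, background 0 → 2.0."""
    px = np.zeros((5, 5))
    nucleus = np.zeros((5, 5), dtype=bool)
    nucleus[2, 2] = True
    cell = np.zeros((5, 5), dtype=bool)
    cell[1:4, 1:4] = True
    px[nucleus] = 10
    px[cell & ~nucleus] = 20
    sc = SegmentedCell(1, nucleus, cell)
    assert nq.cn_ratio(make_image(px), sc, background=0.0) == 2.0


def test_cn_nc_reciprocal_identity(cn_scene):
    spec, channels, gt = cn_scene
    img = channels["m"]
    for cid in gt.cells.cell_id:
        sc = SegmentedCell(cid, gt.nucleus_mask(cid), gt.cell_mask(cid))
        cn = nq.cn_ratio(img, sc, spec.background_level)
        nc = nq.nc_gradient(img, sc, spec.background_level)
        assert cn * nc == pytest.approx(1.0, rel=1e-12)
        assert cn == pytest.approx(2.0, rel=1e-12)  # planted 200/100


def test_cn_ratio_nonpositive_denominator_flagged():
    cell = SegmentedCell(1, disk_mask((40, 40), (20, 20), 5), disk_mask((40, 40), (20, 20), 12))
    img = make_image(np.full((40, 40), 50.0))
    with pytest.raises(UndefinedMetric, match="nuclear mean"):
        nq.cn_ratio(img, cell, background=50.0)


@pytest.mark.parametrize("planted", [0.5, 2.0, 4.0])
def test_planted_cn_recovered_under_noise(planted):
    """Median relative error < 10% at SNR 10 (Poisson + Gaussian noise)."""
    errs = []
    for seed in range(5):
        spec = SceneSpec(
            n_cells=6,
            seed=seed,
            poisson=True,
            gaussian_sd=10.0,  # nucleus level 100 → SNR 10
            markers=[MarkerSpec(name="m", nucleus_level=100, cytosol_level=100 * planted)],
        )
        channels, gt = generate_scene(spec)
        for cid in gt.cells.cell_id:
            sc = SegmentedCell(cid, gt.nucleus_mask(cid), gt.cell_mask(cid))
            cn = nq.cn_ratio(channels["m"], sc, spec.background_level)
            errs.append(abs(cn - planted) / planted)
    assert np.median(errs) < 0.10


# ---------------------------------------------------------------------------
# laminar intensity and envelope/nucleoplasm


def test_laminar_intensity_constant_and_oracle():
    ring = nq.make_ring(disk_mask((60, 60), (30, 30), 10), 3.0, 0.0, 1.0)
    img = make_image(np.full((60, 60), 42.0))
    assert nq.laminar_intensity(img, ring, background=10.0) == 32.0
    rng = np.random.default_rng(1)
    px = rng.uniform(0, 500, (60, 60))
    img2 = make_image(px)
    assert nq.laminar_intensity(img2, ring, 0.0) == brute_force_mean(px, ring)


def test_planted_ring_level_recovered_noise_free():
    spec = SceneSpec(
        n_cells=4,
        seed=2,
        markers=[MarkerSpec(name="ring", ring_level=300, gap_fraction=0.0)],
    )
    channels, gt = generate_scene(spec)
    for cid in gt.cells.cell_id:
        ring = nq.make_ring(gt.nucleus_mask(cid), 1.3, 0.0, spec.pixel_size)
        lam = nq.laminar_intensity(channels["ring"], ring, spec.background_level)
        assert lam == pytest.approx(300, rel=0.05)


def test_envelope_nucleoplasm_uniform_and_planted():
    nucleus = disk_mask((60, 60), (30, 30), 12)
    img = make_image(np.full((60, 60), 77.0))
    assert nq.envelope_to_nucleoplasm_ratio(img, nucleus) == pytest.approx(1.0)
    # planted: band at 2x the nucleoplasm level
    px = np.zeros((60, 60))
    px[nucleus] = 100
    from scipy import ndimage
    from skimage.morphology import disk as dfp

    band = ndimage.binary_dilation(nucleus, structure=dfp(1)) & ~nucleus
    px[band] = 200
    ratio = nq.envelope_to_nucleoplasm_ratio(make_image(px), nucleus, band_px=1)
    assert ratio == pytest.approx(2.0, abs=0.01)


def test_envelope_nucleoplasm_degenerate_nucleus():
    tiny = np.zeros((10, 10), dtype=bool)
    tiny[5, 5] = True
    with pytest.raises(UndefinedMetric, match="too small"):
        nq.envelope_to_nucleoplasm_ratio(make_image(np.ones((10, 10))), tiny)


# ---------------------------------------------------------------------------
# puncta


def test_detect_puncta_blank_and_filters():
    img = make_image(np.zeros((80, 80)))
    region = np.ones((80, 80), dtype=bool)
    assert len(nq.detect_puncta(img, region, 10, 1, 50)) == 0
    # one disk below the area floor is excluded
    px = np.zeros((80, 80))
    px[disk_mask((80, 80), (40, 40), 2)] = 100
    ps = nq.detect_puncta(make_image(px), region, 10, min_area_um2=50, max_area_um2=500)
    assert len(ps) == 0
    with pytest.raises(ValueError, match="min_area"):
        nq.detect_puncta(img, region, 10, 5, 5)


def test_detect_puncta_planted_exact_noise_free():
    spec = SceneSpec(
        n_cells=4,
        seed=9,
        markers=[MarkerSpec(name="p", n_puncta=5, punctum_level=400, punctum_radius_um=0.6)],
    )
    channels, gt = generate_scene(spec)
    for cid in gt.cells.cell_id:
        cyto = gt.cell_mask(cid) & ~gt.nucleus_mask(cid)
        ps = nq.detect_puncta(channels["p"], cyto, spec.background_level + 200, 0.1, 5.0)
        assert len(ps) == 5
        # detected centroids match planted ones within a pixel
        planted = gt.puncta_centroids["p"][cid]
        det = ps.table[["centroid_row", "centroid_col"]].to_numpy()
        d = np.linalg.norm(planted[:, None, :] - det[None, :, :], axis=2)
        assert (d.min(axis=1) <= 1.5).all()


def test_roundness_filter_excludes_bar():
    px = np.zeros((80, 80))
    px[disk_mask((80, 80), (20, 20), 4)] = 100  # round punctum
    px[60:62, 10:50] = 100  # elongated bar, same intensity
    region = np.ones((80, 80), dtype=bool)
    all_blobs = nq.detect_puncta(make_image(px), region, 50, 1, 200)
    assert len(all_blobs) == 2
    round_only = nq.detect_puncta(make_image(px), region, 50, 1, 200, min_roundness=0.6)
    assert len(round_only) == 1
    assert round_only.table.roundness.iloc[0] > 0.8


def test_envelope_distance_filter():
    nucleus = disk_mask((100, 100), (50, 50), 15)
    px = np.zeros((100, 100))
    px[disk_mask((100, 100), (50, 68), 3)] = 100  # 3 px from the rim
    px[disk_mask((100, 100), (50, 90), 3)] = 100  # 25 px out
    region = ~nucleus
    near = nq.detect_puncta(
        make_image(px), region, 50, 1, 100,
        max_dist_to_envelope_um=5.0, nucleus_mask=nucleus,
    )
    assert len(near) == 1
    assert near.table.dist_to_envelope_um.iloc[0] == pytest.approx(3.0, abs=1.0)
    with pytest.raises(ValueError, match="nucleus_mask"):
        nq.detect_puncta(make_image(px), region, 50, 1, 100, max_dist_to_envelope_um=5.0)


def test_puncta_summaries():
    empty = nq.detect_puncta(make_image(np.zeros((20, 20))), np.ones((20, 20), bool), 1, 1, 10)
    n, mean_area = nq.puncta_size_summary(empty)
    assert n == 0 and np.isnan(mean_area)
    tab = pd.DataFrame({"area_um2": [1.0, 2.0, 3.0]})
    ps = nq.PunctaSet(table=tab, params={})
    assert nq.puncta_size_summary(ps) == (3, 2.0)
    assert nq.puncta_count(ps) == 3


# ---------------------------------------------------------------------------
# envelope profile and continuity


def test_envelope_profile_full_ring_flat(ring_scene):
    spec = SceneSpec(
        n_cells=3, seed=4,
        markers=[MarkerSpec(name="ring", ring_level=300, gap_fraction=0.0)],
    )
    channels, gt = generate_scene(spec)
    for cid in gt.cells.cell_id:
        prof = nq.envelope_profile(channels["ring"], gt.nucleus_mask(cid), 1.3)
        assert np.all(prof.intensity >= 300)  # every position sees the rim
        assert prof.arc_um[0] == 0.0
        assert np.all(np.diff(prof.arc_um) > 0)
        assert prof.arc_um[-1] == pytest.approx(prof.perimeter_um)
        assert tuple(prof.path[0]) == tuple(prof.path[-1])


def test_profile_perimeter_near_analytic_circumference():
    nucleus = disk_mask((100, 100), (50, 50), 30)
    img = make_image(np.zeros((100, 100)), pixel_size=0.5)
    prof = nq.envelope_profile(img, nucleus, 1.0)
    assert prof.perimeter_um == pytest.approx(2 * np.pi * 30 * 0.5, rel=0.05)


def test_continuity_index_quarter_gap_arc_arithmetic():
    """One 90° gap on a circular rim → index 0.75, one fragment, one gap."""
    shape = (120, 120)
    nucleus = disk_mask(shape, (60, 60), 25)
    from scipy import ndimage
    from skimage.morphology import disk as dfp

    band = ndimage.binary_dilation(nucleus, structure=dfp(4)) & ~nucleus
    rr, cc = np.nonzero(band)
    ang = np.arctan2(rr - 60.0, cc - 60.0) % (2 * np.pi)
    px = np.zeros(shape)
    keep = ~((ang >= np.pi / 4) & (ang < 3 * np.pi / 4))
    px[rr[keep], cc[keep]] = 200
    prof = nq.envelope_profile(make_image(px), nucleus, 4.0)
    idx, frags, gaps = nq.continuity_index(prof, 100)
    assert idx == pytest.approx(0.75, abs=0.03)
    assert frags == 1 and gaps == 1


def test_continuity_trivial_cases():
    nucleus = disk_mask((60, 60), (30, 30), 12)
    full = make_image(np.full((60, 60), 200.0))
    prof = nq.envelope_profile(full, nucleus, 2.0)
    assert nq.continuity_index(prof, 100) == (1.0, 1, 0)
    blank = make_image(np.zeros((60, 60)))
    prof0 = nq.envelope_profile(blank, nucleus, 2.0)
    assert nq.continuity_index(prof0, 100) == (0.0, 0, 1)


@pytest.mark.parametrize("gap", [0.0, 0.25, 0.5])
def test_planted_gap_fraction_recovered(gap):
    spec = SceneSpec(
        n_cells=5, seed=13, image_shape=(300, 300),
        markers=[MarkerSpec(name="ring", ring_level=300, gap_fraction=gap)],
    )
    channels, gt = generate_scene(spec)
    tab = gt.cells.set_index("cell_id")
    for cid in tab.index:
        prof = nq.envelope_profile(channels["ring"], gt.nucleus_mask(cid), 1.3)
        thr = nq.default_continuity_threshold(prof, background=spec.background_level)
        idx, frags, gaps = nq.continuity_index(prof, thr)
        assert idx == pytest.approx(1 - gap, abs=0.05)
        planted = int(tab.loc[cid, "ring_n_gaps"])
        assert gaps == planted
        assert frags == (planted if planted else 1)


def test_continuity_monotone_in_gap_fraction():
    means = []
    for gap in (0.0, 0.2, 0.4, 0.6):
        spec = SceneSpec(
            n_cells=4, seed=21, image_shape=(300, 300),
            markers=[MarkerSpec(name="ring", ring_level=300, gap_fraction=gap)],
        )
        channels, gt = generate_scene(spec)
        vals = []
        for cid in gt.cells.cell_id:
            prof = nq.envelope_profile(channels["ring"], gt.nucleus_mask(cid), 1.3)
            idx, _, _ = nq.continuity_index(prof, spec.background_level + 150)
            vals.append(idx)
        means.append(np.mean(vals))
    assert all(a > b for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# circularity


def test_circularity_analytic_cases():
    # formula identities: circle = 1, square = pi/4
    assert 4 * np.pi * np.pi * 1**2 / (2 * np.pi * 1) ** 2 == pytest.approx(1.0)
    s = 3.7
    assert 4 * np.pi * s**2 / (4 * s) ** 2 == pytest.approx(np.pi / 4)
    # rasterized disk r=50 within [0.95, 1.05]
    mask = disk_mask((120, 120), (60, 60), 50)
    assert 0.95 <= nq.circularity(mask, 1.0) <= 1.05
    # rasterized square with raw step weights reproduces the formula value
    sq = np.zeros((100, 100), dtype=bool)
    sq[10:90, 10:90] = True
    assert nq.circularity(sq, 1.0, calibrated=False) == pytest.approx(np.pi / 4, rel=0.03)


def test_circularity_errors_on_empty():
    with pytest.raises(ValueError, match="empty"):
        nq.circularity(np.zeros((5, 5), dtype=bool), 1.0)


# ---------------------------------------------------------------------------
# colocalization


def test_colocalization_identity_disjoint_and_planted():
    rng = np.random.default_rng(5)
    px = rng.uniform(0, 100, (60, 60))
    a = make_image(px, name="a")
    b = make_image(px.copy(), name="b")
    assert nq.colocalization_ratio(a, b, 50, 50) == 1.0
    pa = np.zeros((60, 60))
    pb = np.zeros((60, 60))
    pa[10:20, 10:20] = 100
    pb[40:50, 40:50] = 100
    assert nq.colocalization_ratio(make_image(pa), make_image(pb), 50, 50) == 0.0
    spec = SceneSpec(
        n_cells=4, seed=5,
        markers=[
            MarkerSpec(name="a", nucleus_level=100, cytosol_level=100),
            MarkerSpec(name="b", overlap_with=("a", 0.35), cytosol_level=150),
        ],
    )
    channels, gt = generate_scene(spec)
    r = nq.colocalization_ratio(
        channels["a"], channels["b"], spec.background_level, spec.background_level
    )
    assert r == pytest.approx(0.35, abs=0.02)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(0.1, 5.0), st.floats(-3.0, 50.0))
def test_colocalization_invariant_to_monotone_rescale(scale, shift):
    """Jointly rescaling intensities and thresholds leaves the ratio fixed."""
    rng = np.random.default_rng(17)
    pa = rng.uniform(0, 100, (40, 40))
    pb = rng.uniform(0, 100, (40, 40))
    base = nq.colocalization_ratio(make_image(pa), make_image(pb), 60, 40)
    pa2 = np.clip(scale * pa + shift, 0, None)
    pb2 = np.clip(scale * pb + shift, 0, None)
    r2 = nq.colocalization_ratio(
        make_image(pa2), make_image(pb2), scale * 60 + shift, scale * 40 + shift
    )
    assert r2 == base


def test_colocalization_empty_reference_undefined():
    z = make_image(np.zeros((20, 20)))
    with pytest.raises(UndefinedMetric):
        nq.colocalization_ratio(z, z, 10, 10)


# ---------------------------------------------------------------------------
# line profile


def test_line_profile_constant_gradient_and_colocalized():
    const = make_image(np.full((50, 50), 9.0), pixel_size=0.5)
    prof = nq.line_profile(const, (10, 5), (10, 45), n_samples=41)
    assert np.allclose(prof["test"], 9.0)
    assert prof["distance_um"].iloc[-1] == pytest.approx(40 * 0.5)
    # linear gradient reproduced exactly at pixel centres
    grad = make_image(np.tile(np.arange(50.0), (50, 1)))
    p = nq.line_profile(grad, (25, 0), (25, 49), n_samples=50)
    assert np.allclose(p["test"], np.arange(50.0))
    # perfectly colocalized channels: r ~ 1
    rng = np.random.default_rng(2)
    px = rng.uniform(0, 100, (50, 50))
    a, b = make_image(px, name="a"), make_image(2 * px, name="b")
    p2 = nq.line_profile([a, b], (5, 5), (45, 45), n_samples=60)
    r = np.corrcoef(p2["a"], p2["b"])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)


def test_line_profile_validates_endpoints():
    img = make_image(np.zeros((20, 20)))
    with pytest.raises(ValueError, match="coincide"):
        nq.line_profile(img, (5, 5), (5, 5))
    with pytest.raises(ValueError, match="outside"):
        nq.line_profile(img, (5, 5), (25, 5))


# ---------------------------------------------------------------------------
# normalization


def test_normalize_to_control_hand_example():
    tab = pd.DataFrame(
        {
            "experiment_id": ["e1", "e1", "e2", "e2"],
            "group": ["ctrl", "mut", "ctrl", "mut"],
            "value": [10.0, 20.0, 20.0, 20.0],
        }
    )
    out = nq.normalize_to_control(tab, "ctrl")
    assert out.loc[1, "value"] == 2.0
    assert out.loc[3, "value"] == 1.0
    # control mean is 1 in every experiment afterwards
    ctrl = out[out.group == "ctrl"].groupby("experiment_id")["value"].mean()
    assert np.allclose(ctrl, 1.0)


def test_normalize_to_control_missing_control_errors():
    tab = pd.DataFrame(
        {"experiment_id": ["e1"], "group": ["mut"], "value": [1.0]}
    )
    with pytest.raises(ValueError, match="e1"):
        nq.normalize_to_control(tab, "ctrl")
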