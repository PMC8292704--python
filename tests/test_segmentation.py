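"""Thresholding, labeling, target selection and centroid tracking,
each checked against an independent brute-force oracle where one exists."""

import numpy as np
import pytest

from traj4d import (
    AcquisitionSpec,
    ImageGrid,
    MarkerSpec,
    MotionSpec,
    PhantomSpec,
    PhaseVolumeSet,
    render_volume,
    simulate_cbct,
)
from traj4d.segmentation import (
    LabeledComponent,
    SegmentationConfig,
    binarize_otsu,
    label_components,
    morph_open,
    phase_centroids,
    select_target,
)

GRID1 = ImageGrid((1.0, 1.0, 1.0), (0.0, 0.0, 0.0), (16, 16, 16))


def otsu_variance_curve(values, nbins=256):
    """Between-class variance of every candidate split of the nbins
    histogram — the definitional (brute-force) Otsu objective. Candidate
    k thresholds at bin center k, i.e. classes are bins [0..k] / [k+1..].
    Returns (candidate thresholds, variances)."""
    hist, edges = np.histogram(values, bins=nbins)
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    variances = np.full(nbins - 1, -np.inf)
    for k in range(nbins - 1):
        w0, w1 = p[: k + 1].sum(), p[k + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (p[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (p[k + 1 :] * centers[k + 1 :]).sum() / w1
        variances[k] = w0 * w1 * (mu0 - mu1) ** 2
    return centers[:-1], variances


def flood_fill_labels(mask):
    """26-connectivity flood fill, the oracle for component labeling."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            i, j, k = stack.pop()
            for a, b, c in offsets:
                q = (i + a, j + b, k + c)
                if all(0 <= q[d] < mask.shape[d] for d in range(3)):
                    if mask[q] and not labels[q]:
                        labels[q] = nxt
                        stack.append(q)
    return labels


class TestOtsu:
    def two_class_set(self):
        rng = np.random.default_rng(0)
        vols = []
        for _ in range(3):
            v = np.full((12, 12, 12), -800.0)
            v[4:8, 4:8, 4:8] = 40.0
            vols.append(v + rng.normal(0, 5, v.shape))
        return PhaseVolumeSet(vols, ImageGrid((1, 1, 1), (0, 0, 0), (12, 12, 12)))

    def test_two_delta_histogram_separates_classes(self):
        v = np.full((10, 10, 10), -800.0)
        v[3:6, 3:6, 3:6] = 40.0
        pvs = PhaseVolumeSet([v], ImageGrid((1, 1, 1), (0, 0, 0), (10, 10, 10)))
        masks, th = binarize_otsu(pvs)
        assert -800.0 < th < 40.0
        np.testing.assert_array_equal(masks[0], v > -400)

    def test_maximizes_between_class_variance(self):
        pvs = self.two_class_set()
        _, th = binarize_otsu(pvs)
        pooled = np.stack(pvs.volumes).ravel()
        cands, variances = otsu_variance_curve(pooled)
        # the returned threshold attains the brute-force maximum
        k = int(np.argmin(np.abs(cands - th)))
        assert variances[k] >= variances.max() * (1 - 1e-12)
        assert abs(cands[k] - th) <= np.ptp(pooled) / 256

    def test_shift_equivariance(self):
        pvs = self.two_class_set()
        masks, th = binarize_otsu(pvs)
        shifted = PhaseVolumeSet(
            [v + 123.0 for v in pvs.volumes], pvs.grid, list(pvs.phase_labels)
        )
        masks2, th2 = binarize_otsu(shifted)
        assert th2 == pytest.approx(th + 123.0, abs=1e-6)
        for m1, m2 in zip(masks, masks2):
            np.testing.assert_array_equal(m1, m2)

    def test_constant_volume_rejected(self):
        pvs = PhaseVolumeSet(
            [np.zeros((5, 5, 5))], ImageGrid((1, 1, 1), (0, 0, 0), (5, 5, 5))
        )
        with pytest.raises(ValueError):
            binarize_otsu(pvs)


class TestMorphOpen:
    def test_isolated_voxel_removed(self):
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        assert not morph_open(m, 1).any()

    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(1)
        m = rng.random((8, 8, 8)) > 0.7
        out = morph_open(m, 0)
        np.testing.assert_array_equal(out, m)

    def test_solid_sphere_nearly_preserved(self):
        grid = ImageGrid((1, 1, 1), (-15.5, -15.5, -15.5), (32, 32, 32))
        p = PhantomSpec(target_diameter=20.0)
        mask = render_volume(p, (0, 0, 0), grid) > -400
        opened = morph_open(mask, 1)
        assert opened.sum() >= 0.85 * mask.sum()
        c0 = np.array(np.nonzero(mask)).mean(axis=1)
        c1 = np.array(np.nonzero(opened)).mean(axis=1)
        assert np.linalg.norm(c1 - c0) < 0.1


class TestLabeling:
    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            mask = rng.random((10, 10, 10)) > 0.75
            comps = label_components(mask, GRID1)
            oracle = flood_fill_labels(mask)
            assert len(comps) == oracle.max()
            # same partition: each labeled component maps to one oracle label
            from skimage.measure import label as sklabel

            ours = sklabel(mask, connectivity=3)
            for c in comps:
                sel = ours == c.label
                assert len(np.unique(oracle[sel])) == 1

    def test_two_spheres_two_components(self):
        grid = ImageGrid((1, 1, 1), (-31.5, -15.5, -15.5), (64, 32, 32))
        p = PhantomSpec(target_diameter=10.0)
        v1 = render_volume(p, (-15, 0, 0), grid)
        v2 = render_volume(p, (15, 0, 0), grid)
        vol = np.maximum(v1, v2)
        comps = label_components(vol > -400, grid)
        assert len(comps) == 2
        centroids = sorted(c.centroid[0] for c in comps)
        assert centroids[0] == pytest.approx(-15, abs=0.05)
        assert centroids[1] == pytest.approx(15, abs=0.05)

    def test_full_foreground_single_component_centered(self):
        mask = np.ones((5, 7, 9), bool)
        grid = ImageGrid((1, 1, 1), (0, 0, 0), (5, 7, 9))
        comps = label_components(mask, grid)
        assert len(comps) == 1
        np.testing.assert_allclose(comps[0].centroid, [2, 3, 4])

    def test_empty_mask_empty_list(self):
        assert label_components(np.zeros((4, 4, 4), bool), GRID1) == []


class TestSelectTarget:
    def comp(self, label, centroid, count=10):
        c = np.asarray(centroid, float)
        return LabeledComponent(label, count, c, np.stack([c, c], axis=1))

    def test_nearest_wins(self):
        picked = select_target(
            [self.comp(1, (1, 0, 0)), self.comp(2, (5, 0, 0))], (0, 0, 0)
        )
        assert picked.label == 1

    def test_tie_broken_by_size(self):
        picked = select_target(
            [self.comp(1, (2, 0, 0), 10), self.comp(2, (-2, 0, 0), 500)], (0, 0, 0)
        )
        assert picked.label == 2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_target([], (0, 0, 0))

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            comps = [
                self.comp(i + 1, rng.uniform(-20, 20, 3), int(rng.integers(1, 100)))
                for i in range(rng.integers(2, 8))
            ]
            seed = rng.uniform(-20, 20, 3)
            picked = select_target(comps, seed)
            dists = [np.linalg.norm(c.centroid - seed) for c in comps]
            assert np.linalg.norm(picked.centroid - seed) == min(dists)


class TestPhaseCentroids:
    def test_tracks_simulated_cbct_ground_truth(self, cbct_sims):
        pvs, truth = cbct_sims[14.0]
        traj = phase_centroids(pvs, seed=truth.center)
        err = np.abs(traj.centroids - truth.centroids)
        assert err[:, 0].max() <= 0.1  # SI
        assert err[:, 1:].max() <= 0.05  # AP / LR

    def test_static_target_constant_centroids(self):
        m = MotionSpec(kind="sine", excursion=(0, 0, 0), cycle_time=5.0)
        a = AcquisitionSpec(modality="CBCT4D", scan_duration=60, n_frames=240, noise_sd=0.0)
        pvs, truth = simulate_cbct(PhantomSpec(), m, a)
        traj = phase_centroids(pvs, seed=truth.center)
        assert np.ptp(traj.centroids, axis=0).max() < 1e-9

    def test_marker_never_selected(self):
        grid = ImageGrid((1.0, 1.0, 1.0), (-63.5, -23.5, -23.5), (128, 48, 48))
        p = PhantomSpec(center=(10.0, 0.0, 0.0), marker=MarkerSpec(offset=(-60.0, 0, 0)))
        m = MotionSpec(kind="sine", excursion=(10, 0, 0), cycle_time=5.0)
        a = AcquisitionSpec(
            modality="CBCT4D", grid=grid, scan_duration=60, n_frames=240, noise_sd=0.0
        )
        pvs, truth = simulate_cbct(p, m, a)
        traj = phase_centroids(pvs, seed=(10.0, 0.0, 0.0))
        # marker sits around SI -50; target tracks near SI +10
        assert np.all(traj.centroids[:, 0] > -20)
        assert np.abs(traj.centroids[:, 0] - 10 - truth.displacements[:, 0]).max() < 0.5

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        vols = []
        for k in range(10):
            v = np.full((16, 16, 16), -800.0)
            v[4 + k % 2 : 8 + k % 2, 4:8, 4:8] = 40.0
            vols.append(v)
        grid = ImageGrid((1, 1, 1), (0, 0, 0), (16, 16, 16))
        pvs = PhaseVolumeSet([v.copy() for v in vols], grid)
        traj = phase_centroids(pvs, seed=(6, 6, 6))
        shifted = PhaseVolumeSet([np.roll(v, 3, axis=2) for v in vols], grid)
        traj2 = phase_centroids(shifted, seed=(6, 6, 9))
        np.testing.assert_allclose(
            traj2.centroids - traj.centroids, [[0.0, 0.0, 3.0]] * 10, atol=1e-9
        )

    def test_kept_masks_cover_only_the_target(self):
        v = np.full((12, 12, 12), -800.0)
        v[3:7, 3:7, 3:7] = 40.0
        noise_obj = v.copy()
        noise_obj[10, 10, 10] = 40.0  # clutter component
        grid = ImageGrid((1, 1, 1), (0, 0, 0), (12, 12, 12))
        pvs = PhaseVolumeSet([v, noise_obj], grid, [0, 1])
        traj = phase_centroids(
            pvs, seed=(4.5, 4.5, 4.5), cfg=SegmentationConfig(keep_masks=True)
        )
        assert len(traj.masks) == 2
        for mask, c in zip(traj.masks, traj.centroids):
            got = np.array(np.nonzero(mask)).mean(axis=1)
            np.testing.assert_allclose(grid.index_to_mm(got), c, atol=1e-9)
        assert not traj.masks[1][10, 10, 10]

    def test_failure_names_phase(self):
        # phase 0 fine, phase 1 has no foreground after global threshold
        v0 = np.full((8, 8, 8), -800.0)
        v0[2:5, 2:5, 2:5] = 40.0
        v1 = np.full((8, 8, 8), -800.0)
        grid = ImageGrid((1, 1, 1), (0, 0, 0), (8, 8, 8))
        pvs = PhaseVolumeSet([v0, v1], grid, [0, 1])
        with pytest.raises(ValueError, match="phase 1"):
            phase_centroids(pvs, seed=(3, 3, 3))
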