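"""Drift correction, segmentation, and per-cell atom-fraction quantification
on synthetic ion-image stacks."""

import numpy as np
import pytest

from sipquant import (
    CellROI,
    IonImageStack,
    SegmentationParams,
    align_and_accumulate,
    atom_fraction,
    labeled_fraction,
    measure_roi_counts,
    segment_cells,
    simulate_nanosims,
)
from sipquant.nanosims import CN12, CN13


def small_field(**kwargs):
    defaults = dict(
        n_cells=12, labeled_fraction=0.25, shape=(192, 192), scans=8, seed=42
    )
    defaults.update(kwargs)
    return simulate_nanosims(**defaults)


class TestAlignAndAccumulate:
    def test_single_scan_identity(self):
        stack, _, _ = small_field(scans=1)
        planes, trace = align_and_accumulate(stack)
        assert trace == [(0, 0)]
        assert np.array_equal(planes[CN12], stack.counts[0, 0])
        assert np.array_equal(planes[CN13], stack.counts[0, 1])

    def test_planted_shifts_recovered_exactly(self):
        stack, _, offsets = small_field(scans=10, drift_px=3, seed=7)
        _, trace = align_and_accumulate(stack)
        assert trace == offsets

    @pytest.mark.parametrize("seed", [7, 8, 21])
    def test_correction_improves_cell_contrast(self, seed):
        # same field with planted drift, accumulated naively vs corrected;
        # peak cell contrast (smoothed max over median) must improve
        from skimage.filters import gaussian

        stack, _, _ = small_field(
            scans=12, drift_px=8, cell_radius_px=3, seed=seed
        )
        aligned, _ = align_and_accumulate(stack)
        raw = stack.counts[:, 0].sum(axis=0)  # naive accumulation

        def contrast(img):
            sm = gaussian(img.astype(float), 2.0, preserve_range=True)
            return sm.max() / max(np.median(sm), 1e-9)

        assert contrast(aligned[CN12]) > contrast(raw)

    def test_zero_count_scan_excluded_with_warning(self):
        stack, _, _ = small_field(scans=3)
        counts = stack.counts.copy()
        counts[1] = 0
        broken = IonImageStack(counts=counts, species=stack.species)
        with pytest.warns(UserWarning, match="zero total counts"):
            planes, trace = align_and_accumulate(broken)
        assert planes[CN12].sum() == counts[[0, 2], 0].sum()

    def test_alignment_never_creates_counts(self):
        stack, _, _ = small_field(scans=10, drift_px=3, seed=3)
        planes, _ = align_and_accumulate(stack)
        for i, name in enumerate(stack.species):
            assert planes[name].sum() <= stack.counts[:, i].sum()


class TestSegmentation:
    def test_blank_plane_yields_no_rois(self, rng):
        plane = rng.poisson(0.1, size=(128, 128))
        assert segment_cells(plane) == []

    def test_planted_disks_recovered_with_centroids(self):
        stack, truth, _ = simulate_nanosims(
            n_cells=20, labeled_fraction=0.0, shape=(256, 256), scans=8, seed=5
        )
        planes, _ = align_and_accumulate(stack)
        rois = segment_cells(planes[CN12])
        assert len(rois) == 20
        centers = {(r, c) for r, c in truth[["row", "col"]].itertuples(index=False)}
        for roi in rois:
            cy, cx = roi.centroid
            assert any(abs(cy - r) <= 1 and abs(cx - c) <= 1 for r, c in centers)

    def test_touching_disks_split_by_watershed(self):
        plane = np.zeros((64, 64))
        yy, xx = np.mgrid[:64, :64]
        r = 6
        for cy, cx in [(32, 26), (32, 26 + 2 * r - 1)]:  # overlap by 1 px
            plane[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] += 50.0
        rois = segment_cells(
            plane, SegmentationParams(split_touching=True, watershed_min_distance=4)
        )
        assert len(rois) == 2

    def test_stable_under_background_noise(self, rng):
        stack, _, _ = small_field(seed=21)
        planes, _ = align_and_accumulate(stack)
        base = segment_cells(planes[CN12])
        cell_signal = planes[CN12].max()
        noisy = planes[CN12] + rng.poisson(0.1 * cell_signal / 10, planes[CN12].shape)
        assert len(segment_cells(noisy)) == len(base)

    def test_roi_counts_within_plane_totals(self):
        stack, _, _ = small_field()
        planes, _ = align_and_accumulate(stack)
        rois = measure_roi_counts(segment_cells(planes[CN12]), planes)
        for name in (CN12, CN13):
            assert sum(r.counts[name] for r in rois) <= planes[name].sum()


class TestAtomFraction:
    def roi_with(self, n13, n12):
        return CellROI(
            label=1, rows=np.array([0]), cols=np.array([0]),
            counts={CN13: n13, CN12: n12},
        )

    def test_zero_heavy_counts(self):
        res = atom_fraction(self.roi_with(0, 1000))
        assert res.k_a == 0.0 and not res.enriched

    def test_natural_like_cell_not_enriched(self):
        res = atom_fraction(self.roi_with(110, 9890))
        assert res.k_a == pytest.approx(0.011)
        assert not res.enriched  # below the 2 atom% display threshold

    def test_zero_total_counts_flagged_invalid(self):
        res = atom_fraction(self.roi_with(0, 0))
        assert not res.valid

    def test_planted_cells_within_three_poisson_se(self):
        stack, truth, _ = simulate_nanosims(
            n_cells=15, labeled_fraction=0.4, shape=(256, 256), scans=25, seed=9
        )
        planes, _ = align_and_accumulate(stack)
        rois = measure_roi_counts(segment_cells(planes[CN12]), planes)
        assert len(rois) == 15
        truth_af = {
            (r, c): af
            for r, c, af in truth[["row", "col", "atom_fraction"]].itertuples(index=False)
        }
        for roi in rois:
            res = atom_fraction(roi)
            # default rates give ~1e4 counts per cell; the inner-margin ROI
            # captures the interior share of them
            assert res.total_cn >= 4000
            cy, cx = roi.centroid
            af = next(
                v for (r, c), v in truth_af.items()
                if abs(r - cy) <= 2 and abs(c - cx) <= 2
            )
            assert abs(res.k_a - af) <= 3 * res.poisson_se
            assert res.enriched == (af > 0.02)

    @pytest.mark.parametrize("af", [0.011, 0.02, 0.05, 0.10])
    def test_planted_atom_fraction_bias_small(self, af, rng):
        # count-level recovery: Poisson split of >= 1e4 counts per cell
        errs = []
        for _ in range(50):
            n13 = rng.poisson(12_000 * af)
            n12 = rng.poisson(12_000 * (1 - af))
            errs.append(atom_fraction(self.roi_with(n13, n12)).k_a - af)
        assert abs(np.mean(errs)) < 0.002

    def test_ka_invariant_under_uniform_scaling(self):
        res1 = atom_fraction(self.roi_with(500, 9500))
        res2 = atom_fraction(self.roi_with(5000, 95000))
        assert res1.k_a == pytest.approx(res2.k_a)


class TestLabeledFraction:
    def result(self, enriched, valid=True):
        return atom_fraction(
            CellROI(
                label=1, rows=np.array([0]), cols=np.array([0]),
                counts={CN13: 3000 if enriched else 10, CN12: 7000 if enriched else 9990}
                if valid
                else {},
            )
        )

    def test_all_enriched(self):
        frac, _ = labeled_fraction([self.result(True)] * 5)
        assert frac == 1.0

    def test_none_enriched(self):
        frac, _ = labeled_fraction([self.result(False)] * 8)
        assert frac == 0.0

    def test_invalid_results_excluded(self):
        results = [self.result(True)] * 3 + [self.result(False)] + [self.result(True, valid=False)]
        frac, _ = labeled_fraction(results)
        assert frac == pytest.approx(0.75)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            labeled_fraction([])

    def test_bootstrap_ci_seeded_and_contains_point(self):
        results = [self.result(True)] * 3 + [self.result(False)] * 17
        frac, (lo, hi) = labeled_fraction(results, seed=1)
        frac2, (lo2, hi2) = labeled_fraction(results, seed=1)
        assert (lo, hi) == (lo2, hi2)
        assert lo <= frac <= hi
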