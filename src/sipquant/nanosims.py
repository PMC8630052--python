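"""NanoSIMS ion-image processing: drift-corrected scan accumulation, cell
segmentation, and per-cell ¹³C atom-fraction quantification.

A measurement is a stack of raster scans over the same field of view, one
integer count plane per secondary-ion species and scan. Successive scans
drift laterally by a few pixels; scans are registered against a running
reference by cross-correlation of the ¹²C¹⁴N⁻ plane (the cell-structure
channel), the same integer shift is applied to every species, and the
aligned planes are summed. Cells are segmented on the accumulated ¹²C¹⁴N⁻
plane and eroded by one pixel, an automated stand-in for drawing each region
of interest along the cell's inner margin. The per-cell ¹³C atom fraction is

    K_A = N(¹³C¹⁴N⁻) / (N(¹³C¹⁴N⁻) + N(¹²C¹⁴N⁻))

over the accumulated raw ion counts of the region, with a binomial
(counting-statistics) standard error. Cells with K_A above 2 atom% are
called ¹³C-enriched by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk, erosion
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .constants import NATURAL_13C

__all__ = [
    "IonImageStack",
    "CellROI",
    "CellIsotopeResult",
    "SegmentationParams",
    "align_and_accumulate",
    "segment_cells",
    "measure_roi_counts",
    "atom_fraction",
    "labeled_fraction",
]

CN12 = "12C14N"
CN13 = "13C14N"

#: default enrichment threshold on K_A (Fig-2-style 2 atom% display gate)
ENRICHMENT_THRESHOLD = 0.02
#: default field geometry: 25 x 25 um at 512 x 512 px
DEFAULT_PIXEL_SIZE_UM = 25.0 / 512


@dataclass
class IonImageStack:
    """Multi-scan, multi-species ion-count images.

    ``counts`` has shape (scans, species, rows, cols) and holds non-negative
    integers; ``species`` labels axis 1. Isotope work requires both
    ``"12C14N"`` and ``"13C14N"`` channels; other species are carried
    through untouched.
    """

    counts: np.ndarray
    species: tuple[str, ...]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise ValueError("counts must be 4-D (scan, species, row, col)")
        if self.counts.shape[0] < 1:
            raise ValueError("at least one scan required")
        if self.counts.shape[1] != len(self.species):
            raise ValueError("species labels must match counts axis 1")
        if np.any(self.counts < 0):
            raise ValueError("ion counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("ion counts must be integral")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_scans(self) -> int:
        return self.counts.shape[0]

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"species {name!r} not in stack {self.species}") from None

    def require_cn_pair(self) -> tuple[int, int]:
        return self.species_index(CN12), self.species_index(CN13)


@dataclass
class CellROI:
    """One segmented cell: its pixel set and accumulated per-species counts."""

    label: int
    rows: np.ndarray
    cols: np.ndarray
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def area_px(self) -> int:
        return int(self.rows.size)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())


@dataclass(frozen=True)
class CellIsotopeResult:
    """Per-cell isotope quantification.

    ``k_a`` is the ¹³C atom fraction of the cell's CN⁻ secondary ions,
    ``poisson_se`` its counting-statistics standard error, and ``enriched``
    the threshold call. ``valid`` is False when the region carried no CN
    counts at all.
    """

    label: int
    counts_13CN: int
    counts_12CN: int
    k_a: float
    poisson_se: float
    enriched: bool
    valid: bool = True

    @property
    def total_cn(self) -> int:
        return self.counts_13CN + self.counts_12CN


@dataclass
class SegmentationParams:
    """Knobs for automated cell segmentation.

    ``smooth_sigma`` — Gaussian pre-smoothing in px; ``threshold`` —
    absolute count threshold (None → Otsu on the smoothed plane);
    ``min_area_px`` — discard smaller regions; ``erode_px`` — inner-margin
    erosion radius; ``split_touching`` — watershed split of merged cells;
    ``watershed_min_distance`` — minimum peak separation in px.
    """

    smooth_sigma: float = 1.0
    threshold: float | None = None
    min_area_px: int = 5
    erode_px: int = 1
    split_touching: bool = False
    watershed_min_distance: int = 5


def _integer_shift(plane: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift a 2-D plane by whole pixels, filling vacated pixels with 0."""
    out = np.zeros_like(plane)
    src_r = slice(max(0, -dy), plane.shape[0] - max(0, dy))
    src_c = slice(max(0, -dx), plane.shape[1] - max(0, dx))
    dst_r = slice(max(0, dy), plane.shape[0] - max(0, -dy))
    dst_c = slice(max(0, dx), plane.shape[1] - max(0, -dx))
    out[dst_r, dst_c] = plane[src_r, src_c]
    return out


def align_and_accumulate(
    stack: IonImageStack,
    reference_species: str = CN12,
    max_shift_px: int | None = None,
) -> tuple[dict[str, np.ndarray], list[tuple[int, int]]]:
    """Register scans to a running reference and sum them per species.

    Per-scan integer-pixel offsets are estimated by cross-correlating each
    scan's reference-species plane (¹²C¹⁴N⁻ by default) against the running
    accumulated reference; the correction is applied identically to all
    species. Returns the accumulated planes, cropped symmetrically so that
    only pixels covered by every scan survive, and the drift trace: the
    estimated (row, col) offset of each scan relative to scan 0. Scans with
    zero total counts are excluded with a warning (their trace entry repeats
    the previous offset).
    """
    ref_idx = stack.species_index(reference_species)
    n_scans, n_species = stack.counts.shape[:2]
    acc = np.zeros(stack.counts.shape[1:], dtype=np.int64)
    ref_acc = np.zeros(stack.counts.shape[2:], dtype=float)
    trace: list[tuple[int, int]] = []
    last = (0, 0)
    for s in range(n_scans):
        planes = stack.counts[s]
        if planes.sum() == 0:
            warnings.warn(f"scan {s} has zero total counts; excluded")
            trace.append(last)
            continue
        if ref_acc.sum() == 0:
            offset = (0, 0)
        else:
            shift, _, _ = phase_cross_correlation(
                ref_acc, planes[ref_idx].astype(float), normalization=None
            )
            dy, dx = int(round(shift[0])), int(round(shift[1]))
            # phase correlation returns the shift that registers the moving
            # plane onto the reference; the scan's offset is its negative
            offset = (-dy, -dx)
            if max_shift_px is not None:
                offset = (
                    int(np.clip(offset[0], -max_shift_px, max_shift_px)),
                    int(np.clip(offset[1], -max_shift_px, max_shift_px)),
                )
        trace.append(offset)
        last = offset
        dy, dx = -offset[0], -offset[1]
        for c in range(n_species):
            acc[c] += _integer_shift(planes[c], dy, dx)
        ref_acc += _integer_shift(planes[ref_idx], dy, dx).astype(float)
    my = max((abs(t[0]) for t in trace), default=0)
    mx = max((abs(t[1]) for t in trace), default=0)
    h, w = acc.shape[1:]
    cropped = acc[:, my : h - my or None, mx : w - mx or None]
    planes_out = {name: cropped[i] for i, name in enumerate(stack.species)}
    return planes_out, trace


def segment_cells(
    cn_plane: np.ndarray,
    params: SegmentationParams | None = None,
) -> list[CellROI]:
    """Segment cells on an accumulated ¹²C¹⁴N⁻ plane.

    Otsu (or fixed) thresholding of the smoothed plane, optional watershed
    splitting of touching cells, one-pixel inward erosion (the inner-margin
    convention), connected-component labeling, and a minimum-area filter.
    Returns ROIs without counts; attach them with ``measure_roi_counts``.
    """
    params = params or SegmentationParams()
    plane = np.asarray(cn_plane, dtype=float)
    if plane.size == 0:
        return []
    smooth = gaussian(plane, sigma=params.smooth_sigma, preserve_range=True)
    if params.threshold is not None:
        thr = params.threshold
    else:
        if smooth.max() <= smooth.min():
            return []
        thr = threshold_otsu(smooth)
        # a structureless (pure-background) plane has its Otsu threshold
        # sitting inside the noise, close to the plane mean; real cells are
        # far brighter than background
        if thr <= 2.0 * smooth.mean():
            return []
    mask = smooth > thr
    if not mask.any():
        return []
    if params.split_touching:
        distance = ndimage.distance_transform_edt(mask)
        from skimage.feature import peak_local_max

        peaks = peak_local_max(
            distance,
            min_distance=params.watershed_min_distance,
            labels=mask,
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        labels = watershed(-distance, markers, mask=mask)
    else:
        labels = sk_label(mask)
    if params.erode_px > 0:
        eroded = erosion(mask, disk(params.erode_px))
        labels = labels * eroded
    rois = []
    for region in regionprops(labels):
        if region.area < params.min_area_px:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        rois.append(CellROI(label=int(region.label), rows=rr, cols=cc))
    # relabel sequentially for deterministic downstream tables
    for new_label, roi in enumerate(
        sorted(rois, key=lambda r: (r.centroid[0], r.centroid[1])), start=1
    ):
        roi.label = new_label
    return sorted(rois, key=lambda r: r.label)


def measure_roi_counts(
    rois: list[CellROI], planes: dict[str, np.ndarray]
) -> list[CellROI]:
    """Accumulate per-species ion counts over each ROI's pixels, in place."""
    for roi in rois:
        roi.counts = {
            name: int(plane[roi.rows, roi.cols].sum())
            for name, plane in planes.items()
        }
    return rois


def atom_fraction(
    roi: CellROI,
    threshold: float = ENRICHMENT_THRESHOLD,
    threshold_on_excess: bool = False,
) -> CellIsotopeResult:
    """¹³C atom fraction of one cell from its accumulated CN⁻ counts.

    K_A = N13 / (N13 + N12); the standard error is the binomial-proportion
    error sqrt(K_A(1−K_A)/N) of the total CN count. The enrichment call
    compares K_A to ``threshold`` (2 atom% by default); with
    ``threshold_on_excess`` the comparison is against natural abundance +
    threshold instead. Regions with zero CN counts yield an invalid result
    that summaries must exclude.
    """
    n13 = roi.counts.get(CN13, 0)
    n12 = roi.counts.get(CN12, 0)
    total = n13 + n12
    if total == 0:
        return CellIsotopeResult(
            label=roi.label, counts_13CN=0, counts_12CN=0,
            k_a=float("nan"), poisson_se=float("nan"),
            enriched=False, valid=False,
        )
    k_a = n13 / total
    se = float(np.sqrt(max(k_a * (1 - k_a), 1.0 / total) / total))
    cut = NATURAL_13C + threshold if threshold_on_excess else threshold
    return CellIsotopeResult(
        label=roi.label, counts_13CN=int(n13), counts_12CN=int(n12),
        k_a=float(k_a), poisson_se=se, enriched=bool(k_a > cut),
    )


def labeled_fraction(
    results: list[CellIsotopeResult],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Fraction of valid cells called enriched, with a seeded bootstrap
    95% confidence interval."""
    flags = np.array([r.enriched for r in results if r.valid], dtype=float)
    if flags.size == 0:
        raise ValueError("no valid cell results")
    frac = float(flags.mean())
    rng = np.random.default_rng(seed)
    boots = rng.choice(flags, size=(n_boot, flags.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return frac, (float(lo), float(hi))
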