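"""Quantify single-cell ¹³C assimilation in a simulated nanoSIMS field.

Builds a 512×512 px field (25×25 μm) with 100 cells, 15 of them labeled at
10 atom% ¹³C, accumulated over 25 drifting scans; then runs the full chain:
drift correction, segmentation, per-cell atom fraction, biovolume, and
carbon assimilation rate at the study parameters (ρ_C = 93.4 fg/μm³,
t = 96 h).
"""

import numpy as np

from sipquant import (
    RateParams,
    align_and_accumulate,
    assimilated_fraction,
    assimilation_rate,
    atom_fraction,
    cell_volume,
    labeled_fraction,
    measure_roi_counts,
    segment_cells,
    simulate_nanosims,
)

stack, truth, planted_drift = simulate_nanosims(
    n_cells=100, labeled_fraction=0.15, atom_fraction_labeled=0.10,
    scans=25, drift_px=3, seed=11,
)
planes, drift = align_and_accumulate(stack)
print(f"scans accumulated: {stack.n_scans}; drift recovered exactly: {drift == planted_drift}")

rois = measure_roi_counts(segment_cells(planes["12C14N"]), planes)
results = [atom_fraction(roi) for roi in rois]
frac, (lo, hi) = labeled_fraction(results, seed=11)
print(f"cells found: {len(rois)} (planted 100)")
print(f"labeled-cell fraction: {frac:.2f}  (95% CI {lo:.2f}-{hi:.2f}; planted 0.15)")

params = RateParams(k_s=0.10, t_h=96.0)
rates = []
for roi, res in zip(rois, results):
    if not res.enriched:
        continue
    geom = cell_volume(roi, stack.pixel_size_um)
    x = assimilated_fraction(min(res.k_a, params.k_s), params)
    rates.append(assimilation_rate(x, geom, params).f_c)
print(f"enriched cells: {len(rates)}; K_A of brightest: {max(r.k_a for r in results):.3f}")
print(
    f"assimilation rates F_c: median {np.median(rates):.3f}, "
    f"up to {max(rates):.3f} fg cell^-1 h^-1"
)
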