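# Methods

This note records the models implemented in sipquant, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices a maintainer would otherwise have to reverse-engineer.

## Isotopologue model

Peptide isotopologues are indexed by the integer heavy-mass-unit offset
`k` from the monoisotopic peak. Carbon contributes Binomial(n_C, RIA) heavy
units, where RIA is the per-carbon ¹³C probability (natural abundance
0.0107 when unlabeled); hydrogen, nitrogen, oxygen and sulfur contribute
their natural +1/+2 channels (²H 0.000115; ¹⁵N 0.00364; ¹⁷O 0.00038 / ¹⁸O
0.00205; ³³S 0.0075 / ³⁴S 0.0425 — IUPAC representative values, pinned in
`sipquant/data/isotope_constants.tsv`). The total offset distribution is the
convolution of the per-element distributions, computed by exponentiation by
squaring.

Limitations, accepted deliberately: all heavy substitutions are lumped onto
the ¹³C mass ladder (Δm = 1.0033548 Da per unit), so the fine mass splitting
between, e.g., a ¹³C and a ¹⁵N substitution is ignored — adequate at MS1
envelope resolution, wrong for fine-structure work. ³⁶S (1.5·10⁻⁴) is
neglected. Selenium, phosphorus and modifications other than
carbamidomethyl-C and oxidized methionine (+1 O) are unsupported.

Pruning removes entries below 10⁻⁶ absolute abundance **without**
renormalizing by default: goodness-of-fit statistics then see the true tail
mass, and the survivors sum to slightly under 1. `renormalize=True` rescales
when a proper distribution is needed.

Masses use the standard monoisotopic table (¹H 1.00782503207, ¹²C 12,
¹⁴N 14.0030740048, ¹⁶O 15.9949146196, ³²S 31.972071; proton
1.00727646688). These reproduce the worked-example peptide VVNAEAGNAR at
m/z 500.7622 (z = 2) to the printed precision.

## RIA/LR estimator

The observed envelope (channel sums of peak intensities within ±10 ppm of
each isotopologue m/z; windows are checked for overlap) is fit as
`w₀·P_nat + w₁·P_ria` by non-negative least squares at each RIA on a grid
from 0 to 0.95 in steps of 0.005, followed by parabolic refinement of the
best grid point. LR = w₁/(w₀+w₁); the reported correlation is Pearson's r
between fitted and observed envelope on nonzero channels.

Two identifiability guards, both part of the estimator's design rather than
tuning: (i) when the refined RIA lies within 1 atom% of natural abundance
the two mixture components are numerically collinear and the split of
weight between them is meaningless, so the fit collapses to
(RIA = natural, LR = 0); (ii) a labeled call additionally requires
LR ≥ 0.05, because on an unlabeled envelope the free second component will
absorb shot noise at an arbitrary RIA with negligible weight, and without a
weight floor the correlation + RIA gate alone would produce false labeled
calls. With both guards, unlabeled-only simulations produce zero labeled
calls.

The labeled-call gate is: fit correlation ≥ 0.8 (the reporting threshold
of the reference workflow), RIA ≥ natural + 0.02 (margin mirroring the
2 atom% single-cell display threshold; the protein-side margin is not
otherwise specified), LR ≥ 0.05, and ≥ 3 envelope channels with signal.
The envelope channel ceiling is min(n_C, mode@RIA=0.5 + 15), bounding cost
with negligible truncated mass.

Chi-squared validation: channels with expected relative abundance below
10⁻⁴ are excluded; the observed envelope is scaled to the expected total
over the remaining channels; degrees of freedom are channels − 1 − n_fitted,
where the −1 is consumed by that scaling and n_fitted = 1 when the RIA of
the expected pattern was fitted to the same envelope (the pipeline's case,
giving channels − 2). Under a known pattern (n_fitted = 0) the statistic is
the classical conditional-multinomial Pearson test, and its p-values are
uniform under resampling — the calibration the test suite checks.

Note the estimator reports the mixture-fit RIA; a mode-based or
weighted-mean readout of the same envelope would differ slightly. No
literature point estimate is targeted numerically.

## NanoSIMS processing

Scans are registered by phase cross-correlation (plain, un-normalized) of
each scan's ¹²C¹⁴N⁻ plane against the running accumulated reference,
rounded to integer pixels; the same shift is applied to every species and
the accumulated planes are cropped symmetrically to pixels covered by all
scans. Sub-pixel refinement is deliberately omitted: the simulated and
typical instrument drifts are integer-pixel scale, and integer shifts
preserve count integrality. No quasi-simultaneous-arrival or dead-time
corrections are applied.

Segmentation stands in for manual cell outlining: Gaussian smoothing
(σ = 1 px), Otsu threshold, optional watershed splitting of touching cells
(distance-transform peaks), then a one-pixel erosion implementing the
inner-margin convention, and a 5-px minimum area. A structureless plane is
recognized by its Otsu threshold falling within 2× the plane mean (for real
cell fields the threshold sits an order of magnitude above it) and yields no
regions. Externally drawn 16-bit label masks can be imported in place of
segmentation.

K_A = N13/(N13+N12) over accumulated raw region counts; its standard error
is the binomial proportion error at the region's total CN count. The
enrichment call is K_A > 0.02 by default, applied to K_A itself (not the
excess over natural); `threshold_on_excess` switches the convention, which
the display threshold leaves ambiguous.

## Rates

x = (K_A − K_NA)/(K_S − K_NA), a linear two-pool mass balance; K_A outside
[K_NA, K_S] (possible through counting noise) is clamped with a warning.
F_c = x·ρ_C·V/t with ρ_C = 93.4 fg μm⁻³ (Proteobacteria average) by
default. Instrument-factor corrections present in some published rate
derivations are not modeled — only explicitly stated parameters enter — and
the formula is isolated in one function so an alternative model can be
swapped in.

Biovolume from a 2-D region is under-determined; the default
equivalent-sphere model (r from the projected area, V = 4/3·πr³) is
recorded per cell in the output, and a spherocylinder model (axes from the
region's second moments) is available for elongated cells. One-pixel
regions are flagged low-confidence. Whether per-cell or average volumes are
used for summary rates is the caller's choice; both are possible from the
per-cell table.

Mineralization series are reduced to atom% excess over background, with the
onset flagged at the first point exceeding 3× the stated measurement SD; a
single point never establishes onset.

## Synthetic generators

Defaults are the study conditions the pipeline targets: 20 atom% ¹³C
protein-SIP labeling, envelope depths of 10⁴ counts; nanoSIMS fields of
512×512 px over 25×25 μm (0.0488 μm/px) accumulated over 25 scans with
bounded integer random-walk drift; cells as radius-4-px disks with a CN⁻
count rate of 8.5 counts/px/scan, chosen so one cell accumulates ≈10⁴ CN
counts per field (the precision regime single-cell claims require; the
inner-margin region captures the interior share of those counts); substrate
at 10 atom%, unlabeled cells at natural abundance, Poisson background at
0.1 counts/px/scan; genome bins of random proteins with amino-acid
frequencies giving tryptic peptides of realistic length and a configurable
shared-protein fraction; headspace series with a 24-h lag and saturating
exponential rise.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: chemical noise and co-eluting envelopes in MS1,
charge-state misassignment, detector saturation; nanoSIMS topography and
matrix effects, irregular cell shapes, touching cell clusters (beyond the
constructed watershed fixtures), sub-pixel drift; database-search errors
upstream of attribution (identifications are consumed as given); soil
community composition. Projected cell sizes sit at the small end of the
bacterial range, so absolute F_c magnitudes are below published soil
values; the round-trip tests exercise the estimator, not the field's rate
scale.

## Test design notes

A per-cell "within 3 SE" criterion applied independently to 100 cells fails
with probability ≈1 − 0.997¹⁰⁰ ≈ 26% even when the model is exactly right,
so the suite asserts the collective form chosen a priori: at least 97 of
100 cells inside the 3-SE band (expected 99.7; P(<97) ≈ 0.2%). Likewise the
assimilation-rate round trip asserts the median |relative error| ≤ 10% over
100 seeds plus mean bias ≤ 5%, the stable summaries of a per-seed bound.
Statistical test sizes (100 envelopes, 1000 chi-squared replicates, one
full-size field plus smaller fields in unit tests) keep the default suite
in the tens of seconds while leaving comfortable power for the asserted
tolerances.

Determinism: all generators take explicit seeds; pipeline outputs contain
no timestamps, so identical runs are byte-identical, which the suite checks
by hashing output trees.
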