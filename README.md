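# sipquant

Quantification toolkit for stable-isotope-probing (SIP) studies that trace
¹³C-labeled substrates into microbial biomass. It serves microbial
ecologists who combine protein-SIP metaproteomics with nanoSIMS single-cell
imaging to identify and quantify substrate-degrading populations directly in
environmental samples (e.g., biphenyl degraders in contaminated soils).

## What it computes

**Peptide isotopologue model.** A peptide with elemental composition
C&#8342;H&#8346;N&#8345;O&#8348;S&#8347; and per-carbon ¹³C probability *RIA*
has isotopologue abundances given by the convolution of
Binomial(n_C, RIA) with the natural-abundance +1/+2 channels of H, N, O and
S, indexed by the integer heavy-mass-unit offset *k* from the monoisotopic
peak (m/z spacing 1.0033548/z).

**RIA / LR estimation.** An observed MS1 envelope is fit as the mixture

    E(k) ∝ (1 − LR) · P_nat(k) + LR · P_RIA(k)

by non-negative least squares over a grid of RIA values with parabolic
refinement. *RIA* is the ¹³C content of the labeled molecules, *LR* the
labeled fraction of the peptide population. A peptide is reported
¹³C-labeled when the fit correlation is ≥ 0.8 and RIA exceeds natural
abundance (1.07 atom%) by ≥ 2 atom%; the fit is validated with a Pearson
chi-squared test against the theoretical distribution.

**Single-cell atom fractions and rates.** NanoSIMS scan stacks are
drift-corrected by cross-correlation, accumulated, and segmented; each
cell's ¹³C atom fraction is K_A = N(¹³C¹⁴N⁻)/(N(¹³C¹⁴N⁻)+N(¹²C¹⁴N⁻)), with
cells above 2 atom% called enriched. A linear two-pool mass balance converts
K_A into the assimilated-carbon fraction x = (K_A − K_NA)/(K_S − K_NA) and,
with biovolume V and carbon density ρ_C = 93.4 fg μm⁻³, into the single-cell
assimilation rate F_c = x·ρ_C·V/t (fg cell⁻¹ h⁻¹).

**MAG attribution.** Proteins of each metagenome-assembled genome are
digested in silico (trypsin, 2 missed cleavages); a labeled peptide is
attributed to a bin only when every protein that could produce it lies in
that bin, and proteins count as identified with ≥ 2 unique peptides.

A seeded synthetic-data module generates MS1 spectra, multi-scan ion-image
stacks, protein bins and ¹³CO₂ headspace series with ground truth, so the
entire pipeline runs and is tested without instrument data.

## Worked example

```sh
python examples/peptide_labeling.py
```

```text
peptide composition: C40 H69 N15 O15
monoisotopic m/z (z=2):      500.7622
m/z 8 heavy units up (z=2):  504.7756
fitted RIA:         0.200   (per-carbon 13C fraction; truth 0.200)
fitted LR:          1.000   (labeled population fraction; truth 1.0)
fit correlation:    0.9996 (labeled calls need >= 0.8)
chi-squared p:      0.231   (pattern consistency check)
labeled call:       True
```

The peptide VVNAEAGNAR (a PAH-dioxygenase fragment) at charge 2 sits at
m/z 500.7622; at 20 atom% ¹³C its envelope mode moves ~8 heavy units up to
504.7756, and the mixture fit recovers both the label strength (RIA) and
the labeled population fraction (LR) from a shot-noise-limited spectrum of
10⁴ counts. The other examples cover the nanoSIMS field
(`examples/nanosims_field.py`: 100 cells, labeled fraction recovered as
0.15 with exact drift correction), MAG attribution
(`examples/mag_attribution.py`: planted 6/4/3 unique peptides recovered,
shared peptides set aside), and mineralization onset detection
(`examples/mineralization.py`).

The `sipquant` CLI exposes the same chains for shell use:
`sipquant simulate`, `sipquant protein-sip`, `sipquant nanosims`,
`sipquant attribute`, `sipquant report`; runs are hash-stable for a fixed
seed and configuration.

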