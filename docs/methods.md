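# Methods

## Scope and model

`mnscore` implements an automated micronucleus (MN) scoring assay for
whole-slide images of mouse peripheral blood smears. Micronuclei in
enucleated red blood cells (Howell-Jolly bodies) are retained nuclear
remnants whose frequency rises with genotoxic exposure; the fraction of
MN-positive red cells is therefore usable as a minimally invasive
pharmacodynamic biomarker, e.g. for PARP-inhibitor activity. The assay's
central readouts are percentages within the evaluable red-cell population:

    MN⁺-RBC (%) = 100 · N(MN⁺-RBC) / (N(MN⁻-RBC) + N(MN⁺-RBC))

with the analogous MN⁺-NCE and MN⁺-RET percentages when the brightfield
(May-Grünwald Giemsa, MGG) modality distinguishes mature normochromic
erythrocytes (NCEs) from reticulocytes (RETs). White cells, platelets and
debris never enter a denominator. A sample with fewer than 10,000 evaluable
RBCs fails QC and its frequencies are withheld; the boundary is inclusive
(exactly 10,000 passes).

Because no image data are deposited for this assay class, the package
bundles a smear simulator as a first-class module: every downstream stage
is validated against per-cell ground truth under the assay's reference
population parameters (spontaneous MN⁺ fraction 0.139%, RET fraction 1.46%, treated
inductions up to ~15-fold).

## Smear simulator

Two modalities share one population model. Each cell is drawn independently:
WBC / platelet / RBC class first, then for RBCs a reticulocyte flag,
a degradation morphology (echinocyte or elongated, applied to mature RBCs),
and an MN status (count 2 with configurable probability given MN⁺, else 1).
Diameters are Gaussian (RBC 5.5 ± 0.5 μm, clipped to the 4–7 μm
physiological range; WBC 10 ± 1 μm; platelet 2.2 ± 0.3 μm). Reticulocytes
are scaled ×1.25 and MN⁺ cells ×1.15 (capped at 7.8 μm so no single cell
exceeds the 50 μm² aggregate threshold), reflecting that both populations
run larger than mature MN⁻ cells.

Rendering uses smooth radial profiles plus additive Gaussian noise
(sd 0.02 on a [0, 1] intensity scale):

* **Fluorescence** (two channels): the cell-body channel shows discs with a
  central pallor dip; the DNA channel is dark except for MN foci
  (1.0 ± 0.2 μm discs, clipped to [0.7, 1.8] μm, rendered with a half-pixel
  halo so the smallest foci stay detectable) and WBC nuclei (0.62 of the
  cell diameter). The explicit cell-body channel is a simulator convention:
  how enucleated outlines are visualised on DNA-stain-only slides is not
  part of the assay definition, so the assumption is made explicit and
  configurable.
* **Brightfield MGG** (RGB): cells subtract per-channel optical density
  from a bright background (0.92). NCEs are salmon-pink (blue−red mean
  intensity ≈ −0.12 over the mask), RETs bluish-grey (≈ +0.10), MN foci and
  WBC nuclei purple (dark in green relative to red/blue).

Placement is rejection sampling with a 5 px minimum surface gap; a
configurable fraction of cells is instead placed touching a neighbour at
0.85 of the summed radii to exercise the separation chain. Echinocytes are
rendered as discs with 6–10 cosine spicules (amplitude 0.22 r); elongated
cells as area-preserving ellipses with aspect ratio drawn from U(2.6, 4.0).
Per-field seeds derive from the sample seed via `SeedSequence`, so a whole
sample is reproducible bit-for-bit from one integer.

`degrade_sample` maps storage time to degradation rates with a saturating
exponential increment (room temperature: amplitudes 0.12/0.06, τ = 8 h;
refrigerated: 0.02/0.01, τ = 24 h). Only the qualitative contract is
asserted — monotone in time, faster at room temperature, reticulocyte
fraction untouched — since the assay defines no quantitative storage curve.

**What the simulator does not emulate:** stain variability and uneven
illumination, optical blur and halos, true smear density gradients
(feathered edges), cell fragments/debris fields, nucleated erythroid
precursors, and platelet clumps. Passing tests therefore demonstrate that
the post-processing chain, the counting statistics and the QC logic are
correct under controlled morphology — not that the fixed thresholds would
transfer to scanner data unchanged.

## Segmentation

Otsu thresholding of the cell-body signal (fluorescence) or green-channel
darkness (brightfield; all stained cells absorb green) followed by
4-connected labelling. Guards: components below 16 px (1 μm² at the default
0.25 μm/px) are discarded as noise speckle, and the Otsu split is trusted
only if the two intensity classes separate by at least four pooled standard
deviations (a blank field otherwise thresholds mid-noise).

Post-processing follows the assay protocol in fixed order:

1. **Exclusion masks.** WBC and platelet candidate masks (nuclear-scale
   DNA component, or sub-7 μm² with no DNA) are removed before geometric
   refinement; a cell is removed when more than 50% of its pixels fall
   under an exclusion mask.
2. **Separation of juxtaposed cells.** Each mask is eroded with a 3 px
   disc; the eroded region is split by marker-based watershed on its
   Euclidean distance transform, markers being distance maxima at least one
   anticipated cell diameter (4 μm) apart; fragments are re-grown by 3 px
   (nearest-fragment tie-break) clipped to the parent footprint. Masks that
   erode to nothing are dropped and tallied. The watershed realisation of
   the protocol's "object separation assuming elliptical geometry" is a
   design choice; it honours the same 4 μm parameter.
3. **Size exclusion.** Debris below 7 μm² and aggregates above 50 μm² are
   excluded; the interval is closed (equality retains) because the
   protocol's exclusion rules are strict inequalities. The thresholds are
   read in μm² — the only physically possible unit for red-cell areas.
   Border-touching masks are excluded by default to avoid double counting
   across tiles.

## Classification

All gates are exposed in `ClassifierParams`. DNA foci are connected
components of the DNA channel (fluorescence, threshold 0.35) or of the
purple score `(R+B)/2 − G` (MGG, threshold 0.22) with area in
[0.2, 6.0] μm²; larger components are candidate WBC nuclei. A boundary
focus counts if at least half its pixels are inside the mask.

* Fluorescence: WBC if any DNA component ≥ 6 μm² or DNA/cell area ratio
  ≥ 0.25; platelet if < 7 μm² with no DNA; debris if solidity < 0.70 with
  no DNA; otherwise MN⁺/MN⁻-RBC by focus count.
* MGG: WBC by the same nuclear rule; otherwise RET iff the blue-dominance
  index (mean B − mean R over the mask) ≥ 0.0, the midpoint between the
  rendered chromatic populations; MN positivity from foci.
* Degradation pass (separate over MGG samples): elongated iff aspect ratio
  > 2.5 (the one gate fixed by the assay definition); else echinocyte iff
  the smoothed angular boundary-radius profile has ≥ 3 prominent peaks
  *and* solidity ≤ 0.94. Elongation takes precedence. The two echinocyte
  defaults were calibrated on simulated smears across both modalities:
  separation re-dilation blunts spicule tips, which raises echinocyte
  solidity to ~0.93 and makes unsmoothed peak counts noise-dominated;
  at the chosen defaults calibration showed 87% echinocyte recall with no
  false positives on smooth discs.

## Quantification and statistics

Frequencies, fold changes (ratios of percentages, by default on group
means), multi-MN frequency (cells with ≥ 2 foci over evaluable RBCs), and
the subsampling CV curve: for each subsample size n, the MN⁺ frequency is
recomputed on replicate draws and its CV (100·sd/mean, sample sd) reported.
Without-replacement sampling matches subsampling a finite slide and is the
default; with-replacement sampling is provided because it admits the
binomial closed form CV(n) = 100·√((1−p)/(np)) used as an oracle. A
population whose subsample means are all zero yields CV = NaN (flagged
undefined). Tumor volume is length × width² × π/6 with swapped inputs
reordered (length is defined as the longest diameter), and RTV is the ratio
to the volume at randomisation.

Two-group comparisons are normality-gated: Shapiro-Wilk per group at
α = 0.05; both pass → two-tailed Welch's t; otherwise two-tailed
Mann-Whitney U — exact by full enumeration of partitions when the combined
n ≤ 16 (midranks, so ties are exact; two-sided p is the null probability of
a U at least as far from n₁n₂/2 as observed), normal approximation with tie
correction otherwise. Groups of fewer than 3 observations cannot be
Shapiro-Wilk tested and route directly to the exact test; identical
constant groups yield p = 1 through the same route. No multiple-testing
correction is applied (readouts are reported as raw pairwise p-values).
Concordance is Pearson correlation plus OLS on paired values, with
R² = r² by construction and verified against the residual definition.

## Numerical and reproducibility choices

Coordinates are 0-based row-major; areas are pixel counts × pixel-size².
The size filter compares closed-interval in μm²; tests of the boundary use
the binary-exact 0.25 μm pixel so 7.00 and 50.00 μm² are representable.
All randomness flows from integer seeds through `numpy.random.Generator`;
reports are canonical sorted-key JSON with no timestamps, so a rerun with
the same config and seed is byte-identical. Every excluded object carries a
reason (`wbc_mask`, `platelet_mask`, `eroded_empty`, `size_below`,
`size_above`, `border`), and `detected = retained + Σ excluded` holds per
field and per sample.

## Problem sizes

Validation runs use one 1024 × 1024 field per ~600 cells (0.25 μm/px,
matching a 40× scan): frequency recovery on 35-field (~21,000-cell)
samples, fold-change recovery on 84 fields (~50,000 cells) per arm, RET
recovery on 34 MGG fields, and subsampling CVs on 1,000 replicates. These
sizes keep recovered frequencies within three binomial standard errors of
the injected truth while a full two-arm comparison completes in minutes on
one CPU.

## Known limitations

* Thresholds are calibrated to the simulator's intensity model; real
  scanner data would need re-calibration (the classifier is deliberately
  rule-based, not learned).
* Deeply overlapped small cells (centres closer than the 4 μm marker
  spacing) are not separable and are either counted once or excluded as
  aggregates; frequency readouts remain approximately unbiased because
  merging is MN-status-agnostic, but cell yields drop in dense fields.
* The platelet and debris rules are morphometric surrogates: the assay
  defines these classes only through annotated training data.
* Echinocyte recall is ~87% under default rendering; blunted spicules after
  mask re-dilation are the dominant loss mode.
* Storage-degradation kinetics are a monotone phenomenological stand-in,
  not a fitted model.
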