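# Methods

## Scope and model

`dvhcompare` implements the analysis layer of a three-modality
(photon / proton / helium-ion) treatment-plan comparison: given one
cumulative DVH per (patient, modality, structure), it computes dosimetric
indices, LKB NTCP per endpoint, and paired nonparametric statistics over
the cohort. Treatment-plan optimization, dose calculation, RBE modelling
and DICOM handling are out of scope: the pipeline starts from plan
exports, and physical Gy and GyRBE are treated as the same numeric axis.

## DVH representation and numerics

Relative (fractional) volume is canonical; the structure's absolute volume
(cm³) is metadata that only enters the integral dose. Bins are half-open
`[edge_i, edge_{i+1})`; the differential bin dose is the bin midpoint;
generated curves use 0.1 Gy bins (≤ 0.2% of the 54 Gy prescription, so
discretization is negligible against the modality effects of interest).
Cumulative ↔ differential conversion is adjacent differencing / reverse
cumulative summation and is an exact inverse pair on curves that terminate
at zero volume; residual volume at the top edge is attributed to the last
edge dose in `d_mean`.

Dose-at-volume D_x interpolates linearly on the cumulative curve; exact
ties (flat segments) resolve to the highest dose at the requested volume,
which is the conservative choice for near-maximum metrics. The DVH
estimators for the extreme doses in IC are D_max = dose at the last
nonzero cumulative point and D_min = the highest dose still covering 100%
of the volume; both are robust to binning, at the price that HI and IC on
a literal single-bin (uniform) curve vanish only up to the bin width —
test fixtures therefore use near-degenerate bins (1e-9 Gy).

gEUD is evaluated on the differential form with midpoint doses; zero-dose
bins contribute zero. The n = 1 shortcut (gEUD = D_mean) agrees with the
general power-mean path to 1e-12 and is checked against it. The normal CDF
is the double-precision error function; no truncated series are involved.
Doses enter NTCP as plan total doses without fractionation (LQ/EQD2)
correction, matching how such planning comparisons are typically reported.

## LKB parameters

The registry (`data/lkb_parameters.csv`, editable and replaceable via
`--params`) ships probit parameters for endocrine dysfunction (pituitary:
TD50 60.6 Gy, m 0.08, n 1), tinnitus (cochlea: 46.52 Gy, 0.35, 1) and
hearing loss (cochlea: 55.57 Gy, 0.14, 1). Contoured inner-ear volumes are
mapped to the cochlea parameters through a configurable structure→endpoint
map, the usual practice when only inner-ear contours are available. These
parameter sets derive from historical, mostly adult photon cohorts; NTCP
values for pediatric ion-beam plans are comparative quantities, not
absolute risk predictions. No hippocampal endpoint is computed (no
established parameter set). n = 1 for all shipped endpoints makes
gEUD = D_mean; the general n path is implemented and tested for n ∈ (0, 1].

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes:
15 patients × 3 modalities × 9 structures (CTV, ipsi/contralateral
hippocampus and inner ear, pituitary, brainstem, whole brain, skin),
54 Gy in 30 × 1.8 Gy prescribed to the CTV median, CTV coverage
D95 ≥ 95% of prescription, and OAR dose falloff steepening from photons to
protons to helium ions.

* **CTV**: cumulative volume is a symmetric sigmoid centred at the
  prescription, `v(D) = 1/(1 + exp((D − D_p)/s))`, spread s per modality
  (defaults 0.55 / 0.45 / 0.30 Gy for photon / proton / helium, ±10%
  lognormal patient jitter). The spread is capped at
  `0.05·D_p/ln 19` so the 95%-coverage constraint holds for every draw by
  construction.
* **Ordinary OAR**: `v(D) = 1/(1 + expm1(g·D)/expm1(g·D50))`, truncated to
  [0, prescription]. The family is exactly 1 at zero dose and exactly 0.5
  at the configured D50, so the generator's median-dose parameter is the
  measured median — a plain logistic renormalized to v(0)=1 would shift
  its median and bias effect recovery. `D50 = baseline × lognormal patient
  effect × modality factor`; the gradient g is modality-wide (0.35 / 0.50 /
  0.70 Gy⁻¹).
* **Brain and skin** carry a two-component mixture: a small high-dose
  logistic component (the volume abutting the target; 20% for brain, 4%
  for skin) plus an exponential low-dose bath with modality-dependent
  half-dose λ, so their median doses can fall below 1 Gy and exercise the
  exclusion rules exactly as whole-brain and skin D50 do in practice.

Per-structure baselines (photon scale) and modality factors are chosen so
cohort means land in the ranges typical of published pediatric
posterior-fossa comparisons (e.g. pituitary D50 ≈ 9 / 12 / 15 Gy for
He / H+ / Ph); this is a soft calibration of plausibility, not a claim of
reproducing any specific study's tables, whose per-patient data are
unavailable. The patient-level lognormal effect is shared across
modalities (capped per structure so even the largest modality factor keeps
the falloff inside the plan range — capping the shared effect rather than
the per-modality dose preserves paired ratios exactly).

**Seeding.** A single global seed feeds a per-(patient, structure)
substream (`SeedSequence(entropy=seed, spawn_key=(patient, crc32(name)))`),
so adding or removing a structure never perturbs other structures' draws,
and all patient randomness is shared across modalities: with three
identical modality profiles, a patient's three plans are identical, and a
null-effect configuration yields exactly zero relative differences.

**What the generator does not emulate**: anatomy and spatial dose, DVH
shapes beyond smooth monotone families, intra-structure heterogeneity
patterns, planning-constraint trade-offs, or modality-specific per-patient
noise (real plans would add independent per-plan variability; here the
paired contrasts are nearly noise-free by design). Passing tests therefore
demonstrate correctness of the metrics, NTCP chain and statistics, and
internal consistency of the simulation — not clinical realism of any
particular dose distribution.

**Voxel phantom oracle.** For any plan, a brute-force voxel array is built
by stratified inverse-CDF sampling of the cumulative curve (default 20 000
equal-volume voxels per structure). DVH-derived D_mean, D50 and gEUD must
match the voxel-array mean, median and power mean within half a bin width;
the binned voxel DVH matches the curve within one bin width.

## Statistics

Cohorts of 15 are too small for asymptotic approximations to be
trustworthy, so both tests use exact permutation distributions:

* **Wilcoxon signed-rank** (two-sided): zero differences are dropped
  before ranking (classic convention); the null distribution of W+ is
  built by dynamic programming over doubled average ranks (exact for any
  tie pattern) for n ≤ 25, with a tie- and continuity-corrected normal
  approximation above. p = min(1, 2·min(P(W+ ≤ w), P(W+ ≥ w))).
* **Friedman** (k = 3): under the null each patient's within-row ranking
  is uniform over the 3! orderings; the joint distribution of column rank
  sums is built by convolution over patients — exact for any n when rows
  have no internal ties; tied rows fall back to the tie-corrected
  chi-square approximation. The reported statistic is the usual Friedman
  chi-square; the exact p is P(ΣR_j² ≥ observed).

Both are validated against full enumeration (2ⁿ sign assignments, 6ⁿ rank
permutations) at small n to 1e-12, and against scipy in the approximate
regime. The Friedman test never gates the post-tests: both p-values are
always reported, significance is the raw two-sided Wilcoxon p < 0.05, and
no multiplicity correction is applied — a deliberate fidelity-to-practice
choice for this table layout, documented rather than "fixed".

## Exclusion rules

Dose metrics (Gy-valued: D_mean, D1, D50, D95, D99) below 1 Gy for **all
three** modalities exclude that patient-metric from the statistical
analysis; more than five excluded patients mark the row not-applicable.
Relative-difference columns are additionally gated per contrast pair: a
patient's ratio is dropped when both paired values are below 1 Gy, and a
contrast cell with more than five dropped patients renders `nan ± nan`.
The pairwise gate is what lets a brain-D50-style row be not-applicable for
He vs H+ (both sub-Gy) while still reporting H+ vs Ph (photon ≈ 2 Gy).
HI, IC, ID and NTCP are never thresholded. The rules are idempotent and
order-independent.

## Aggregation and rendering

Relative differences are computed per patient, `(a − b)/b × 100` with the
second-named modality as denominator, then averaged; SEM = sample SD/√n.
A constant multiplicative modality effect c therefore yields exactly
(c − 1)·100 with SEM 0. NTCP contrasts are absolute differences
(NTCP_He − NTCP_H+). Rendered tables round the SEM to two significant
figures and the value to the SEM's last decimal (capped at six decimals);
machine CSVs keep full precision.

## Problem sizes

Default analyses run 15 patients × 3 modalities × 9 structures with
0.1 Gy bins (≈ 540-point curves); the effect-recovery check repeats the
cohort over 20 seeds; voxel oracles use 20 000 voxels per structure;
enumeration oracles go to n = 12 (Wilcoxon) and n = 6 (Friedman). These
sizes keep the full suite in seconds while leaving the statistics in their
exact-test regime.

## Known limitations

* NTCP parameters are historical/adult-derived; outputs are comparative.
* The generator's paired contrasts have almost no residual noise, so
  significance flags on synthetic cohorts are near-deterministic —
  informative about the pipeline, not about clinical effect sizes.
* Absolute-volume (cm³-axis) DVH files, DICOM-RT and vendor export
  dialects are not parsed.
* The exact Friedman path assumes untied within-patient triples
  (continuous dose metrics); tied triples use the chi-square
  approximation.
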