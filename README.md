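# dvhcompare

Paired three-modality radiotherapy treatment-plan comparison from
dose–volume histograms (DVHs): dosimetric indices, Lyman–Kutcher–Burman
(LKB) normal tissue complication probabilities (NTCP), and the matched
nonparametric statistics that decide whether one modality spares organs at
risk better than another.

The package targets the in-silico planning-study workflow for pediatric
posterior-fossa tumors (e.g. ependymoma): the same patients are planned
with photon IMRT, actively scanned protons, and scanned helium ions
(54 Gy in 30 × 1.8 Gy prescribed to the CTV median dose), per-structure
DVHs are exported as plain text, and the three plans are compared pairwise
on target coverage, OAR sparing and modeled late-toxicity risk. Because
clinical plan exports are rarely shareable, a seeded synthetic-cohort
generator reproduces the statistical structure of such a study (paired
patients, modality-ordered dose falloff, coverage constraints) and doubles
as a test bed with voxel-level brute-force oracles.

## What it computes

**Dosimetric indices** from a cumulative DVH (volume fraction at-or-above
dose):

- D_x — minimum dose received by the hottest x% of the volume (D1 near-max,
  D50 median, D95/D99 coverage), by linear interpolation on the curve;
- D_mean and integral dose ID = D_mean × V [Gy·cm³];
- homogeneity index HI = (D5 − D95)/D_p × 100 (0 = perfectly flat target
  dose) and inhomogeneity coefficient IC = (D_max − D_min)/D_mean.

**LKB NTCP** via the generalized equivalent uniform dose,

    gEUD = [ Σ_i v_i · D_i^(1/n) ]^n,
    t    = (gEUD − TD50) / (m · TD50),
    NTCP = Φ(t),

with TD50 the uniform whole-organ dose giving 50% complication probability,
m the probit slope, and n the volume effect (n = 1 ⇒ gEUD = D_mean). The
shipped registry covers endocrine dysfunction (pituitary, TD50 = 60.6 Gy,
m = 0.08) and the auditory endpoints tinnitus (TD50 = 46.52 Gy, m = 0.35)
and hearing loss (TD50 = 55.57 Gy, m = 0.14), with cochlea parameters
applied to inner-ear DVHs.

**Paired comparison** in a statsmodels-like shape: `ModalityComparison`
(built from a long-format records table) → `.fit()` →
`ComparisonResults` with per-modality mean ± SEM, per-patient relative
differences (He vs H+, H+ vs Ph; denominator = second-named modality),
exact-permutation Friedman and Wilcoxon signed-rank tests, and the
exclusion rules of small-dose metrics (values < 1 Gy for all modalities are
dropped; rows with more than five dropped patients are reported `nan`).

## Worked example

```python
from dvhcompare import (default_config, generate_cohort, metric_battery,
                        ModalityComparison)
from dvhcompare.ntcp import load_lkb_registry, ntcp_from_dvh

cohort = generate_cohort(default_config(n_patients=15, seed=1))

# LKB NTCP for one patient's ipsilateral inner ear (tinnitus endpoint)
rec = ntcp_from_dvh(cohort[0]["inner_ear_il"], load_lkb_registry()[0])
print(f"gEUD={rec.geud:.2f} Gy  t={rec.t:.3f}  NTCP={100*rec.ntcp:.1f}%")
# gEUD=29.54 Gy  t=-1.043  NTCP=14.9%

# paired comparison of the pituitary median dose across the cohort
records = [r for p in cohort for r in metric_battery(p)]
row = ModalityComparison.from_metric_records(records).fit().row("pituitary", "D50")
print({m: f"{row.means[m]:.2f}" for m in ("helium", "proton", "photon")})
# {'helium': '9.06', 'proton': '12.08', 'photon': '15.10'}
c = row.contrast("helium_vs_proton")
print(f"{c.diff_mean:.2f}% (Wilcoxon p={c.wilcoxon.pvalue:.2e})")
# -25.00% (Wilcoxon p=6.10e-05)
```

The gEUD of ~29.5 Gy sits well below the tinnitus TD50 of 46.52 Gy, giving
a 15% modeled risk for this photon plan. The cohort's pituitary median
doses are ordered helium < proton < photon (9/12/15 Gy), and the helium
plans deliver 25% less median pituitary dose than the proton plans — the
generator's configured modality effect, recovered by the pipeline and
flagged by the exact Wilcoxon post-test (p = 2/2¹⁵).

## Command line

```bash
dvhcompare simulate --n-patients 15 --seed 1 --out-dir dvh/
dvhcompare metrics  --in-dir dvh/ --out metrics.csv
dvhcompare ntcp     --in-dir dvh/ --out ntcp.csv
dvhcompare compare  --metrics metrics.csv --ntcp ntcp.csv --out tables/
dvhcompare run-all  --seed 1 --out-dir results/   # everything incl. plots
```

DVH files use a plain-text dialect (`# key: value` header, one
`## structure:` block per organ, `dose_Gy,relative_volume` rows at six
decimals); see `dvhcompare.io`.

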