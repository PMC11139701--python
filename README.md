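# y90pet

Quantitative evaluation of post-treatment ⁹⁰Y-radioembolization PET: can the
standard 20-minute scan be shortened without losing image quality or
dosimetric accuracy?  After selective internal radiation therapy (SIRT) of
liver tumors with ⁹⁰Y microspheres, the rare internal-pair branch of ⁹⁰Y
decay makes PET verification of the delivered dose possible.  `y90pet`
re-implements that evaluation as a reusable, fully tested pipeline driven by
a synthetic phantom, so every step — image-quality metrics across scan
durations and OSEM iteration numbers, voxel and compartment dosimetry, lung
shunt estimation, paired statistics — can be exercised and validated without
patient data.

## What it computes

**Image quality** from one spherical lesion VOI and eight equal-radius
background VOIs, propagated unchanged across the 5 × 4 factorial of scan
durations (20/15/10/5/1 min) and OSEM iteration numbers (2/4/6/8):

```
SNR_peak = (VOI_L-peak − VOI_BG-mean) / VOI_BG-SD
SNR_mean = (VOI_L-mean − VOI_BG-mean) / VOI_BG-SD
COV      =  VOI_BG-SD / VOI_BG-mean
LBR      =  VOI_L-max / VOI_BG-mean
```

where `VOI_L-peak` is the mean over a 1 cm³ sphere centered on the hottest
lesion voxel (SUVpeak convention).

**Dosimetry** by the local deposition model (LDM): for a decay-corrected
activity concentration C (kBq/ml) of a permanent implant,

```
D [Gy] = C·10³ [Bq/ml] × (T½/ln2) [s] × Ē_β [J] / ρ [kg/ml]
```

with T½ = 64.05 h and Ē_β = 0.9267 MeV, giving 49.39 Gy·kg per GBq.  From
the voxel dose map the pipeline extracts tumor D2/D50/D70/Dmean (nearest-rank
DVH), whole-liver normal-tissue dose and mean lung dose (ρ_lung = 0.26 g/ml),
flagging the 20 Gy lung limit.  Predicted (pre-treatment) doses use the
multi-compartment partition model: injected activity split between tumor and
normal liver in proportion to image counts, with the lung fed by the lung
shunt fraction LSF = GM_lung / (GM_lung + GM_liver) estimated from
anterior/posterior planar geometric means.

**Statistics**: paired two-sided Wilcoxon signed-rank tests (exact
enumeration p for small cohorts) across the six duration pairs and three
iteration pairs, plus Tukey boxplot summaries.

The phantom module emulates a patient: a liver ellipsoid with a hot tumor
sphere, low-uptake lungs, an abdominal scatter floor, Gaussian PSF blur and
count-statistics noise whose SD follows `g(iterations)·√(C/(c·t))` — so
background COV obeys the 1/√t law and grows with the iteration number.

## Worked example

```
$ y90pet full --seed 1 --out demo
{
 "out_dir": "demo",
 "iq_rows": 340,
 "dose_rows": 340,
 "comparison_rows": 90,
 ...
}
```

This simulates a 17-replicate cohort, 20 condition images each (340 rows =
17 × 20), and writes `iq_metrics.csv`, `dose_metrics.csv`,
`predicted_vs_actual.csv`, `shunt.json`, `comparisons.csv` and boxplot
figures.  Median image-quality metrics at 2 iterations:

```
duration_min  snr_peak    cov     lbr
1.0             49.634  0.223  14.194
5.0            110.729  0.099  12.938
10.0           155.415  0.071  12.646
15.0           190.403  0.058  12.553
20.0           219.648  0.050  12.485
```

COV doubles from 20 to 5 min (0.050 → 0.099, the 1/√4 counting law) and LBR
inflates at 1 min as noise pushes up the lesion maximum.  The
predicted-vs-actual table shows the partition-model prediction overshooting
the measured tumor dose by ~9% and the planar-predicted lung dose
(3.65 Gy) exceeding the measured 1.75 Gy — both well below the 20 Gy lung
limit (`shunt.json`: `"lung_limit_exceeded": false`, LSF 0.0066).

Other subcommands: `simulate` (write the NIfTI image tree + checksum
manifest), `iq`, `dose`, `shunt`, `compare`; all accept `--config` (YAML),
`--seed`, `--replicates`.  The same functionality is importable
(`y90pet.run_full`, `y90pet.voxel_ldm_dose`, …).

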