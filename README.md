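# tessella

Objective quantification of fundus tessellation from color fundus
photographs.

A tessellated (tigroid) fundus — large choroidal vessels showing through
between patches of retinal pigment epithelium — is a common feature of
myopic eyes and a clinical marker for later retinochoroidal degeneration,
but it is usually graded by eye. `tessella` computes reproducible scalar
indices of tessellation from ordinary fundus photographs and ships the full
statistical battery needed to validate them against subjective grades and
choroidal thickness, plus a synthetic fundus simulator so the entire
pipeline can be exercised without clinical data.

## The indices

A circular region of interest (default diameter 250 px) is centred on the
midpoint of the fovea–optic-disc axis, which keeps the large retinal vessel
arcades and the peripapillary conus outside the analysed area. From the
mean red, green and blue intensities R, G, B of the pixels inside the disk:

    TFI-1 = (R − G) / R
    TFI-2 = R / (R + G + B)
    TFI-3 = (R − G) / (R + G + B)

All three are ratios of channel means, hence invariant to global brightness
changes between photographs, and TFI-3 = TFI-1 · TFI-2 identically. A more
visible choroidal vasculature makes the region redder and less green, so
all three indices increase with the degree of tessellation.

## The statistical battery

Implemented from the defining formulas (scipy supplies only distribution
primitives):

- **Spearman rank correlation** (mid-rank ties, Student-t p-value) for
  index–covariate relationships;
- **Steel–Dwass all-pairs comparison** (tie-corrected standardized rank
  statistic referred to the studentized range Q(k, ∞)) for differences
  among the non- / weakly / strongly tessellated grade groups;
- **Fleiss kappa** for agreement among the three raters;
- **ICC(A,1)** — two-way model, absolute agreement, single measurement —
  for intersession repeatability.

## Worked example

```
$ tessella simulate --n 100 --seed 42 --out cohort/
wrote 100 images + landmarks.csv + cohort.csv to cohort

$ tessella compute --images cohort/ --landmarks cohort/landmarks.csv \
                   --cohort cohort/cohort.csv --out tfi.csv
wrote 100 rows to tfi.csv (0 skipped)

$ tessella analyze --cohort cohort/cohort.csv --tfi tfi.csv --out report/
wrote reports to report
```

`report/report_summary.txt` then contains (abridged):

```
Cohort: 100 eyes

Index by tessellation grade (mean ± SD):
  grade  n               tfi1             tfi2             tfi3
  NT     47     0.333 ± 0.035    0.483 ± 0.010    0.161 ± 0.020
  WT     30     0.374 ± 0.047    0.495 ± 0.013    0.185 ± 0.027
  ST     23     0.376 ± 0.042    0.496 ± 0.015    0.187 ± 0.026

All-pairs Steel-Dwass comparisons:
  tfi3  NT vs WT: t =  -3.907, p = 0.0003 *
  tfi3  NT vs ST: t =  -3.857, p = 0.0003 *
  tfi3  WT vs ST: t =  -0.162, p = 0.9857  (n.s.)

Spearman correlations:
  tfi3 vs sfct: rho =  -0.461, p = 0.0000 *
  tfi3 vs nct: rho =  -0.473, p = 0.0000 *
  axial_length vs sfct: rho =  -0.439, p = 0.0000 *

Rater agreement: Fleiss kappa = 0.700 (observed 0.807, chance 0.355,
100 eyes x 3 raters)
```

Reading: the indices rise across the subjective grades and clearly separate
the non-tessellated group from both tessellated groups; tessellation
correlates negatively with subfoveal and nasal choroidal thickness (a thin
choroid exposes the vessels), and axial length correlates negatively with
choroidal thickness — the correlation structure such a validation study
expects.

The same output is available through the library API
(`generate_cohort`, `compute_tfi`, `run_study`, …); the CLI is a thin
wrapper over it.

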