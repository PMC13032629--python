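# mhri — macular-hole OCT reflectivity indices and their prognostic value

Full-thickness macular holes (FTMH) are surgically closed in >90% of eyes,
but visual recovery is far less predictable. Because the brightness of the
retinal pigment epithelium (RPE) on an OCT B-scan reflects the state of the
RPE–photoreceptor complex, reflectivity at the hole base is a candidate
prognostic biomarker. This package implements, end to end, the measurement
and statistical analysis of a family of reflectivity indices measured on
8-bit greyscale B-scans:

| index | definition |
|---|---|
| CRI-Max  | max central brightness / normal-RPE brightness |
| CRI-Mean | mean central brightness / normal-RPE brightness |
| PCRI-Min | min paracentral brightness / normal-RPE brightness |
| PCRI-Mean| mean paracentral brightness / normal-RPE brightness |
| MHRI     | max central brightness / min paracentral brightness |

where "central" is the hyperreflective region at the hole base, "paracentral"
the hyporeflective regions flanking it on either side, and the normal RPE is
sampled far from the hole. Alongside the indices the package measures the
minimum linear diameter (MLD), the shortest distance between the inner hole
edges, and runs the full prognostic battery: normality-dispatched group
tests, Spearman correlations, multiple linear regression of post-operative
logMAR VA with VIF/tolerance collinearity diagnostics, ROC curves with
Youden-index (J = sensitivity + specificity − 1) cutoffs for anatomical
closure and for visual success (post-op VA ≤ 0.3 logMAR among closed eyes),
and inter-rater agreement via ICC(2,1) and Bland-Altman limits of agreement.

Patient scans are not redistributable, so the package ships two first-class
simulators: B-scan phantoms with exact programmed ground truth
(`mhri.synthetic_oct`) on which every measurement operation is verified, and
synthetic surgical cohorts (`mhri.cohort`) with the group-conditional
MHRI/MLD/VA structure of a 48-eye FTMH case series.

## Layout

- `src/mhri/` — the library: `synthetic_oct`, `reflectometry`, `cohort`,
  `prognostats`, `report`, `plots`, `cli`
- `analysis/` — numbered narrative drivers (simulate phantoms → measure →
  simulate cohort → cohort statistics → diagnostic performance) writing
  their outputs under `results/`
- `tests/` — pytest suite, including oracle-based checks of every
  measurement primitive
- `scripts/acceptance.py` — recomputes the checkable headline quantities

## Worked example

```sh
python analysis/03_simulate_cohort.py --seed 1
python analysis/05_diagnostic_performance.py --seed 1
```

prints (abridged):

```
wrote cohort of 48 eyes -> results/cohort.csv
          mhri                mld_um
          mean    std count     mean     std count
closure
failure  1.862  0.798     2  419.743   3.328     2
success  1.417  0.166    46  315.381  75.430    46
...
visual success (closed eyes) — mhri: AUC 78.1% (CI 64–90%), cutoff 1.36
  (lower predicts positive), J 0.50, sens 65%, spec 85%
inter-rater MHRI: ICC 0.993, bias -0.0011, LOA [-0.0527, 0.0505]
```

Reading: in this simulated cohort the 46 closed eyes carry lower MHRI
(1.42 ± 0.17) than the 2 failures; among closed eyes an MHRI below ≈1.36
predicts a post-operative VA of 0.3 logMAR or better with AUC 78%, and the
two simulated raters agree almost perfectly (ICC 0.99). With only ~3
failures per 48-eye cohort the anatomical ROC is highly seed-variable —
exactly the small-sample caveat such a cohort carries.

The same pipeline is available as a CLI (`mhri simulate-images`,
`simulate-cohort`, `measure`, `analyze`, `report`), e.g.

```sh
mhri simulate-images --n 5 --seed 1 --outdir out/imgs
mhri measure --images out/imgs --auto --out out/indices.csv
mhri analyze --cohort results/cohort.csv --seed 1 --outdir out/report --plots
```

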