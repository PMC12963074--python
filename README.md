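# ctbmd — opportunistic CT bone densitometry

Routine contrast-enhanced CT scans of the chest and abdomen image the lumbar
spine for free. The attenuation (in Hounsfield units, HU) of the trabecular
bone of L1–L4 is a usable proxy for bone mineral density, which makes every
such scan an opportunity to screen for osteoporosis without extra imaging.
The catch: iodinated contrast raises trabecular HU, so the same patient looks
denser in the arterial or venous phase than on the non-contrast series —
enough to flip a diagnosis.

`ctbmd` is a tested pipeline for exactly this analysis, aimed at researchers
quantifying contrast effects in opportunistic screening cohorts:

* **ROI extraction** — given a CT volume and a co-registered vertebral label
  mask (NIfTI), build a trabecular region of interest centred on each
  vertebral body (centroid-centred box ∩ label, eroded away from the cortical
  rim) and extract mean/median HU, voxel count and volume per vertebra and
  for the pooled L1–L4 region.
* **Scoring** — convert HU to DXA-style scores against a sex/age reference
  model:

  `T = (HU − μ_young,sex) / σ_young,sex` and `Z = (HU − μ_age,sex) / σ_age,sex`

  with the WHO bands: `T > −1.0` normal, `−2.5 ≤ T ≤ −1.0` osteopenia,
  `T < −2.5` osteoporosis (both boundaries belong to osteopenia; scores that
  cannot be computed are carried explicitly as `unknown`).
* **Phase comparison** — paired absolute/relative changes of HU, T and Z
  between the non-contrast baseline and each enhanced phase (Wilcoxon
  signed-rank), 4×4 diagnostic transition tables, per-subgroup
  misclassification rates, and the standard group tests (Mann–Whitney U,
  Kruskal–Wallis, Pearson chi-squared).
* **Synthetic data** — because no patient data ship with the package, a fully
  deterministic generator produces reference populations (linear age decline
  of trabecular HU with a sex difference), triphasic cohorts with a
  parameterised contrast-enhancement model, and labelled 3-D vertebral
  phantoms, so every stage is verifiable end to end.

## Worked example

```python
from ctbmd import (GenerativeParams, generate_reference_population,
                   generate_cohort, score_cohort, paired_changes,
                   transition_table, misclassification_report)

params = GenerativeParams(n_patients=200, seed=42)
ref, _ = generate_reference_population(params)
patients, measurements, truth = generate_cohort(params)
scored = score_cohort(measurements, patients, ref)

base = scored[(scored.phase == "noncontrast") & (scored.level == "L1")]
print("baseline median T:", round(base["t"].median(), 2))
for ph in ("arterial", "venous"):
    hu = paired_changes(scored, "noncontrast", ph, "L1", "HU")
    t = paired_changes(scored, "noncontrast", ph, "L1", "T")
    print(f"{ph}: dHU {hu.median_abs_change:+.1f} "
          f"({hu.median_rel_change_pct:+.1f}%), dT {t.median_abs_change:+.2f}")

tabs = {ph: transition_table(scored, "noncontrast", ph, "L1")
        for ph in ("arterial", "venous")}
rep = misclassification_report(tabs, subgroup_n=len(patients))
print(rep[rep.kind != "transition"][["phase_pair", "kind", "count", "pct"]])
```

prints

```
baseline median T: -1.98
arterial: dHU +29.8 (+27.3%), dT +0.85
venous: dHU +18.2 (+18.1%), dT +0.52
     phase_pair       kind  count  pct
       arterial pair_total     61 30.5
         venous pair_total     50 25.0
arterial+venous    overall    111 55.5
```

Read: on this synthetic cohort the median non-contrast T-score sits in the
osteopenic band; arterial contrast raises trabecular HU by ~30 HU (about
+0.85 T), and 61 of 200 patients (30.5 %) change diagnostic category between
the non-contrast and arterial series. The `overall` row counts change
*events* across both enhanced phases (a patient reclassified in both
comparisons counts twice); a unique-patient rate is also available via
`unique_patient_change_rate`.

The same flow is available from the shell:

```sh
bmd simulate --n-patients 200 --seed 42 --out run/
bmd score  --reference run/reference.csv --cohort run/cohort.csv \
           --measurements run/measurements.csv --out run/
bmd report --scored run/scored.csv --cohort run/cohort.csv --out run/
```

`bmd simulate --phantoms` additionally writes NIfTI image/mask phantom pairs,
and `bmd extract --volumes <dir>` runs the ROI stage over them (or over real
image/mask pairs named `<patient>_<phase>_image.nii.gz`). For real data an
explicit reference table is always required — there is no silent default.

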