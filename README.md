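# edemaquant

Quantitative-MRI analysis of drug-induced vasodilatory edema.

Dihydropyridine-type (L-type) calcium-channel blockers lower blood
pressure effectively but commonly cause peripheral edema, because they
dilate arterioles more than venules and raise capillary hydrostatic
pressure. Mixed T- and L-type blockers promise the antihypertensive
effect with less edema. In the preclinical setting both effects can be
quantified simultaneously: proton-density (PD) mapping of the thigh
muscles tracks interstitial free water minute-by-minute after drug
delivery, while an arterial cannula records the mean arterial pressure
(MAP). `edemaquant` implements that analysis as a tested, reusable
pipeline for people developing or evaluating such imaging biomarkers —
and ships a synthetic study generator with known ground truth, so the
whole chain can be validated without scanner data.

## The model

A multi-slice multi-echo spin-echo acquisition gives one image per echo
time. Each voxel's echo train decays monoexponentially,

    SI(TE) = K · PD · e^(−TE/T2) · (1 − e^(−TR/T1)),

where K is a scanner constant and the T1 saturation factor is the same
at every TE, so both are absorbed into the fitted amplitude A ∝ PD.
The pipeline fits (A, T2) per voxel by Levenberg–Marquardt least
squares, pools A over an ROI drawn on nine contiguous slices of the
bilateral thigh muscles (bone excluded), and forms the fractional
change relative to the pre-delivery scan,

    ΔPD(t) = (PD(t) − PD(0)) / PD(0),

in which the unknown gain cancels. Two endpoints summarize a subject's
trajectory over the 55-minute delivery:

* **ULE** (ultra-early level of edema) = ∫₀⁵ ΔPD(τ) dτ — the integral
  of the fractional change over the first 5 minutes;
* **DLE** (dose-dependent level of edema) = dΔPD/dt — the slope of the
  linear trend ΔPD(t) = a·t + b.

Treatment arms (solvent, L-CCB, T&L-CCB; n = 16 each) are compared per
endpoint with a one-way ANOVA; a mean-centered Levene test gates the
post-hoc procedure (Bonferroni when variances are homogeneous,
Tamhane's T2 otherwise), and groups are reported as mean±SD±SEM.

## Worked example

Simulate a scaled-down study (3 arms × 8 subjects, 64×64 matrix, 3 ROI
slices, Gaussian noise at first-echo SNR 50), fit every scan, compute
the indices and run the statistics:

```python
from edemaquant import AcquisitionParams, SyntheticStudyConfig, run_all
from edemaquant.pipeline import RunConfig, render_report
from edemaquant.synthetic import sigma_for_snr

params = AcquisitionParams(matrix_rows=64, matrix_cols=64, n_slices=3)
study = SyntheticStudyConfig(n_per_group=8, noise_model="gaussian",
                             noise_sigma=sigma_for_snr(50.0), seed=1)
res = run_all(RunConfig(study=study, acquisition=params, n_roi_slices=3))
print(render_report(res.reports))
```

prints (excerpt):

```
DLE
---
  solvent    n=8   0.0009736 ± 6.371e-05 ± 2.253e-05
  L-CCB      n=8   0.004695 ± 0.0007316 ± 0.0002586
  T&L-CCB    n=8   0.002312 ± 0.0003761 ± 0.000133
  ANOVA: F(2,21) = 125.26, P = 2.13e-12
  Levene (mean-centered): 9.53, P = 0.001 -> post hoc: Tamhane
    solvent vs L-CCB: diff = -0.003721, adj. P = 5.01e-06
    solvent vs T&L-CCB: diff = -0.001339, adj. P = 4.62e-05
    L-CCB vs T&L-CCB: diff = 0.002382, adj. P = 2.16e-05
```

The recovered per-arm mean DLE (0.00097, 0.0047, 0.0023 per minute)
matches the generator's configured effect sizes (0.0010, 0.0047,
0.0025), the arms order solvent < T&L-CCB < L-CCB, and the omnibus F
cleanly separates them — the L-type blocker drives the fastest edema
growth, the mixed blocker roughly half of it.

The same stages are available from a shell:

```sh
edemaquant simulate --config study.yaml --out study/ --seed 1
edemaquant fit --volume study/solvent_01_t0000.nii.gz --mask study/solvent_01_roi.nii.gz --out fit/
edemaquant indices --study study/ --out indices.csv
edemaquant map-reductions --study study/ --out map.csv
edemaquant stats --indices indices.csv --map map.csv --out report/
edemaquant run-all --config run.yaml --out out/ --seed 1
```

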