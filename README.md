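# petlesionsim

Synthetic lesion insertion and attenuation-correction bias evaluation for
brain PET.

## The problem

Quantitative brain PET requires correcting each line of response for the
attenuation of 511 keV photons. On PET/CT the attenuation map comes from CT
(CTAC) and is the accepted reference; on PET/MRI it must be inferred from MR
images (MRAC), which cannot see cortical bone directly. The classic MRAC
families — DIXON (soft tissue only), DIXONbone (model-based bone), UTE
(short-echo-time bone segmentation) and DL-DIXON (deep-learning pseudo-CT) —
therefore misrepresent the skull to different degrees, and the resulting
activity bias is largest in cortex adjacent to bone.

Validating a new MRAC method normally requires tri-modality patient data.
`petlesionsim` implements the alternative: insert *synthetic* lesions and
ROIs directly into PET projection space with full physics modelling
(attenuation, normalization, calibration, scatter, Poisson noise),
reconstruct with attenuation-corrected OSEM under each candidate map, and
score the ROI-level bias against the CTAC reconstruction — no measured
emission data needed. Because no clinical cohort ships with the package, an
analytic digital head phantom (ellipsoidal scalp/skull/brain with a 16-region
cortical parcellation) stands in for the patients, and the four MRAC
families are emulated as controlled degradations of the ground-truth
attenuation map.

## The model

For an ROI mean activity `PET_MRAC` reconstructed with a candidate map and
`PET_CTAC` with the reference map, the package reports

    relative bias (%) = 100 · (PET_MRAC − PET_CTAC) / PET_CTAC
    absolute bias (%) = 100 · |PET_MRAC − PET_CTAC| / PET_CTAC

per subject, ROI, method and condition (lesion inserted into the patient
background, lesion reconstructed alone, and the original lesion-free data).
Lesions enter the data as expected-count sinograms

    E = P(psf ∗ x_lesion) · a(μ) · n · (sensitivity · duration)

with `P` an exact Siddon parallel-beam projector, `a(μ) = exp(−∫ μ dl)` the
survival factors of the *true* attenuation map, `n` the normalization
factors, plus a scaled broad-Gaussian scatter term and a Poisson draw.
Reconstruction is standard OSEM (default 3 iterations × 21 subsets, 4 mm
Gaussian post-filter); only the attenuation factors inside the system model
change between methods, so image differences isolate the AC method. Cohort
results are summarized as median [IQR] and compared with two-sided paired
t-tests of absolute bias against the reference method, Benjamini–Hochberg
corrected.

## Worked example

```python
from petlesionsim.pipeline import smoke_config, run_experiment
from petlesionsim.evaluation import records_frame

cfg = smoke_config(master_seed=1, n_subjects=5)   # 64×64×8 grid, 48 angles
result = run_experiment(cfg, out_dir="demo")

df = records_frame(result.records)
near = df[(df.roi_id == "superior_frontal_sphere")
          & (df.condition == "with_background")]
print(near.groupby("method")["relative_bias_pct"].median().round(2))
for s in result.stats:
    if s.roi_id == "superior_frontal_sphere" and s.condition == "with_background":
        print(s.comparison, "t=%.2f" % s.t_statistic, "p_adj=%.4f" % s.p_adjusted)
```

prints (about 4 s on one CPU):

```
method
dixon       -9.19
dixonbone   -2.80
dl_dixon     0.58
ute         -4.80
Name: relative_bias_pct, dtype: float64
dl_dixon_vs_dixon t=-18.89 p_adj=0.0002
dl_dixon_vs_dixonbone t=-23.59 p_adj=0.0002
dl_dixon_vs_ute t=-12.69 p_adj=0.0005
```

Read: for a 4 mm sphere inserted in the superior frontal cortex (adjacent to
the skull) the bone-blind DIXON map underestimates activity by ~9 % in the
median over five synthetic subjects, UTE and DIXONbone recover part of the
loss, and the near-truth DL-DIXON map is unbiased within noise; the paired
tests confirm its absolute bias is significantly smaller than every
alternative. The same run writes `demo/bias_records.csv` (one row per
subject × ROI × method × condition), `demo/summary.json` (medians, IQRs,
adjusted p-values, boxplot-ready group lists) and a provenance copy of the
fully resolved configuration.

The command-line interface exposes the same pipeline (`petlesionsim run
--config cfg.yaml --out dir`) plus stage-by-stage verbs `phantom`, `mumaps`,
`insert`, `recon` and `evaluate` operating on NIfTI volumes; each supports
`--help`.

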