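# fermiperf

Quantitative first-pass perfusion CMR with scar-corrected ischemic burden.

In diseases such as hypertrophic cardiomyopathy, microvascular ischemia and
myocardial fibrosis coexist: scar tissue has reduced vascularity, so it
appears hypoperfused on stress perfusion imaging and inflates the measured
ischemic burden.  `fermiperf` implements the full analysis chain needed to
separate the two on a pixel-by-pixel basis:

1. **Fermi-constrained deconvolution** of myocardial signal curves against
   the arterial input function (AIF).  The tissue impulse response is
   modelled as

   ```
   h(t) = R · [1 / (exp((t − τ₀ − τ_d)·k) + 1)] · u(t − τ_d)
   ```

   fitted by bounded nonlinear least squares over (R, k, τ₀) with the
   arrival delay τ_d fixed (chosen by exhaustive search).  Myocardial blood
   flow is the delay-free initial response height, MBF = R/(e^(−τ₀k) + 1),
   and myocardial perfusion reserve (MPR) is stress MBF / rest MBF —
   computed per pixel (high-resolution maps) and per AHA segment.
2. **LGE scar segmentation** by the 6-SD rule: overt scar is myocardial
   signal more than six standard deviations above the mean of a remote,
   non-enhanced region.
3. **Scar transfer** from LGE geometry into perfusion-map geometry through
   contour-normalised polar coordinates (angle from the RV insertion,
   transmural depth fraction).
4. **Ischemic burden**: the percentage of LV myocardium with MPR below a
   threshold, with and without exclusion of overt scar, plus the relative
   error between the two, tertile recategorisation across a cohort, and
   Bland–Altman/Pearson interobserver reproducibility.

Because clinical CMR data of this kind are not publicly available, the
package ships a fully ground-truthed synthetic phantom (gamma-variate AIF,
Fermi forward model, configurable noise/motion/coil bias, scar with elevated
LGE signal and depressed stress flow, multi-subject cohorts) so that every
stage is testable end to end.  See `docs/methods.md` for the model,
assumptions and limitations.

## Worked example

Quantify one synthetic subject with a mid-ventricular scar and compare the
burden with and without scar correction:

```python
import numpy as np
from fermiperf import RunConfig, run_subject

cfg = RunConfig(
    phantom=dict(
        shape=[64, 64], slice_labels=["mid"],
        endo_radii_mm=[16.0], epi_radii_mm=[25.0],
        snr=25.0,
        scar=dict(angle_start=0.5, angle_width=0.9,
                  depth_range=[0.2, 0.8], slices=[0], stress_mbf=0.7),
    ),
    seed=7,
)
res = run_subject(cfg)
print(f"LGE extent:          {res.lge_percent:.1f} % of myocardium")
print(f"burden @ MPR<1.5:    {res.burden_uncorrected.at(1.5):.1f} % uncorrected")
print(f"                     {res.burden_corrected.at(1.5):.1f} % corrected")
err = 100 * (res.burden_uncorrected.at(1.5) - res.burden_corrected.at(1.5)) \
      / res.burden_uncorrected.at(1.5)
print(f"overestimation:      {err:.1f} % of the uncorrected burden")
```

prints

```
LGE extent:          8.9 % of myocardium
burden @ MPR<1.5:    8.9 % uncorrected
                     0.0 % corrected
overestimation:      100.0 % of the uncorrected burden
```

The scar occupies ~9 % of the myocardium and its depressed apparent MPR
(true scar MPR 0.7) accounts for the entire apparent ischemic burden at the
MPR < 1.5 threshold in this subject: excluding overt scar removes it
completely, because the remaining myocardium is genuinely well perfused.  On a cohort, `run_cohort` aggregates
these per-subject results into burden-vs-threshold curves stratified by LGE
status, a relative-error curve, a tertile recategorisation table and the
interobserver reproducibility of the corrected burden.

A thin CLI wraps the same library:

```sh
fermiperf simulate --config cfg.yaml --out subject_dir
fermiperf burden   --config cfg.yaml
fermiperf cohort   --config cfg.yaml --n-subjects 30 --out results/
fermiperf report   --config cfg.yaml --n-subjects 30 --out results/
```

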