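# flimqc

Quality control for large-area fluorescence lifetime imaging microscopy
(FLIM) data, plus a multi-component TCSPC decay simulator for planning
phasor-based experiments.

## The problem

Large mosaic FLIM acquisitions — thousands of tiles collected over hours —
are never uniform: photon counts drift with tissue morphology and laser
power, z-focus estimation stripes the intensity, detectors overload and
drop tiles, and lifetime estimates from photon-poor decay curves are far
noisier than the intensity image suggests. Comparing regions or samples
without accounting for this variability quietly degrades the statistics of
any downstream biological conclusion.

`flimqc` addresses this with three tools:

1. **Pixelwise QC maps.** For co-registered intensity (I) and mean-lifetime
   (τ, ps) images, it computes NaN-aware local coefficient-of-variation
   maps over a square kernel window, `CV = σ/μ` (population σ), and their
   ratio

   > **F′ = CV_τ / CV_I**

   — a per-pixel, SNR-like figure of merit that captures dual variation in
   lifetime and intensity (the detector/count-rate scaling factor of the
   classical FLIM figure of merit is omitted). Background is removed with
   Triangle-method intensity thresholding (removed pixels become NaN and
   are excluded from every window statistic). Histogram ranges of F′ are
   exported as binary masks with per-mask lifetime statistics, so analysis
   can be restricted to regions of comparable SNR.

2. **Decay simulation and phasor variability.** Per-pixel biexponential
   TCSPC decays are generated by photon-wise sampling: each photon picks a
   lifetime component with probability equal to its intensity fraction,
   draws an exponential waiting time and wraps it modulo the laser period
   (12.5 ns / 80 MHz by default); background photons are uniform. The
   first-harmonic phasor transform

   > g = Σ c·cos(ωt) / Σ c, s = Σ c·sin(ωt) / Σ c, ω = 2π/T

   places mono-exponential decays on the universal semicircle
   (g−½)² + s² = ¼ and mixtures on chords. Clouds are calibrated against a
   mono-exponential 4 ns reference, median-filtered (3×3), and summarized
   by **convex-hull area × ellipticity** after Mahalanobis-percentile
   outlier exclusion — a single number for how localized a simulated
   image's phasor distribution is, over grids of lifetimes, fractions and
   photon counts.

3. **Separability experiments.** Between two pools of mean-lifetime
   images, the 1-D Wasserstein distance between subsamples of *n* images
   per pool (30 trials by default) quantifies how confidently the pools
   separate as the ROI sample size grows.

A synthetic-mosaic generator (regional lifetime/intensity structure,
acquisition striping, blank detector-overload tiles, photon-limited
lifetime noise) makes all of this testable without any real acquisition.

## Worked example

```python
import numpy as np
import flimqc as fq

# synthetic 256x256 mosaic: bright 1500 ps base, dim 1200 ps region,
# 15% intensity striping, one blank (overloaded) tile
spec = fq.striped_two_region_spec(seed=7)
intensity, lifetime, label = fq.generate_mosaic(spec)

ranges = [fq.RangeSpec("low", 0.0, 0.25),
          fq.RangeSpec("mid", 0.25, 0.4),
          fq.RangeSpec("high", 0.4, 1.0)]
res = fq.qc_pipeline(intensity, lifetime, kernel=25, ranges=ranges)

print(f"Triangle threshold: {res.threshold:.2f} photons")
print(f"dim-region CV_tau:    {np.nanmean(res.cv_tau.values[label == 1]):.4f}")
print(f"bright-region CV_tau: {np.nanmean(res.cv_tau.values[label == 0]):.4f}")
print(res.masks.stats[["label", "n", "mean", "median"]].round(1).to_string(index=False))
```

prints

```
Triangle threshold: 11.60 photons
dim-region CV_tau:    0.1043
bright-region CV_tau: 0.0378
label     n   mean  median
  low 12626 1456.2  1488.7
  mid 34251 1500.2  1499.9
 high  6797 1198.1  1199.3
```

The dim region — same nominal lifetime noise, ~7× fewer photons — shows
nearly 3× the lifetime CV, and the high-F′ mask isolates exactly the
low-SNR 1200 ps region: its mask-restricted median lifetime (1199 ps)
recovers the construction. That is the QC story in miniature: F′ ranges
flag where lifetime values are trustworthy before any biology is compared.

The same pipelines are available from the shell:

```bash
flimqc fixtures --out fx --seed 1
flimqc qc --intensity fx/intensity.tif --lifetime fx/lifetime.tif --kernel 25 --out qc_out
flimqc simulate --tau1 0.5 --tau2-min 2 --tau2-max 8 --tau2-steps 7 \
    --frac-steps 5 --photons 500 --out sweep.csv
flimqc separability --pool-a dir_a --pool-b dir_b --n-values 2,5,10,20 --out sep
```

Every run writes a plain-text manifest of all decided parameters (kernel,
threshold method and value, ranges, seeds) next to its outputs.

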