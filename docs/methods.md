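# Methods

This note documents the models, conventions and numerical decisions behind
`flimqc`, in the order the pipelines run.

## Decay simulation

Each pixel's TCSPC histogram is generated photon by photon. A signal photon
picks component 1 with probability `frac1` (else component 2), draws an
exponential waiting time with that component's lifetime, and is wrapped
modulo the repetition period `T` — the periodic-excitation convention for
an 80 MHz source (`T = 12.5 ns` default), under which the wrapped decay's
Fourier coefficients at harmonics of `1/T` equal those of the unwrapped
exponential exactly. Background photons are uniform on `[0, T)`. Arrival
times are binned into `n_bins = 256` equal bins (both configurable).

Decisions and assumptions:

* **`frac1` is an intensity fraction** (the probability a detected photon
  came from component 1), so the phasor of a mixture is exactly linear:
  `P = frac1·P(τ1) + (1−frac1)·P(τ2)`. Amplitude fractions would bend this
  relation; the intensity convention is the one the linearity tests verify.
* **Photon numbers are Poisson** around `n_photons` and `background`
  (shot statistics); `fixed_counts=True` freezes them for
  variance-decomposition tests.
* **No instrument response function**, dead time, afterpulsing or pile-up:
  decays are ideal exponentials. The simulator is for statistical planning,
  not instrument emulation.
* **Per-pixel substreams** come from `SeedSequence.spawn` in row-major
  order, so cubes are bit-reproducible and independent of evaluation order.

## Phasor analysis

The first-harmonic transform uses **bin-center times**; the residual
discretization bias this leaves (≤ 2·10⁻⁴ at 256 bins for lifetimes
0.5–8 ns) is absorbed by calibration. Calibration compares the
count-weighted centroid of a mono-exponential reference cloud (default
reference lifetime 4 ns) with the closed form
`P(τ) = (1/(1+(ωτ)²), ωτ/(1+(ωτ)²))` in polar form, yielding a
multiplicative modulation factor and an additive phase shift applied to
every pixel as a complex rotation/scaling. Count weighting lets brighter
pixels dominate, matching how a reference is actually measured; an
unweighted mode is available.

The "median filter of 1" is read as one pass of a 3×3 NaN-aware median,
the common meaning in FLIM software; zero-count (NaN) pixels stay NaN so
the exclusion mask survives filtering.

**Cloud variability metric.** Finite (g, s) points are centered; points
whose Mahalanobis distance exceeds the 95th-percentile cutoff (default)
are excluded; the metric is the convex hull area of the retained points
times the ellipticity `1 − sqrt(λ_minor/λ_major)` of their covariance
(0 = circular, → 1 = line). The hull area is computed after median
filtering. Degenerate cases: identical points → area 0, ellipticity 0;
collinear points → area 0; fewer than 3 retained points → error. The
Mahalanobis cut uses the covariance pseudo-inverse so collinear clouds
remain well-defined.

**Fraction along a chord.** Because mixing is linear, the orthogonal
projection of a point onto the chord `P(τ2) → P(τ1)`, normalized and
clamped to [0, 1], estimates `frac1`. This is a diagnostic for parameter
recovery, not a general unmixing method.

A note on Monte-Carlo error in calibrated comparisons: the calibration
itself is estimated from a finite reference cube, and its centroid error
propagates to every calibrated point scaled by `|P_sample|/|P_ref|`. Tests
that compare calibrated centroids against closed forms therefore use a
bright reference (~10⁷ photons) and include the propagated reference SE in
their error budget.

## QC maps

* **Local CV** uses the population standard deviation (divisor N) — CV is
  a distribution property, not an estimator — over the finite values in a
  `kernel × kernel` window. Windows are **clipped at borders**: statistics
  run over the available pixels, no padding values are invented (border CVs
  therefore average fewer samples). Output is NaN where the center pixel is
  NaN, where the window holds no finite value, or where the mean is 0.
  Implementation: moving window sums of a globally mean-shifted image
  (shifting removes the `E[x²] − E[x]²` cancellation), verified bit-close
  (≤ 10⁻¹⁰ relative) against a per-pixel brute-force loop.
* **Kernel size** defaults to 49 — suited to large mosaics where per-pixel
  CV would be dominated by pixel-to-pixel texture — and should be chosen
  against the scale of the relevant structures and the upstream fit's
  spatial binning. On a homogeneous (noise-only) mosaic, the spatial
  variance of the CV map decreases monotonically with kernel size; once
  windows straddle genuinely distinct regions the CV map instead picks up
  boundary contrast, which is signal, not noise.
* **F′ = CV_τ / CV_I**, NaN where either input is NaN or CV_I = 0 (NaN
  rather than infinity keeps histograms and mask ranges finite).
* **Triangle threshold**: histogram (256 bins, the 8-bit-era convention of
  the common implementations) of finite intensities; line from the peak to
  the zero-height far end of the longer tail; threshold = upper edge of
  the bin maximizing perpendicular distance to that line. It always runs
  on the finite values of the raw intensity, before any other exclusion.
* **Ranges are half-open** `[low, high)` so adjacent ranges partition
  exactly; masks are False wherever the source map is NaN; per-mask
  statistics (n, mean, SD, median, quartiles, min, max) are computed on a
  designated map, typically mean lifetime.
* Pipeline order: threshold → NaN-propagate into all maps → CV maps →
  F′ → masks → per-mask stats. No stage converts a NaN to a finite number.

## Separability

The separability score is the **raw first-order Wasserstein distance**
(units of the input, ps for lifetime) between the pooled values of `n`
images subsampled from each pool — no normalization, so scores are
directly interpretable as lifetime offsets. Subsampling is **without
replacement within a trial** (a tile is a physical region, sampled once),
fresh across trials; 30 trials by default. Pools can be flattened as all
finite pixels or as per-image means; the per-image-mean mode is the default
for ROI-style experiments. With one trial the SD is reported as NaN (no
degrees of freedom), never as 0.

## Synthetic mosaics

The generator emulates the features of real large-area data the QC stages
must handle: rectangular/elliptical regions with their own mean lifetime,
lifetime SD and mean intensity; Poisson pixel intensities; per-tile-row
intensity striping `(1 ± amplitude)`; all-NaN overload tiles; and lifetime
noise inflated by `sqrt(reference_intensity / intensity)` — a photon-limited
precision rule reflecting that lifetime estimates from fewer photons are
less precise. It deliberately does **not** emulate tissue texture, optical
blur, autofluorescence spectra, or any particular estimator's
variance-vs-lifetime curve; passing tests show the pipeline's arithmetic
and ranking behaviour, not fidelity to any specific instrument.

Default study conditions used by the tests and the acceptance script:
two-region mosaics of 4×4 tiles of 64×64 px (1500 ps / 1200 ps regions,
50 ps lifetime SD, 80 vs 12 mean photons, 15% striping, one blank tile);
separability pools of 25 single-tile 32×32 px images with 100 ps pixel
noise, 50 ps per-image jitter and a 300 ps between-pool offset over
n ∈ {2, 5, 10, 20}; phasor sweeps with τ1 = 0.5 ns, τ2 ∈ 2–8 ns,
fractions 0–1, and 50–5000 photons/pixel on 32×32 cubes (~10 replicates
per condition). These sizes keep the full suite under a minute while
leaving Monte-Carlo error well inside every asserted tolerance.

## Files and units

Lifetime is **picoseconds in files** (matching how large-area maps are
published) and **nanoseconds in simulator math** (natural for 12.5 ns
periods); conversions are explicit. Scalar maps are single-channel TIFFs
with NaN as the exclusion value and a JSON description tag carrying kind
and units; decay cubes are multi-page uint16 TIFFs with a JSON sidecar;
masks export as 8-bit TIFF and PNG (0/255). Every CLI run writes a
manifest of all decided parameters so published analyses are auditable.

## Known limitations

* Phasor support is first-harmonic by default; higher harmonics are
  computed but not validated against any reference.
* No 2-D transport: phasor-pool separability uses per-image centroid g
  only.
* The Triangle threshold assumes a unimodal-background histogram; heavily
  multimodal intensity distributions may need a fixed threshold instead.
* The fixture's `1/sqrt(photons)` lifetime-noise law is a qualitative
  stand-in for estimator precision, adequate for ranking tests but not for
  quantitative variance prediction.
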