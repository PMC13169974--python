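"""Pixelwise quality-control maps for co-registered FLIM intensity/lifetime images.

The core quantities:

* local coefficient of variation, ``CV = sigma / mu`` over a square kernel
  window around each pixel (population standard deviation, NaN-aware,
  windows clipped at image borders);
* the F'-value map, ``F' = CV_tau / CV_I`` — a per-pixel SNR-like figure of
  merit that captures dual variation in fitted mean lifetime and photon
  intensity (the detector/count-rate scaling factor of the classical FLIM
  figure of merit is deliberately omitted);
* Triangle-method intensity thresholding for background removal, with the
  removed pixels set to NaN so they are excluded from all window statistics;
* binary masks from histogram ranges of a map (typically F'), with per-mask
  statistics of a chosen map (typically mean lifetime, ps).

NaN is the single exclusion convention throughout: no stage ever turns a
NaN pixel back into a number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .exceptions import DegenerateHistogramError, DimensionError, ParameterError

__all__ = [
    "ScalarMap",
    "RangeSpec",
    "MaskSet",
    "QCResult",
    "local_cv_map",
    "fprime_map",
    "triangle_threshold",
    "apply_intensity_threshold",
    "masks_from_ranges",
    "qc_pipeline",
]

MAP_KINDS = ("intensity", "lifetime_ps", "cv", "fprime", "auxiliary")

#: Kernel used for the published large-area maps; tune to the size of the
#: biological structures of interest and the upstream fit's spatial binning.
DEFAULT_CV_KERNEL = 49
#: Histogram bins for the Triangle threshold (8-bit-era convention).
DEFAULT_TRIANGLE_BINS = 256


@dataclass
class ScalarMap:
    """A 2-D float image where NaN marks excluded pixels."""

    values: np.ndarray
    kind: str = "auxiliary"
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError(f"ScalarMap must be 2-D, got shape {self.values.shape}")
        if self.kind not in MAP_KINDS:
            raise ParameterError(f"kind must be one of {MAP_KINDS}, got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def finite_values(self) -> np.ndarray:
        return self.values[self.finite_mask()]


@dataclass(frozen=True)
class RangeSpec:
    """Half-open value range [low, high) with a label.

    Half-open semantics make adjacent ranges partition exactly.
    """

    label: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ParameterError(f"range {self.label!r}: low must be < high")


@dataclass
class MaskSet:
    """Named binary masks plus per-mask statistics of a designated map."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def union(self) -> np.ndarray:
        out = None
        for m in self.masks.values():
            out = m.copy() if out is None else (out | m)
        return out


def _window_sums(a: np.ndarray, kernel: int) -> np.ndarray:
    """Clipped-window sums over kernel x kernel neighbourhoods."""
    return uniform_filter(a, size=kernel, mode="constant", cval=0.0) * (kernel * kernel)


def local_cv_map(smap: ScalarMap, kernel: int) -> ScalarMap:
    """Local coefficient-of-variation map, ``sigma/mu`` per kernel window.

    Statistics use the population convention (divisor N) over the finite
    values inside the window; windows are clipped at borders — no padding
    values are invented.  Output is NaN where the centre pixel is NaN,
    where the window holds no finite value, or where the window mean is 0.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError(f"kernel must be an odd integer >= 1, got {kernel}")
    v = np.asarray(smap.values, dtype=float)
    finite = np.isfinite(v)
    out = np.full(v.shape, np.nan)
    if finite.any():
        # shift by the global mean so sumsq - sum^2 does not cancel
        c = v[finite].mean()
        z = np.where(finite, v - c, 0.0)
        cnt = np.rint(_window_sums(finite.astype(float), kernel))
        s1 = _window_sums(z, kernel)
        s2 = _window_sums(z * z, kernel)
        with np.errstate(invalid="ignore", divide="ignore"):
            m_shift = s1 / cnt
            var = np.clip(s2 / cnt - m_shift * m_shift, 0.0, None)
            mean = m_shift + c
            cv = np.sqrt(var) / mean
        valid = finite & (cnt > 0) & (mean != 0)
        out[valid] = cv[valid]
    return ScalarMap(out, kind="cv", units="")


def fprime_map(cv_tau: ScalarMap, cv_intensity: ScalarMap) -> ScalarMap:
    """F' = CV_tau / CV_I, elementwise; NaN where undefined.

    NaN where either input is NaN or where CV_I = 0 (keeps histogram and
    mask ranges finite instead of injecting infinities).
    """
    if cv_tau.shape != cv_intensity.shape:
        raise DimensionError(
            f"shape mismatch: {cv_tau.shape} vs {cv_intensity.shape}"
        )
    if cv_tau.kind != "cv" or cv_intensity.kind != "cv":
        raise ParameterError("fprime_map expects two CV maps")
    a, b = cv_tau.values, cv_intensity.values
    with np.errstate(invalid="ignore", divide="ignore"):
        f = a / b
    f = np.where(np.isfinite(a) & np.isfinite(b) & (b != 0), f, np.nan)
    return ScalarMap(f, kind="fprime", units="")


def triangle_threshold(
    intensity: ScalarMap, n_hist_bins: int = DEFAULT_TRIANGLE_BINS
) -> float:
    """Background threshold by the Zack Triangle method.

    A histogram of the finite intensities is built; a line is drawn from the
    histogram peak to the far (zero-height) end of the longer tail, and the
    threshold is the bin maximizing the perpendicular distance between the
    histogram and that line.  Returns the upper edge of that bin in
    intensity units; pixels *below* the returned value are background.
    """
    if n_hist_bins < 2:
        raise ParameterError("n_hist_bins must be >= 2")
    vals = intensity.finite_values()
    if vals.size < 2 or vals.min() == vals.max():
        raise DegenerateHistogramError(
            "intensity histogram is degenerate (constant or empty image)"
        )
    hist, edges = np.histogram(vals, bins=n_hist_bins)
    peak = int(np.argmax(hist))
    nz = np.flatnonzero(hist)
    first, last = int(nz[0]), int(nz[-1])
    if last - peak >= peak - first:
        end = last
        candidates = np.arange(peak + 1, end + 1)
    else:
        end = first
        candidates = np.arange(end, peak)
    if candidates.size == 0:
        # peak sits at the end of its longer tail: fall back to peak bin edge
        return float(edges[peak + 1])
    # perpendicular distance to the line from (peak, h_peak) to (end, 0)
    h_peak = float(hist[peak])
    dx, dy = float(end - peak), -h_peak
    norm = np.hypot(dx, dy)
    d = np.abs(dx * (hist[candidates] - h_peak) - dy * (candidates - peak)) / norm
    best = int(candidates[int(np.argmax(d))])
    return float(edges[best + 1])


def apply_intensity_threshold(
    maps: list[ScalarMap], intensity: ScalarMap, threshold: float
) -> list[ScalarMap]:
    """NaN out every pixel whose intensity is below the threshold, in all maps.

    Returns new maps (inputs untouched).  Include the intensity map itself in
    ``maps`` to propagate the exclusion into it as well.
    """
    below = intensity.values < threshold  # NaN compares False: stays as-is
    out = []
    for m in maps:
        if m.shape != intensity.shape:
            raise DimensionError(f"shape mismatch: {m.shape} vs {intensity.shape}")
        v = m.values.copy()
        v[below] = np.nan
        out.append(ScalarMap(v, kind=m.kind, units=m.units))
    return out


_STAT_COLUMNS = ["label", "n", "mean", "sd", "median", "q1", "q3", "min", "max", "empty"]


def _mask_stats_row(label: str, vals: np.ndarray) -> dict:
    if vals.size == 0:
        return dict.fromkeys(_STAT_COLUMNS[1:-1], np.nan) | {
            "label": label,
            "n": 0,
            "empty": True,
        }
    return {
        "label": label,
        "n": int(vals.size),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "median": float(np.median(vals)),
        "q1": float(np.percentile(vals, 25)),
        "q3": float(np.percentile(vals, 75)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "empty": False,
    }


def masks_from_ranges(
    smap: ScalarMap,
    ranges: list[RangeSpec],
    stats_map: ScalarMap | None = None,
) -> MaskSet:
    """Binary masks ``low <= value < high`` (finite pixels only) per range.

    Per-mask statistics are computed over ``stats_map`` (defaults to the
    thresholded map itself); empty masks are flagged in the stats table.
    Disjoint ranges yield pairwise disjoint masks by construction.
    """
    if stats_map is None:
        stats_map = smap
    if stats_map.shape != smap.shape:
        raise DimensionError("stats_map shape must match the mask source map")
    v = smap.values
    finite = np.isfinite(v)
    masks: dict[str, np.ndarray] = {}
    rows = []
    for r in ranges:
        with np.errstate(invalid="ignore"):
            mask = finite & (v >= r.low) & (v < r.high)
        masks[r.label] = mask
        sv = stats_map.values[mask]
        rows.append(_mask_stats_row(r.label, sv[np.isfinite(sv)]))
    stats = pd.DataFrame(rows, columns=_STAT_COLUMNS)
    return MaskSet(masks=masks, stats=stats)


@dataclass
class QCResult:
    """Output bundle of :func:`qc_pipeline`."""

    threshold: float
    cv_tau: ScalarMap
    cv_intensity: ScalarMap
    fprime: ScalarMap
    masks: MaskSet


def qc_pipeline(
    intensity: ScalarMap,
    lifetime: ScalarMap,
    kernel: int = DEFAULT_CV_KERNEL,
    ranges: list[RangeSpec] | None = None,
    *,
    threshold_mode: str = "triangle",
    fixed_threshold: float | None = None,
    n_hist_bins: int = DEFAULT_TRIANGLE_BINS,
) -> QCResult:
    """End-to-end QC: threshold -> NaN-propagate -> CV maps -> F' -> masks.

    The intensity image is background-thresholded (Triangle by default), the
    removed pixels become NaN in both maps, local CV maps are computed for
    lifetime and intensity, their ratio gives the F' map, and the requested
    F' ranges become binary masks with mean-lifetime statistics per mask.
    """
    if intensity.shape != lifetime.shape:
        raise DimensionError(
            f"intensity {intensity.shape} and lifetime {lifetime.shape} must be co-registered"
        )
    if threshold_mode == "triangle":
        thr = triangle_threshold(intensity, n_hist_bins)
    elif threshold_mode == "fixed":
        if fixed_threshold is None:
            raise ParameterError("fixed threshold mode requires fixed_threshold")
        thr = float(fixed_threshold)
    elif threshold_mode == "none":
        thr = -np.inf
    else:
        raise ParameterError(f"unknown threshold_mode {threshold_mode!r}")
    intensity_t, lifetime_t = apply_intensity_threshold(
        [intensity, lifetime], intensity, thr
    )
    cv_tau = local_cv_map(lifetime_t, kernel)
    cv_int = local_cv_map(intensity_t, kernel)
    fprime = fprime_map(cv_tau, cv_int)
    if ranges is None:
        ranges = []
    if not np.isfinite(fprime.values).any():
        warnings.warn(
            "no finite pixels survive thresholding; mask set is empty", stacklevel=2
        )
    masks = masks_from_ranges(fprime, ranges, stats_map=lifetime_t)
    return QCResult(
        threshold=thr, cv_tau=cv_tau, cv_intensity=cv_int, fprime=fprime, masks=masks
    )
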