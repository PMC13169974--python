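"""First-harmonic phasor transform, calibration and cloud-variability metrics.

The phasor transform maps a decay histogram to a point (g, s) on the unit
plane via the first Fourier harmonic:

    g = sum_k c_k cos(w t_k) / sum_k c_k
    s = sum_k c_k sin(w t_k) / sum_k c_k,      w = 2*pi*harmonic / period,

with t_k the bin-center times.  Mono-exponential decays lie on the
universal semicircle (g - 1/2)^2 + s^2 = 1/4; mixtures lie on chords
between their components' points.  Raw coordinates carry instrument and
discretization bias, removed by calibrating against a reference of known
mono-exponential lifetime (modulation ratio + phase shift).

The spread of a cloud of per-pixel phasor points summarizes how well a
single image localizes its lifetimes: here it is quantified as the convex
hull area of the points times the cloud's ellipticity, after excluding
outliers beyond a Mahalanobis-distance percentile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import generic_filter
from scipy.spatial import ConvexHull, QhullError

from .decay_sim import TCSPCCube
from .exceptions import (
    DegenerateCloudError,
    DegenerateReferenceError,
    ParameterError,
)

__all__ = [
    "PhasorCloud",
    "CalibrationFactors",
    "PhasorVariability",
    "phasor_transform",
    "theoretical_monoexp_phasor",
    "compute_calibration",
    "apply_calibration",
    "median_filter_phasor",
    "phasor_variability",
    "estimate_fraction_along_chord",
]


@dataclass
class PhasorCloud:
    """Per-pixel (g, s) coordinates at a fixed harmonic.

    Pixels with zero photons carry NaN in both coordinates.  ``total_counts``
    is kept for count-weighted calibration statistics.
    """

    g: np.ndarray
    s: np.ndarray
    omega: float
    harmonic: int
    total_counts: np.ndarray

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.g.shape != self.s.shape:
            raise ParameterError("g and s must share a shape")
        if self.harmonic < 1:
            raise ParameterError("harmonic must be >= 1")

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.g) & np.isfinite(self.s)

    def finite_points(self) -> np.ndarray:
        """(n, 2) array of finite (g, s) pairs."""
        m = self.finite_mask()
        return np.column_stack([self.g[m], self.s[m]])


@dataclass(frozen=True)
class CalibrationFactors:
    """Multiplicative modulation correction and additive phase shift."""

    modulation_factor: float
    phase_shift: float
    ref_tau: float

    def __post_init__(self):
        if not self.modulation_factor > 0:
            raise ParameterError("modulation_factor must be positive")


@dataclass(frozen=True)
class PhasorVariability:
    """Scalar spread summary of a phasor cloud: hull area x ellipticity."""

    hull_area: float
    ellipticity: float
    metric: float
    centroid_g: float
    centroid_s: float
    n_retained: int
    n_excluded: int


def phasor_transform(cube: TCSPCCube, harmonic: int = 1) -> PhasorCloud:
    """First-harmonic (or higher) phasor coordinates of every pixel."""
    if harmonic < 1:
        raise ParameterError(f"harmonic must be >= 1, got {harmonic}")
    omega = 2.0 * math.pi * harmonic / cube.period
    t = cube.bin_centers
    cos_t = np.cos(omega * t)
    sin_t = np.sin(omega * t)
    counts = cube.counts.astype(float)
    total = counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts @ cos_t / total
        s = counts @ sin_t / total
    empty = total == 0
    g[empty] = np.nan
    s[empty] = np.nan
    return PhasorCloud(g=g, s=s, omega=omega, harmonic=harmonic, total_counts=total)


def theoretical_monoexp_phasor(tau: float, omega: float) -> tuple[float, float]:
    """Closed-form phasor of an ideal mono-exponential decay.

    (g, s) = (1 / (1 + (wt)^2), wt / (1 + (wt)^2)); lies on the universal
    semicircle for every tau >= 0.
    """
    if tau < 0:
        raise ParameterError(f"tau must be >= 0, got {tau}")
    x = omega * tau
    d = 1.0 + x * x
    return 1.0 / d, x / d


def compute_calibration(
    ref_cloud: PhasorCloud, ref_tau: float, *, weighted: bool = True
) -> CalibrationFactors:
    """Calibration factors from a mono-exponential reference of known lifetime.

    The count-weighted centroid of the reference cloud is compared, in polar
    form, against the theoretical point for ``ref_tau``:
    ``modulation_factor = m_theory / m_measured`` and
    ``phase_shift = phi_theory - phi_measured``.
    """
    m = ref_cloud.finite_mask()
    if not m.any():
        raise DegenerateReferenceError("reference cloud has no finite pixels")
    if weighted and ref_cloud.total_counts is not None:
        w = np.asarray(ref_cloud.total_counts, dtype=float)[m]
        if w.sum() <= 0:
            w = np.ones(m.sum())
    else:
        w = np.ones(m.sum())
    gbar = float(np.average(ref_cloud.g[m], weights=w))
    sbar = float(np.average(ref_cloud.s[m], weights=w))
    m_meas = math.hypot(gbar, sbar)
    if m_meas == 0:
        raise DegenerateReferenceError("reference centroid has zero modulation")
    phi_meas = math.atan2(sbar, gbar)
    g_th, s_th = theoretical_monoexp_phasor(ref_tau, ref_cloud.omega)
    m_th = math.hypot(g_th, s_th)
    phi_th = math.atan2(s_th, g_th)
    return CalibrationFactors(
        modulation_factor=m_th / m_meas, phase_shift=phi_th - phi_meas, ref_tau=ref_tau
    )


def apply_calibration(cloud: PhasorCloud, cal: CalibrationFactors) -> PhasorCloud:
    """Rotate/scale every finite (g, s) by the calibration; NaN preserved."""
    z = (cloud.g + 1j * cloud.s) * (cal.modulation_factor * np.exp(1j * cal.phase_shift))
    return replace(cloud, g=z.real, s=z.imag)


def median_filter_phasor(cloud: PhasorCloud, radius: int = 1) -> PhasorCloud:
    """NaN-aware square median filter applied to g and s independently.

    ``radius=1`` is the conventional "median filter of 1": a 3x3 window,
    one pass.  The median runs over the finite values in the window
    (windows are clipped at image borders).  Pixels that are NaN on input
    (zero-count pixels) remain NaN so the cloud's exclusion mask survives
    filtering.  ``radius=0`` is the identity.
    """
    if radius < 0:
        raise ParameterError(f"radius must be >= 0, got {radius}")
    if radius == 0:
        return replace(cloud, g=cloud.g.copy(), s=cloud.s.copy())
    size = 2 * radius + 1
    nan_in = ~cloud.finite_mask()

    def _filt(a: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = generic_filter(a, np.nanmedian, size=size, mode="constant", cval=np.nan)
        out[nan_in] = np.nan
        return out

    return replace(cloud, g=_filt(cloud.g), s=_filt(cloud.s))


def phasor_variability(
    cloud: PhasorCloud, outlier_percentile: float = 95.0
) -> PhasorVariability:
    """Convex-hull-area x ellipticity spread summary of a phasor cloud.

    Points whose Mahalanobis distance from the cloud centroid exceeds the
    ``outlier_percentile`` quantile of the distances are excluded; the
    convex hull area and covariance ellipticity are computed on the
    retained points.  Ellipticity is ``1 - sqrt(lambda_minor/lambda_major)``
    (0 = circular cloud, -> 1 = degenerate line).
    """
    if not 0 < outlier_percentile <= 100:
        raise ParameterError("outlier_percentile must lie in (0, 100]")
    pts = cloud.finite_points()
    if pts.shape[0] < 3:
        raise DegenerateCloudError(
            f"need >= 3 finite phasor points, got {pts.shape[0]}"
        )
    centered = pts - pts.mean(axis=0)
    cov = np.cov(pts.T, ddof=1)
    if np.allclose(cov, 0):
        # all points identical: zero spread by definition
        return PhasorVariability(
            hull_area=0.0,
            ellipticity=0.0,
            metric=0.0,
            centroid_g=float(pts[:, 0].mean()),
            centroid_s=float(pts[:, 1].mean()),
            n_retained=pts.shape[0],
            n_excluded=0,
        )
    # pseudo-inverse keeps collinear clouds well-defined
    cov_inv = np.linalg.pinv(cov)
    d2 = np.einsum("ij,jk,ik->i", centered, cov_inv, centered)
    cutoff = np.percentile(d2, outlier_percentile)
    keep = d2 <= cutoff
    retained = pts[keep]
    if retained.shape[0] < 3:
        raise DegenerateCloudError("fewer than 3 points retained after outlier exclusion")
    try:
        hull_area = float(ConvexHull(retained).volume)  # 2-D "volume" is area
    except QhullError:
        hull_area = 0.0
    cov_r = np.cov(retained.T, ddof=1)
    lam = np.linalg.eigvalsh(cov_r)
    lam_minor, lam_major = float(max(lam[0], 0.0)), float(max(lam[1], 0.0))
    if lam_major == 0.0:
        ellipticity = 0.0
    else:
        ellipticity = 1.0 - math.sqrt(lam_minor / lam_major)
    return PhasorVariability(
        hull_area=hull_area,
        ellipticity=ellipticity,
        metric=hull_area * ellipticity,
        centroid_g=float(retained[:, 0].mean()),
        centroid_s=float(retained[:, 1].mean()),
        n_retained=int(retained.shape[0]),
        n_excluded=int(pts.shape[0] - retained.shape[0]),
    )


def estimate_fraction_along_chord(
    point: tuple[float, float], tau1: float, tau2: float, omega: float
):
    """Fraction of component 1 by orthogonal projection onto the mixing chord.

    Because phasor mixing is linear in intensity fractions, a biexponential
    pixel lies (in expectation) on the chord joining the component points
    P(tau1) and P(tau2).  The projected, clamped chord position recovers
    frac1 (1 = pure component 1).  ``point`` may be a pair of scalars or a
    pair of equal-shape arrays.
    """
    if tau1 == tau2:
        raise ParameterError("tau1 and tau2 must differ to define a chord")
    p1 = np.array(theoretical_monoexp_phasor(tau1, omega))
    p2 = np.array(theoretical_monoexp_phasor(tau2, omega))
    v = p1 - p2
    g, s = np.asarray(point[0], dtype=float), np.asarray(point[1], dtype=float)
    t = ((g - p2[0]) * v[0] + (s - p2[1]) * v[1]) / (v @ v)
    out = np.clip(t, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out
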