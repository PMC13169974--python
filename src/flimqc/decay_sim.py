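"""Monte-Carlo simulation of multi-component TCSPC decay histograms.

Time-correlated single-photon counting (TCSPC) records, per pixel, a
histogram of photon arrival times relative to the excitation pulse.  Under
periodic excitation (80 MHz Ti:Sapphire, 12.5 ns repetition period) a
two-component fluorophore mixture produces a sum of exponential decays
wrapped around the period.  This module draws individual photons from that
model: each signal photon picks a lifetime component with probability given
by the *intensity* fraction ``frac1``, draws an exponential waiting time
with that component's lifetime, and is wrapped modulo the period (periodic
excitation re-excites before long decays finish); background photons arrive
uniformly over the period.  Decays are ideal exponentials — no instrument
response function is convolved and no detector dead-time or pile-up is
modelled.

Interpreting ``frac1`` as an intensity fraction makes the first-harmonic
phasor of a mixture exactly linear in ``frac1``:
``P = frac1 * P(tau1) + (1 - frac1) * P(tau2)``.

Per-pixel random substreams are derived from a single seed via
``numpy.random.SeedSequence.spawn``, so results are independent of the
order in which pixels are simulated and reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

#: Laser repetition period for an 80 MHz Ti:Sapphire source, ns.
DEFAULT_PERIOD_NS = 12.5
#: Default number of TCSPC time bins per period.
DEFAULT_N_BINS = 256

__all__ = [
    "DEFAULT_PERIOD_NS",
    "DEFAULT_N_BINS",
    "DecayParams",
    "TCSPCCube",
    "sample_arrival_times",
    "simulate_pixel",
    "simulate_cube",
    "mean_lifetime_of_params",
]


def _as_generator(rng_seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence or an existing Generator."""
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


@dataclass(frozen=True)
class DecayParams:
    """Parameter set for a biexponential pixel decay.

    Parameters
    ----------
    tau1, tau2 : float
        Component lifetimes, ns.  For a mono-exponential decay set
        ``frac1=1`` (``tau2`` is then never sampled).
    frac1 : float
        Intensity fraction of component 1, in [0, 1].
    period : float
        Laser repetition period, ns.
    n_photons : float
        Expected number of signal photons per pixel (Poisson mean).
    background : float
        Expected number of uniform background photons per pixel.
    n_bins : int
        Number of equal-width time bins over one period.
    """

    tau1: float
    tau2: float = 4.0
    frac1: float = 1.0
    period: float = DEFAULT_PERIOD_NS
    n_photons: float = 1000.0
    background: float = 0.0
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self):
        if not (self.tau1 > 0 and np.isfinite(self.tau1)):
            raise ParameterError(f"tau1 must be positive and finite, got {self.tau1}")
        if not (self.tau2 > 0 and np.isfinite(self.tau2)):
            raise ParameterError(f"tau2 must be positive and finite, got {self.tau2}")
        if not 0.0 <= self.frac1 <= 1.0:
            raise ParameterError(f"frac1 must lie in [0, 1], got {self.frac1}")
        if not (self.period > 0 and np.isfinite(self.period)):
            raise ParameterError(f"period must be positive, got {self.period}")
        if self.n_photons < 0:
            raise ParameterError(f"n_photons must be >= 0, got {self.n_photons}")
        if self.background < 0:
            raise ParameterError(f"background must be >= 0, got {self.background}")
        if int(self.n_bins) != self.n_bins or self.n_bins < 2:
            raise ParameterError(f"n_bins must be an integer >= 2, got {self.n_bins}")

    @property
    def bin_width(self) -> float:
        """Width of one time bin, ns."""
        return self.period / self.n_bins


@dataclass
class TCSPCCube:
    """Per-pixel photon arrival-time histograms.

    ``counts`` is indexed ``(row, col, time_bin)`` and holds non-negative
    integer photon counts; ``bin_width * n_bins == period``.
    """

    counts: np.ndarray
    bin_width: float
    period: float
    params: DecayParams | None = field(default=None, repr=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ParameterError("counts must be (row, col, time_bin)")
        if np.any(self.counts < 0):
            raise ParameterError("counts must be non-negative")
        if not np.isclose(self.bin_width * self.n_bins, self.period, rtol=1e-9):
            raise ParameterError("bin_width * n_bins must equal period")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, cols)."""
        return self.counts.shape[:2]

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin-center times over one period, ns."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def total_counts(self) -> np.ndarray:
        """Per-pixel photon totals (rows, cols)."""
        return self.counts.sum(axis=2)


def sample_arrival_times(params: DecayParams, n_draws: int, rng_seed) -> np.ndarray:
    """Draw ``n_draws`` signal-photon arrival times in [0, period).

    Each photon picks component 1 with probability ``frac1`` (else
    component 2), draws Exp(tau) and wraps modulo the period.  Background
    photons are *not* drawn here; they are added by :func:`simulate_pixel`.
    """
    if n_draws < 0:
        raise ParameterError(f"n_draws must be >= 0, got {n_draws}")
    rng = _as_generator(rng_seed)
    if n_draws == 0:
        return np.empty(0, dtype=float)
    if params.frac1 == 1.0:
        tau = np.full(n_draws, params.tau1)
    elif params.frac1 == 0.0:
        tau = np.full(n_draws, params.tau2)
    else:
        comp1 = rng.random(n_draws) < params.frac1
        tau = np.where(comp1, params.tau1, params.tau2)
    t = rng.exponential(tau)
    return np.mod(t, params.period)


def simulate_pixel(params: DecayParams, rng_seed, *, fixed_counts: bool = False) -> np.ndarray:
    """Simulate one pixel's decay histogram (length ``n_bins``).

    Signal and background photon numbers are Poisson-distributed around
    ``n_photons`` and ``background``; with ``fixed_counts=True`` the
    expectations are used directly (rounded), which isolates binomial
    component-choice and timing noise from shot noise.
    """
    rng = _as_generator(rng_seed)
    if fixed_counts:
        n_sig = int(round(params.n_photons))
        n_bg = int(round(params.background))
    else:
        n_sig = int(rng.poisson(params.n_photons))
        n_bg = int(rng.poisson(params.background))
    t_sig = sample_arrival_times(params, n_sig, rng)
    t_bg = rng.uniform(0.0, params.period, n_bg)
    times = np.concatenate([t_sig, t_bg])
    hist, _ = np.histogram(times, bins=params.n_bins, range=(0.0, params.period))
    return hist.astype(np.int64)


def simulate_cube(
    params: DecayParams,
    n_rows: int,
    n_cols: int,
    rng_seed,
    *,
    fixed_counts: bool = False,
) -> TCSPCCube:
    """Simulate an image of independent pixels.

    Each pixel uses its own substream spawned from ``rng_seed`` via
    ``SeedSequence.spawn`` (row-major order), so the cube is bit-reproducible
    for a fixed seed and a pixel's photons never depend on other pixels.
    """
    if n_rows < 1 or n_cols < 1:
        raise ParameterError("n_rows and n_cols must be >= 1")
    ss = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    children = ss.spawn(n_rows * n_cols)
    counts = np.empty((n_rows, n_cols, params.n_bins), dtype=np.int64)
    for idx, child in enumerate(children):
        r, c = divmod(idx, n_cols)
        counts[r, c] = simulate_pixel(params, child, fixed_counts=fixed_counts)
    return TCSPCCube(counts=counts, bin_width=params.bin_width, period=params.period, params=params)


def mean_lifetime_of_params(params: DecayParams) -> float:
    """Ground-truth intensity-weighted mean lifetime, ns.

    ``frac1 * tau1 + (1 - frac1) * tau2`` — the quantity a mean-lifetime
    fit should recover from the simulated mixture.
    """
    return params.frac1 * params.tau1 + (1.0 - params.frac1) * params.tau2
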