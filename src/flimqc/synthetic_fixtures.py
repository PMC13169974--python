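"""Synthetic large-area FLIM mosaics with controllable regional structure.

Real large-area FLIM acquisitions are mosaics of thousands of tiles with
regional lifetime/intensity structure, row-wise intensity striping from
imperfect z-plane estimation, and occasional blank tiles where the detector
overloaded and the tile was dropped.  This module fabricates intensity /
mean-lifetime image pairs with those features so that every QC and
separability stage is testable without any real acquisition.

Per pixel, intensity is Poisson around the region's mean (times the stripe
factor of its tile row), and the fitted mean lifetime is Gaussian around
the region's mean with a standard deviation inflated by
``sqrt(reference_intensity / intensity)`` — a photon-limited precision rule
emulating the fact that lifetime estimates from fewer photons are less
precise.  The fixture *emulates* that behaviour; it does not reproduce any
particular estimator's variance curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .exceptions import ParameterError
from .qc_maps import ScalarMap
from .separability import ImagePool

__all__ = [
    "Region",
    "MosaicSpec",
    "generate_mosaic",
    "generate_pool",
    "striped_two_region_spec",
    "mosaic_spec_to_yaml",
    "mosaic_spec_from_yaml",
]


@dataclass(frozen=True)
class Region:
    """A painted region of the mosaic.

    ``geometry`` is ``"full"`` (covers everything; use for the base layer),
    ``"rect"`` with ``bounds=(r0, c0, r1, c1)`` half-open pixel bounds, or
    ``"ellipse"`` with ``bounds=(center_row, center_col, semi_r, semi_c)``.
    Later regions overwrite earlier ones.
    """

    label: str
    geometry: str
    bounds: tuple
    tau_ps: float
    tau_sd_ps: float
    intensity: float

    def __post_init__(self):
        if self.geometry not in ("full", "rect", "ellipse"):
            raise ParameterError(f"unknown geometry {self.geometry!r}")
        if self.tau_sd_ps < 0 or self.intensity < 0:
            raise ParameterError("tau_sd_ps and intensity must be >= 0")


@dataclass(frozen=True)
class MosaicSpec:
    """Full description of a synthetic mosaic; deterministic given ``seed``."""

    regions: tuple
    tile_shape: tuple = (64, 64)
    grid_shape: tuple = (4, 4)
    stripe_amplitude: float = 0.0
    overload_tiles: tuple = ()
    seed: int = 0
    reference_intensity: float | None = None

    def __post_init__(self):
        if len(self.regions) == 0:
            raise ParameterError("at least one region (the base layer) is required")
        if self.regions[0].geometry != "full":
            raise ParameterError("regions[0] must have geometry 'full' (base layer)")
        if min(self.tile_shape) < 1 or min(self.grid_shape) < 1:
            raise ParameterError("tile and grid dimensions must be >= 1")
        if not 0.0 <= self.stripe_amplitude < 1.0:
            raise ParameterError("stripe_amplitude must lie in [0, 1)")

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        return (
            self.tile_shape[0] * self.grid_shape[0],
            self.tile_shape[1] * self.grid_shape[1],
        )


def _label_map(spec: MosaicSpec) -> np.ndarray:
    rows, cols = spec.mosaic_shape
    label = np.zeros((rows, cols), dtype=np.int32)
    rr, cc = np.mgrid[0:rows, 0:cols]
    for i, reg in enumerate(spec.regions[1:], start=1):
        if reg.geometry == "full":
            label[:] = i
        elif reg.geometry == "rect":
            r0, c0, r1, c1 = reg.bounds
            label[r0:r1, c0:c1] = i
        else:  # ellipse
            cr, cc0, ar, ac = reg.bounds
            inside = ((rr - cr) / ar) ** 2 + ((cc - cc0) / ac) ** 2 <= 1.0
            label[inside] = i
    return label


def generate_mosaic(spec: MosaicSpec) -> tuple[ScalarMap, ScalarMap, np.ndarray]:
    """Render the mosaic: (intensity map, lifetime map [ps], label map).

    Overloaded tiles are all-NaN in both maps and labelled -1.
    """
    rng = np.random.default_rng(spec.seed)
    label = _label_map(spec)
    tau_mean = np.array([r.tau_ps for r in spec.regions])[label]
    tau_sd = np.array([r.tau_sd_ps for r in spec.regions])[label]
    int_mean = np.array([r.intensity for r in spec.regions])[label].astype(float)

    if spec.stripe_amplitude > 0:
        tile_row = np.arange(spec.mosaic_shape[0]) // spec.tile_shape[0]
        stripe = 1.0 + spec.stripe_amplitude * np.where(tile_row % 2 == 0, 1.0, -1.0)
        int_mean = int_mean * stripe[:, None]

    intensity = rng.poisson(int_mean).astype(float)

    ref = spec.reference_intensity
    if ref is None:
        ref = max(r.intensity for r in spec.regions)
    # photon-limited precision: fewer photons -> noisier lifetime estimate
    scale = np.sqrt(ref / np.clip(intensity, 1.0, None)) if ref > 0 else 1.0
    lifetime = rng.normal(tau_mean, tau_sd * scale)

    for tr, tc in spec.overload_tiles:
        rs = slice(tr * spec.tile_shape[0], (tr + 1) * spec.tile_shape[0])
        cs = slice(tc * spec.tile_shape[1], (tc + 1) * spec.tile_shape[1])
        intensity[rs, cs] = np.nan
        lifetime[rs, cs] = np.nan
        label[rs, cs] = -1

    return (
        ScalarMap(intensity, kind="intensity", units="photons"),
        ScalarMap(lifetime, kind="lifetime_ps", units="ps"),
        label,
    )


def striped_two_region_spec(
    *,
    tile_shape: tuple = (64, 64),
    grid_shape: tuple = (4, 4),
    base_tau_ps: float = 1500.0,
    low_tau_ps: float = 1200.0,
    tau_sd_ps: float = 50.0,
    base_intensity: float = 80.0,
    low_intensity: float = 12.0,
    stripe_amplitude: float = 0.15,
    overload_tiles: tuple = ((0, 0),),
    seed: int = 0,
) -> MosaicSpec:
    """Canonical test mosaic: a bright base with a dim rectangular region.

    The dim region receives the same nominal lifetime SD but far fewer
    photons, so its realized lifetime CV (hence F') is higher — the fixture
    analogue of a low-SNR area in a tissue mosaic.
    """
    rows = tile_shape[0] * grid_shape[0]
    cols = tile_shape[1] * grid_shape[1]
    regions = (
        Region("base", "full", (), base_tau_ps, tau_sd_ps, base_intensity),
        Region(
            "low_snr",
            "rect",
            (rows // 2, cols // 2, rows, cols),
            low_tau_ps,
            tau_sd_ps,
            low_intensity,
        ),
    )
    return MosaicSpec(
        regions=regions,
        tile_shape=tile_shape,
        grid_shape=grid_shape,
        stripe_amplitude=stripe_amplitude,
        overload_tiles=overload_tiles,
        seed=seed,
        reference_intensity=base_intensity,
    )


def generate_pool(
    spec: MosaicSpec,
    n_images: int,
    jitter: float,
    seed: int | None = None,
    *,
    return_truth: bool = False,
):
    """Pool of single-tile lifetime images with jittered per-image means.

    Each image is a one-tile mosaic rendered from ``spec`` with every
    region's mean lifetime shifted by a common N(0, jitter^2) draw —
    emulating inter-ROI variability within one sample.  Returns an
    :class:`~flimqc.separability.ImagePool`; with ``return_truth=True`` also
    returns the per-image true (area-weighted) mean lifetimes.
    """
    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    if jitter < 0:
        raise ParameterError("jitter must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    images, truths = [], []
    for _ in range(n_images):
        dtau = float(rng.normal(0.0, jitter)) if jitter > 0 else 0.0
        sub = replace(
            spec,
            regions=tuple(replace(r, tau_ps=r.tau_ps + dtau) for r in spec.regions),
            grid_shape=(1, 1),
            stripe_amplitude=0.0,
            overload_tiles=(),
            seed=int(rng.integers(0, 2**31)),
        )
        _, lifetime, label = generate_mosaic(sub)
        images.append(lifetime)
        taus = np.array([r.tau_ps + dtau for r in sub.regions])
        counts = np.bincount(label[label >= 0].ravel(), minlength=len(sub.regions))
        truths.append(float(np.average(taus, weights=counts)))
    pool = ImagePool(images=images, label="synthetic")
    return (pool, truths) if return_truth else pool


def mosaic_spec_to_yaml(spec: MosaicSpec, path) -> None:
    """Write a spec as a human-readable YAML config."""
    doc = {
        "tile_shape": list(spec.tile_shape),
        "grid_shape": list(spec.grid_shape),
        "stripe_amplitude": spec.stripe_amplitude,
        "overload_tiles": [list(t) for t in spec.overload_tiles],
        "seed": spec.seed,
        "reference_intensity": spec.reference_intensity,
        "regions": [
            {
                "label": r.label,
                "geometry": r.geometry,
                "bounds": list(r.bounds),
                "tau_ps": r.tau_ps,
                "tau_sd_ps": r.tau_sd_ps,
                "intensity": r.intensity,
            }
            for r in spec.regions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def mosaic_spec_from_yaml(path) -> MosaicSpec:
    """Read a spec written by :func:`mosaic_spec_to_yaml`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    regions = tuple(
        Region(
            label=r["label"],
            geometry=r["geometry"],
            bounds=tuple(r["bounds"]),
            tau_ps=float(r["tau_ps"]),
            tau_sd_ps=float(r["tau_sd_ps"]),
            intensity=float(r["intensity"]),
        )
        for r in doc["regions"]
    )
    return MosaicSpec(
        regions=regions,
        tile_shape=tuple(doc["tile_shape"]),
        grid_shape=tuple(doc["grid_shape"]),
        stripe_amplitude=float(doc["stripe_amplitude"]),
        overload_tiles=tuple(tuple(t) for t in doc["overload_tiles"]),
        seed=int(doc["seed"]),
        reference_intensity=doc.get("reference_intensity"),
    )
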