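"""Readers and writers for the package's on-disk conventions.

Scalar maps are single-channel TIFFs (float for lifetime/CV/F', integer or
float for intensity) with NaN encoding excluded pixels; a JSON blob in the
TIFF description tag carries the map kind and units.  Decay cubes are
multi-page 16-bit TIFFs (time bins as pages) with a JSON sidecar holding the
period, bin width and simulation parameters so a cube round-trips
bit-exactly.  Masks are written both as 8-bit TIFF and PNG (0/255).  Every
CLI run writes a plain-text manifest logging all decided parameters, so a
published analysis is auditable and re-runnable.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .decay_sim import DecayParams, TCSPCCube
from .exceptions import FormatError
from .phasor import PhasorCloud
from .qc_maps import MaskSet, ScalarMap

__all__ = [
    "read_scalar_map",
    "write_scalar_map",
    "write_cube",
    "read_cube",
    "write_mask_set",
    "write_phasor_cloud",
    "write_manifest",
    "load_image_pool",
]


def write_scalar_map(smap: ScalarMap, path) -> None:
    """Write a ScalarMap as a single-channel TIFF with JSON metadata tag."""
    meta = json.dumps({"kind": smap.kind, "units": smap.units})
    tifffile.imwrite(path, smap.values, description=meta)


def read_scalar_map(path, kind: str | None = None, units: str | None = None) -> ScalarMap:
    """Read a single-channel TIFF as a ScalarMap.

    ``kind``/``units`` override the file's metadata when given (e.g. for
    files produced by other software without our description tag).
    Integer data are converted losslessly to float; NaN survives in float
    inputs.  Multi-channel/RGB files are rejected.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"no such file: {p}")
    try:
        with tifffile.TiffFile(p) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description or ""
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"{p} is not a readable TIFF: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(
            f"{p}: expected a single-channel 2-D image, got shape {arr.shape}; "
            "multi-channel/RGB and multi-page maps are not scalar maps"
        )
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    return ScalarMap(
        arr.astype(float),
        kind=kind or meta.get("kind", "auxiliary"),
        units=units if units is not None else meta.get("units", ""),
    )


def _cube_sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_cube(cube: TCSPCCube, path, seed=None) -> None:
    """Write a decay cube as a multi-page uint16 TIFF plus a JSON sidecar."""
    if cube.counts.max(initial=0) >= 2**16:
        raise FormatError("cube counts exceed the uint16 range of the TIFF format")
    pages = cube.counts.transpose(2, 0, 1).astype(np.uint16)
    tifffile.imwrite(path, pages)
    meta = {
        "period_ns": cube.period,
        "bin_width_ns": cube.bin_width,
        "n_bins": cube.n_bins,
        "seed": seed,
        "params": None,
        "flimqc_version": __version__,
    }
    if cube.params is not None:
        p = cube.params
        meta["params"] = {
            "tau1": p.tau1,
            "tau2": p.tau2,
            "frac1": p.frac1,
            "period": p.period,
            "n_photons": p.n_photons,
            "background": p.background,
            "n_bins": p.n_bins,
        }
    _cube_sidecar(path).write_text(json.dumps(meta, indent=2))


def read_cube(path) -> TCSPCCube:
    """Read a cube written by :func:`write_cube` (bit-exact round trip)."""
    p = Path(path)
    if not p.exists():
        raise FormatError(f"no such file: {p}")
    pages = tifffile.imread(p)
    if pages.ndim != 3:
        raise FormatError(f"{p}: expected a multi-page (time, row, col) TIFF")
    sidecar = _cube_sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing cube sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    params = None
    if meta.get("params"):
        params = DecayParams(**meta["params"])
    return TCSPCCube(
        counts=pages.transpose(1, 2, 0).astype(np.int64),
        bin_width=float(meta["bin_width_ns"]),
        period=float(meta["period_ns"]),
        params=params,
    )


def write_mask_set(mask_set: MaskSet, out_dir, prefix: str = "mask") -> list[Path]:
    """Write each mask as 8-bit TIFF + PNG (0/255) and the stats as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for label, mask in mask_set.masks.items():
        img = (mask.astype(np.uint8)) * 255
        safe = label.replace("/", "_").replace(" ", "_")
        tif = out / f"{prefix}_{safe}.tif"
        png = out / f"{prefix}_{safe}.png"
        tifffile.imwrite(tif, img)
        iio.imwrite(png, img)
        written += [tif, png]
    csv = out / f"{prefix}_stats.csv"
    mask_set.stats.to_csv(csv, index=False)
    written.append(csv)
    return written


def write_phasor_cloud(cloud: PhasorCloud, tif_path=None, csv_path=None) -> None:
    """Export a phasor cloud as a 2-channel float32 TIFF and/or a CSV.

    CSV columns: row, col, g, s, counts (finite pixels only).
    """
    if tif_path is not None:
        stack = np.stack([cloud.g, cloud.s]).astype(np.float32)
        tifffile.imwrite(
            tif_path,
            stack,
            photometric="minisblack",
            description=json.dumps(
                {"channels": ["g", "s"], "omega": cloud.omega, "harmonic": cloud.harmonic}
            ),
        )
    if csv_path is not None:
        m = cloud.finite_mask()
        rr, cc = np.nonzero(m)
        pd.DataFrame(
            {
                "row": rr,
                "col": cc,
                "g": cloud.g[m],
                "s": cloud.s[m],
                "counts": np.asarray(cloud.total_counts)[m],
            }
        ).to_csv(csv_path, index=False)


def write_manifest(path, entries: dict) -> None:
    """Plain-text run manifest: one ``key: value`` line per decided parameter."""
    lines = [f"flimqc_version: {__version__}"]
    lines += [f"{k}: {v}" for k, v in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_image_pool(source, label: str | None = None, group: str | None = None):
    """Load an ImagePool from a directory of TIFFs or a CSV manifest.

    A directory pools every ``*.tif``/``*.tiff`` inside it.  A CSV manifest
    must have columns ``path`` and ``group``; ``group`` selects the rows.
    Returns a single pool (directory mode or CSV+group) or a dict of pools
    keyed by group (CSV without ``group``).
    """
    from .separability import ImagePool

    src = Path(source)
    if src.is_dir():
        paths = sorted(list(src.glob("*.tif")) + list(src.glob("*.tiff")))
        if not paths:
            raise FormatError(f"no TIFF files in {src}")
        images = [read_scalar_map(p) for p in paths]
        return ImagePool(images=images, label=label or src.name)
    if not src.exists():
        raise FormatError(f"no such file or directory: {src}")
    table = pd.read_csv(src)
    if not {"path", "group"} <= set(table.columns):
        raise FormatError(f"{src}: manifest CSV needs 'path' and 'group' columns")
    base = src.parent
    pools = {}
    for grp, sub in table.groupby("group"):
        images = [
            read_scalar_map(p if Path(p).is_absolute() else base / p)
            for p in sub["path"]
        ]
        pools[str(grp)] = ImagePool(images=images, label=str(grp))
    if group is not None:
        if group not in pools:
            raise FormatError(f"group {group!r} not present in {src}")
        return pools[group]
    return pools
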