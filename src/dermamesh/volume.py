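"""Scalar volumes: slice-stack readers, raster export, and synthetic fields.

A :class:`ScalarVolume` is the field ``f(X, Y, Z)`` sampled on a regular
grid with per-axis physical spacing.  Grid index ``(x, y, z)`` maps to the
physical point ``origin + (x * dX, y * dY, z * dZ)`` (0-based indices).

Slice stacks arrive either as a DICOM series or as 8/16-bit grayscale
raster images (BMP/PNG/JPEG); both are assembled into a volume with all
non-pixel metadata (patient identity, dates, device fields) discarded —
the returned object carries nothing but samples, spacing and origin.
Synthetic analytic fields (spheres, torus, ramps, band-limited noise)
stand in for scan data in tests and examples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np


class VolumeError(ValueError):
    """Invalid volume data or parameters."""


class DimensionMismatchError(VolumeError):
    """Slices in a stack do not share row/column dimensions."""


class InsufficientDataError(VolumeError):
    """Fewer than two slices: no 3D volume can be assembled."""


@dataclass(frozen=True)
class ScalarVolume:
    """A 3D scalar field on a regular grid.

    ``samples`` is indexed ``[x, y, z]``; ``spacing`` is physical units per
    index step, strictly positive on every axis.
    """

    samples: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 3 or min(samples.shape) < 2:
            raise VolumeError(f"volume must be 3D with >= 2 samples per axis, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise VolumeError("volume contains non-finite samples")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.samples.shape  # type: ignore[return-value]

    def physical_coords(self, index_coords: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) index coordinates to physical space."""
        return np.asarray(self.origin) + np.asarray(index_coords) * np.asarray(self.spacing)


@dataclass(frozen=True)
class SliceStackManifest:
    """Description of an ordered stack of 2D slices forming a volume."""

    paths: tuple[Path, ...]
    slice_spacing: float | None = None
    pixel_spacing: tuple[float, float] | None = None
    rescale: tuple[float, float] | None = None  # (slope, intercept) override
    window: tuple[float, float] | None = None  # (center, width); None = full range

    def __post_init__(self) -> None:
        object.__setattr__(self, "paths", tuple(Path(p) for p in self.paths))
        if len(self.paths) < 2:
            raise InsufficientDataError("a slice stack needs at least 2 slices")


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of a synthetic analytic field.

    kinds
        ``sphere``       signed distance ``radius - |p - center|`` (positive inside)
        ``two_spheres``  union (pointwise max) of two sphere fields
        ``torus``        ``tube_radius - sqrt((sqrt(px^2+py^2) - ring_radius)^2 + pz^2)``
                         around ``center``, axis along z
        ``linear_ramp``  ``a*X + b*Y + c*Z + d`` with ``gradient=(a, b, c)``, ``offset=d``
        ``smooth_noise`` seeded Gaussian white noise smoothed to a band-limited
                         field (reproducible for a given seed)
    """

    kind: str
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 1.0
    center2: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius2: float = 1.0
    ring_radius: float = 1.0
    tube_radius: float = 0.25
    gradient: tuple[float, float, float] = (1.0, 0.0, 0.0)
    offset: float = 0.0
    smoothing: float = 2.0
    seed: int = 0

    _KINDS = ("sphere", "two_spheres", "torus", "smooth_noise", "linear_ramp")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise VolumeError(f"unknown field kind {self.kind!r}; expected one of {self._KINDS}")
        if self.kind in ("sphere", "two_spheres") and self.radius <= 0:
            raise VolumeError("sphere radius must be positive")
        if self.kind == "two_spheres" and self.radius2 <= 0:
            raise VolumeError("second sphere radius must be positive")
        if self.kind == "torus" and (self.ring_radius <= 0 or self.tube_radius <= 0):
            raise VolumeError("torus radii must be positive")


def generate_volume(
    spec: FieldSpec,
    dims: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ScalarVolume:
    """Evaluate an analytic field on a regular grid."""
    if any(d < 2 for d in dims):
        raise VolumeError(f"dims must be >= 2 per axis, got {dims}")
    x = origin[0] + spacing[0] * np.arange(dims[0])
    y = origin[1] + spacing[1] * np.arange(dims[1])
    z = origin[2] + spacing[2] * np.arange(dims[2])
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    def sphere(center, radius):
        return radius - np.sqrt(
            (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        )

    if spec.kind == "sphere":
        samples = sphere(spec.center, spec.radius)
    elif spec.kind == "two_spheres":
        samples = np.maximum(sphere(spec.center, spec.radius), sphere(spec.center2, spec.radius2))
    elif spec.kind == "torus":
        px, py, pz = X - spec.center[0], Y - spec.center[1], Z - spec.center[2]
        ring = np.sqrt(px**2 + py**2) - spec.ring_radius
        samples = spec.tube_radius - np.sqrt(ring**2 + pz**2)
    elif spec.kind == "linear_ramp":
        a, b, c = spec.gradient
        samples = a * X + b * Y + c * Z + spec.offset
    else:  # smooth_noise
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(spec.seed)
        samples = gaussian_filter(rng.standard_normal(dims), sigma=spec.smoothing)
    return ScalarVolume(samples=samples, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# raster slices


def convert_slice_to_raster(slice_2d: np.ndarray, window: tuple[float, float] | None = None) -> np.ndarray:
    """Map one scalar slice to an 8-bit grayscale raster.

    With ``window=None`` ("full range") the slice's own [min, max] maps
    linearly onto [0, 255]; a constant slice maps to 0.  An explicit
    ``(center, width)`` window maps ``center - width/2 .. center + width/2``
    onto [0, 255] with clipping.  The mapping is monotone non-decreasing.
    """
    data = np.asarray(slice_2d, dtype=np.float64)
    if window is None:
        lo, hi = float(data.min()), float(data.max())
        if hi == lo:
            return np.zeros(data.shape, dtype=np.uint8)
    else:
        center, width = window
        if width <= 0:
            raise VolumeError("window width must be positive")
        lo, hi = center - width / 2.0, center + width / 2.0
    scaled = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return np.rint(scaled * 255.0).astype(np.uint8)


def write_raster_stack(
    volume: ScalarVolume,
    directory: str | Path,
    fmt: str = "bmp",
    window: tuple[float, float] | None = None,
) -> list[Path]:
    """Export a volume as one 8-bit raster per z-slice (``slice_0000.bmp`` ...).

    A single window is derived from the whole volume (full range unless
    given) so all slices share one intensity mapping.
    """
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if window is None:
        lo, hi = float(volume.samples.min()), float(volume.samples.max())
        window = ((lo + hi) / 2.0, hi - lo) if hi > lo else None
    paths = []
    for z in range(volume.shape[2]):
        raster = convert_slice_to_raster(volume.samples[:, :, z], window)
        path = directory / f"slice_{z:04d}.{fmt}"
        # PIL images are (row, col) = (y, x); samples are [x, y]
        Image.fromarray(raster.T).save(path)
        paths.append(path)
    return paths


def load_raster_stack(
    source: str | Path | Sequence[str | Path],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ScalarVolume:
    """Stack grayscale raster images (lexicographic order for a directory)."""
    import imageio.v3 as iio

    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(
            p for p in Path(source).iterdir()
            if p.suffix.lower() in (".bmp", ".png", ".jpg", ".jpeg", ".tif", ".tiff")
        )
    else:
        paths = [Path(p) for p in source]  # type: ignore[union-attr]
    if len(paths) < 2:
        raise InsufficientDataError(f"need at least 2 raster slices, found {len(paths)}")
    slices = []
    shape = None
    for path in paths:
        img = np.asarray(iio.imread(path))
        if img.ndim == 3:  # collapse redundant channels
            img = img[..., 0]
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise DimensionMismatchError(
                f"slice {path.name} has shape {img.shape}, expected {shape}"
            )
        slices.append(img.astype(np.float64).T)  # (row, col) -> [x, y]
    return ScalarVolume(samples=np.stack(slices, axis=-1), spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# DICOM


def load_dicom_series(manifest: SliceStackManifest) -> ScalarVolume:
    """Assemble a DICOM series into a volume, stripping all non-pixel metadata.

    Slices are ordered by position along the stack normal when image
    positions are present, falling back to instance number, then to the
    manifest's file order.  Stored values are rescaled by the per-slice
    (or manifest override) slope/intercept.  Only pixel data, spacing and
    origin survive into the returned :class:`ScalarVolume`.
    """
    import pydicom

    datasets = []
    for path in manifest.paths:
        try:
            datasets.append((path, pydicom.dcmread(path)))
        except Exception as exc:  # noqa: BLE001 - name the offending slice
            raise IOError(f"cannot read DICOM slice {path}: {exc}") from exc
    if len(datasets) < 2:
        raise InsufficientDataError("a DICOM series needs at least 2 slices")

    def sort_key(item):
        idx, (_, ds) = item
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None and len(pos) == 3:
            return (0, float(pos[2]), idx)
        num = getattr(ds, "InstanceNumber", None)
        if num is not None:
            return (1, float(num), idx)
        return (2, 0.0, idx)  # tie-break: file order
    ordered = [ds for _, (_, ds) in sorted(enumerate(datasets), key=sort_key)]

    shape = None
    slices = []
    positions = []
    for ds in ordered:
        pixels = ds.pixel_array
        if shape is None:
            shape = pixels.shape
        elif pixels.shape != shape:
            raise DimensionMismatchError(
                f"mixed slice dimensions in series: {pixels.shape} vs {shape}"
            )
        if manifest.rescale is not None:
            slope, intercept = manifest.rescale
        else:
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(pixels.astype(np.float64).T * slope + intercept)
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None and len(pos) == 3:
            positions.append(tuple(float(v) for v in pos))

    if manifest.pixel_spacing is not None:
        dy, dx = manifest.pixel_spacing
    else:
        ps = getattr(ordered[0], "PixelSpacing", [1.0, 1.0])
        dy, dx = float(ps[0]), float(ps[1])
    if manifest.slice_spacing is not None:
        dz = manifest.slice_spacing
    elif len(positions) == len(ordered):
        gaps = np.diff([p[2] for p in positions])
        dz = float(abs(gaps).mean()) if len(gaps) and abs(gaps).min() > 0 else 1.0
    else:
        dz = float(getattr(ordered[0], "SliceThickness", 1.0) or 1.0)
    origin = positions[0][:2] + (positions[0][2],) if positions else (0.0, 0.0, 0.0)
    return ScalarVolume(
        samples=np.stack(slices, axis=-1),
        spacing=(dx, dy, dz),
        origin=(float(origin[0]), float(origin[1]), float(origin[2])),
    )


# ---------------------------------------------------------------------------
# raw grid with JSON sidecar


def save_volume_raw(volume: ScalarVolume, path: str | Path) -> Path:
    """Write a little-endian float32 grid plus a JSON sidecar (``.json``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    volume.samples.astype("<f4").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "dims": list(volume.shape),
        "dtype": "<f4",
        "order": "xyz",
        "spacing": list(volume.spacing),
        "origin": list(volume.origin),
    }, indent=2))
    return sidecar


def load_volume_raw(sidecar: str | Path) -> ScalarVolume:
    """Load a raw binary grid described by its JSON sidecar."""
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    raw = sidecar.with_suffix("")  # strip the trailing .json
    dims = tuple(meta["dims"])
    data = np.fromfile(raw, dtype=meta.get("dtype", "<f4"))
    if data.size != math.prod(dims):
        raise VolumeError(f"raw file {raw} has {data.size} samples, sidecar says {math.prod(dims)}")
    return ScalarVolume(
        samples=data.reshape(dims),
        spacing=tuple(meta.get("spacing", (1.0, 1.0, 1.0))),
        origin=tuple(meta.get("origin", (0.0, 0.0, 0.0))),
    )
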