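"""File formats, run configuration and provenance.

NPY float64 is the canonical interchange format for images and sinograms.
Lossy 16-bit TIFF/PNG exports are min-max scaled with the scaling recorded
in a JSON sidecar so values round-trip to within one quantization step.
Sinograms travel as NPY plus a JSON geometry sidecar (angles in radians,
spacing, offset) or as CSV with one row per angle.  DICOM pixel data is
readable (rescale slope/intercept applied) when pydicom is installed;
writing clinical DICOM is out of scope.

All writes are atomic (temp file + rename) and can carry a JSON provenance
sidecar recording the command, configuration hash, seeds and package
version, so any artifact can be traced to the run that produced it.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import os
import sys
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import ImageGrid, ProjectionGeometry, Sinogram

__all__ = [
    "read_image",
    "write_image",
    "read_sinogram",
    "write_sinogram",
    "write_sinogram_csv",
    "read_sinogram_csv",
    "RunConfig",
    "write_provenance",
]

log = logging.getLogger(__name__)

_VERSION = "0.1.0"


class FormatError(ValueError):
    """Raised for unreadable or inconsistent files."""


def _atomic_write_bytes(path: Path, data: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_text(path: Path, text: str) -> None:
    _atomic_write_bytes(Path(path), text.encode())


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def _center_crop_square(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape
    if h == w:
        return arr
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    log.info("center-cropping %dx%d input to %dx%d", h, w, side, side)
    return arr[r0 : r0 + side, c0 : c0 + side]


def write_image(path: str | os.PathLike, img: ImageGrid, *, provenance: dict | None = None) -> None:
    """Write an image as NPY (float64) or scaled 16-bit TIFF/PNG with sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        buf = _npy_bytes(img.pixels)
        _atomic_write_bytes(path, buf)
        meta = {"pixel_size": img.pixel_size, "format": "npy"}
    elif suffix in (".tif", ".tiff", ".png"):
        vmin = float(img.pixels.min())
        vmax = float(img.pixels.max())
        scale = (vmax - vmin) or 1.0
        scaled = np.round((img.pixels - vmin) / scale * 65535.0).astype(np.uint16)
        import imageio.v3 as iio

        data = iio.imwrite("<bytes>", scaled, extension=suffix)
        _atomic_write_bytes(path, data)
        meta = {"pixel_size": img.pixel_size, "format": suffix[1:], "vmin": vmin, "vmax": vmax, "bits": 16}
    else:
        raise FormatError(f"unsupported image format {suffix!r} for {path}")
    if provenance:
        meta["provenance"] = provenance
    _atomic_write_text(_sidecar(path), json.dumps(meta, indent=2, sort_keys=True))


def _npy_bytes(arr: np.ndarray) -> bytes:
    import io as _io

    buf = _io.BytesIO()
    np.save(buf, np.asarray(arr, dtype=float))
    return buf.getvalue()


def read_image(path: str | os.PathLike, pixel_size: float | None = None) -> ImageGrid:
    """Read NPY/TIFF/PNG/DICOM into the shared centered-coordinate convention.

    16-bit exports are rescaled through their JSON sidecar; DICOM applies
    rescale slope/intercept and takes the first frame of multi-frame data
    (with a warning).  Non-square inputs are center-cropped to square.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    meta: dict = {}
    side = _sidecar(path)
    if side.exists():
        try:
            meta = json.loads(side.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"corrupt sidecar for {path}: {exc}") from exc
    if suffix == ".npy":
        try:
            arr = np.load(path)
        except Exception as exc:
            raise FormatError(f"cannot read NPY file {path}: {exc}") from exc
    elif suffix in (".tif", ".tiff", ".png"):
        import imageio.v3 as iio

        try:
            raw = iio.imread(path).astype(float)
        except Exception as exc:
            raise FormatError(f"cannot read image file {path}: {exc}") from exc
        if raw.ndim == 3:
            raw = raw[..., 0]
        if "vmin" in meta and "vmax" in meta:
            scale = (meta["vmax"] - meta["vmin"]) or 1.0
            arr = raw / 65535.0 * scale + meta["vmin"]
        else:
            arr = raw
    elif suffix in (".dcm", ".dicom"):
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - pydicom optional
            raise ImportError(
                "DICOM reading requires the optional pydicom dependency"
            ) from exc
        ds = pydicom.dcmread(path)  # pragma: no cover
        arr = ds.pixel_array.astype(float)  # pragma: no cover
        if arr.ndim == 3:  # pragma: no cover
            import warnings

            warnings.warn("multi-frame DICOM: using the first frame")
            arr = arr[0]
        slope = float(getattr(ds, "RescaleSlope", 1.0))  # pragma: no cover
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))  # pragma: no cover
        arr = arr * slope + intercept  # pragma: no cover
    else:
        raise FormatError(f"unsupported image format {suffix!r} for {path}")
    arr = _center_crop_square(np.asarray(arr, dtype=float))
    if pixel_size is None:
        pixel_size = float(meta.get("pixel_size", 1.0))
    return ImageGrid(arr, pixel_size)


def write_sinogram(path: str | os.PathLike, sino: Sinogram, *, provenance: dict | None = None) -> None:
    """Write sinogram values as NPY with a JSON geometry sidecar."""
    path = Path(path)
    _atomic_write_bytes(path, _npy_bytes(sino.values))
    geom = sino.geometry
    meta = {
        "angles_rad": geom.angles.tolist(),
        "n_detectors": geom.n_detectors,
        "detector_spacing": geom.detector_spacing,
        "detector_center_offset": geom.detector_center_offset,
    }
    if provenance:
        meta["provenance"] = provenance
    _atomic_write_text(_sidecar(path), json.dumps(meta, indent=2, sort_keys=True))


def read_sinogram(path: str | os.PathLike) -> Sinogram:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"missing geometry sidecar {side}")
    meta = json.loads(side.read_text())
    values = np.load(path)
    geom = ProjectionGeometry(
        angles=np.asarray(meta["angles_rad"], dtype=float),
        n_detectors=int(meta["n_detectors"]),
        detector_spacing=float(meta["detector_spacing"]),
        detector_center_offset=float(meta["detector_center_offset"]),
    )
    if values.shape != (geom.n_angles, geom.n_detectors):
        raise FormatError(
            f"sinogram array shape {values.shape} does not match sidecar geometry "
            f"({geom.n_angles}, {geom.n_detectors})"
        )
    return Sinogram(values, geom)


def write_sinogram_csv(path: str | os.PathLike, sino: Sinogram) -> None:
    """CSV export: one row per angle, first column the angle in radians."""
    path = Path(path)
    geom = sino.geometry
    lines = ["angle_rad," + ",".join(f"bin_{i}" for i in range(geom.n_detectors))]
    for alpha, row in zip(geom.angles, sino.values):
        lines.append(",".join(f"{v:.12g}" for v in (alpha, *row)))
    meta = {
        "detector_spacing": geom.detector_spacing,
        "detector_center_offset": geom.detector_center_offset,
    }
    _atomic_write_text(path, "\n".join(lines) + "\n")
    _atomic_write_text(_sidecar(path), json.dumps(meta, indent=2, sort_keys=True))


def read_sinogram_csv(path: str | os.PathLike) -> Sinogram:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if not header or header[0] != "angle_rad":
            raise FormatError(f"{path} is not a sinogram CSV (missing angle_rad header)")
        rows = [[float(v) for v in row] for row in reader if row]
    data = np.asarray(rows)
    angles = data[:, 0]
    values = data[:, 1:]
    geom = ProjectionGeometry(
        angles=angles,
        n_detectors=values.shape[1],
        detector_spacing=float(meta.get("detector_spacing", 1.0)),
        detector_center_offset=float(meta.get("detector_center_offset", 0.0)),
    )
    return Sinogram(values, geom)


@dataclass
class RunConfig:
    """A fully serializable description of one reconstruction run."""

    algorithm: str = "fbp"
    filter_name: str = "ram-lak"
    filter_cutoff: float = 1.0
    n_angles: int = 180
    grid_size: int = 256
    pixel_size: float = 1.0
    block_size: int = 32
    overlap_step: int = 16
    noise_model: str = "none"
    noise_level: float = 0.0
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path: str | os.PathLike) -> None:
        _atomic_write_text(Path(path), yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_provenance(path: str | os.PathLike, config: RunConfig | None = None, **extra) -> dict:
    """Write a JSON provenance record (command line, config hash, seeds, version)."""
    record = {
        "command": sys.argv,
        "version": _VERSION,
        **extra,
    }
    if config is not None:
        record["config_hash"] = config.digest()
        record["seed"] = config.seed
    _atomic_write_text(Path(path), json.dumps(record, indent=2, sort_keys=True))
    return record
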