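"""Reading and writing image stacks, masks and sidecar metadata.

Stacks are plain multi-page TIFFs (or directories of single-slice TIFFs in
lexicographic order), 8- or 16-bit, with z the slice axis. Plain TIFF does
not carry the voxel size, so it travels in a YAML sidecar ``<stem>.yaml``
next to the stack; an explicit ``voxel_size_um`` argument wins over the
sidecar, with a logged warning on conflict.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .volume import ImageVolume

__all__ = ["read_stack", "write_stack", "read_mask", "write_mask"]

logger = logging.getLogger(__name__)

_SUPPORTED = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml") if path.suffix else path / "stack.yaml"


def read_stack(path: str | Path, voxel_size_um: float | None = None) -> ImageVolume:
    """Read a multi-page TIFF or a directory of single-slice TIFFs.

    Raises on inconsistent slice shapes or mixed/unsupported bit depths.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF slices in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
        dtypes = {s.dtype for s in slices}
        if len(dtypes) != 1:
            raise ValueError(f"mixed slice bit depths: {sorted(str(d) for d in dtypes)}")
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    if data.dtype not in _SUPPORTED:
        raise ValueError(f"unsupported bit depth / dtype: {data.dtype}")
    bit_depth = _SUPPORTED[data.dtype]

    sidecar = _sidecar_path(path)
    sidecar_vs = None
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        sidecar_vs = meta.get("voxel_size_um")
    if voxel_size_um is not None:
        if sidecar_vs is not None and abs(sidecar_vs - voxel_size_um) > 1e-12:
            logger.warning("voxel size %.6g from config overrides sidecar value %.6g",
                           voxel_size_um, sidecar_vs)
        vs = voxel_size_um
    elif sidecar_vs is not None:
        vs = float(sidecar_vs)
    else:
        vs = 3.75
        logger.warning("no voxel size given; defaulting to %.3g um", vs)
    return ImageVolume(data, voxel_size_um=vs, bit_depth=bit_depth)


def write_stack(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF plus a YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.astype_quantized())
    _sidecar_path(path).write_text(
        yaml.safe_dump({"voxel_size_um": float(volume.voxel_size_um),
                        "bit_depth": int(volume.bit_depth)}))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary TIFF stack (nonzero = foreground)."""
    data = tifffile.imread(Path(path))
    if data.ndim == 2:
        data = data[None]
    return data > 0


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit TIFF stack (255 = foreground)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path
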