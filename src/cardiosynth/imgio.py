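"""Grayscale image and label-mask I/O.

Float images in [0, 1] are serialized as 16-bit PNG (quantization error
bounded by 1/65535) or as float32 NIfTI; label masks as 8-bit PNG or uint8
NIfTI, preserved exactly.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

_PNG = {".png"}
_NIFTI_SUFFIXES = ((".nii",), (".nii", ".gz"))


def _is_nifti(path: Path) -> bool:
    s = tuple(path.suffixes[-2:])
    return s in _NIFTI_SUFFIXES or (s and s[-1] == ".nii")


def _as_2d(arr: np.ndarray, path) -> np.ndarray:
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected single-channel 2-D data, got shape {arr.shape}")
    return arr


def read_image(path) -> np.ndarray:
    """Read a grayscale image as float32 in [0, 1]."""
    path = Path(path)
    try:
        if path.suffix in _PNG:
            arr = iio.imread(path)
            arr = _as_2d(arr, path)
            if arr.dtype == np.uint16:
                return (arr / 65535.0).astype(np.float32)
            if arr.dtype == np.uint8:
                return (arr / 255.0).astype(np.float32)
            return arr.astype(np.float32)
        if _is_nifti(path):
            arr = np.asanyarray(nib.load(str(path)).dataobj)
            return _as_2d(arr, path).astype(np.float32)
    except (ValueError, OSError):
        raise
    except Exception as e:
        raise ValueError(f"could not parse image file {path}: {e}") from e
    raise ValueError(f"unsupported image format: {path}")


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("only 2-D grayscale images are supported")
    if path.suffix in _PNG:
        q = np.clip(np.round(image * 65535.0), 0, 65535).astype(np.uint16)
        iio.imwrite(path, q)
        return
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(image.astype(np.float32), np.eye(4)),
                 str(path))
        return
    raise ValueError(f"unsupported image format: {path}")


def read_mask(path) -> np.ndarray:
    path = Path(path)
    try:
        if path.suffix in _PNG:
            return _as_2d(iio.imread(path), path).astype(np.uint8)
        if _is_nifti(path):
            arr = np.asanyarray(nib.load(str(path)).dataobj)
            return _as_2d(arr, path).astype(np.uint8)
    except (ValueError, OSError):
        raise
    except Exception as e:
        raise ValueError(f"could not parse mask file {path}: {e}") from e
    raise ValueError(f"unsupported mask format: {path}")


def write_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("only 2-D masks are supported")
    if path.suffix in _PNG:
        iio.imwrite(path, mask.astype(np.uint8))
        return
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), str(path))
        return
    raise ValueError(f"unsupported mask format: {path}")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
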