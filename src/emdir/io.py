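"""Grayscale image reading/writing and component montages."""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)


def load_image(path) -> np.ndarray:
    """Read an 8/16-bit PNG or TIFF as float64 intensities in [0, 1].

    Multi-channel inputs are converted to luminance with a logged warning.
    """
    raw = iio.imread(path)
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
    else:
        scale = max(float(raw.max()), 1.0)
    if raw.ndim == 3:
        logger.warning("%s has %d channels; converting to luminance", path, raw.shape[-1])
        rgb = raw[..., :3].astype(np.float64)
        arr = rgb @ np.array([0.2126, 0.7152, 0.0722])
    else:
        arr = raw.astype(np.float64)
    return arr / scale


def save_image_16bit(path, image: np.ndarray) -> None:
    """Write intensities in [0, 1] as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 65535.0 + 0.5).astype(np.uint16))


def save_stack_hdf5(path, stack) -> None:
    """Persist an IMF stack as HDF5 datasets ``imf1..imfN`` and ``residual``."""
    with h5py.File(path, "w") as fh:
        for i, imf in enumerate(stack.imfs, start=1):
            fh.create_dataset(f"imf{i}", data=imf)
        fh.create_dataset("residual", data=stack.residual)
        fh.attrs["n_imfs"] = stack.n_imfs
        fh.attrs["source_shape"] = stack.source_shape


def load_stack_hdf5(path):
    from .emd import IMFStack

    with h5py.File(path, "r") as fh:
        n = int(fh.attrs["n_imfs"])
        imfs = [fh[f"imf{i}"][...] for i in range(1, n + 1)]
        residual = fh["residual"][...]
        shape = tuple(int(v) for v in fh.attrs["source_shape"])
    return IMFStack(imfs=imfs, residual=residual, source_shape=shape)


def component_montage(image: np.ndarray, stack, pad: int = 2) -> np.ndarray:
    """Tile original, IMFs and residual into one image, each tile rescaled."""
    tiles = [image] + list(stack.imfs) + [stack.residual]
    scaled = []
    for t in tiles:
        lo, hi = float(t.min()), float(t.max())
        scaled.append((t - lo) / (hi - lo) if hi > lo else np.zeros_like(t))
    h, w = image.shape
    out = np.ones((h, (w + pad) * len(scaled) - pad))
    for i, t in enumerate(scaled):
        out[:, i * (w + pad) : i * (w + pad) + w] = t
    return out
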