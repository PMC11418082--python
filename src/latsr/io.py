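"""Checkpoint and image file plumbing.

Value convention: generators and the latent search work on images in [-1, 1];
files on disk (PNG / TIFF) hold values in [0, 1] (or integer codes for 8/16-bit
files).  ``to_internal`` / ``from_internal`` convert between the two.

Checkpoints are single-file archives (numpy ``.npz``) holding named parameter
arrays plus a JSON header with the structural metadata (``kind``, dimensions,
``format_version``); any externally trained model matching the declared
contract can be loaded.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# value-range conventions
# ---------------------------------------------------------------------------

def to_internal(img01: np.ndarray) -> np.ndarray:
    """Map a [0, 1] image to the internal [-1, 1] range."""
    return np.asarray(img01, dtype=np.float64) * 2.0 - 1.0


def from_internal(img: np.ndarray, clip: bool = True) -> np.ndarray:
    """Map an internal [-1, 1] image to [0, 1]."""
    out = (np.asarray(img, dtype=np.float64) + 1.0) / 2.0
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, header: dict, arrays: dict) -> None:
    """Write a checkpoint: JSON header + named float arrays in one archive."""
    header = dict(header)
    header["format_version"] = FORMAT_VERSION
    payload = {f"param/{k}": np.asarray(v, dtype=np.float64) for k, v in arrays.items()}
    payload["_header"] = np.frombuffer(json.dumps(header).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path):
    """Read a checkpoint; returns (header dict, arrays dict)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as z:
        header = json.loads(bytes(z["_header"].tobytes()).decode("utf-8"))
        arrays = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    return header, arrays


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image into a (C, H, W) float array in [0, 1].

    Multi-channel TIFFs are accepted either as C pages or as C
    samples-per-pixel; 8- and 16-bit integer files are scaled by their dtype
    maximum, float files are taken as already being in [0, 1].
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from PIL import Image as PILImage

        arr = np.asarray(PILImage.open(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3:
        # channels last (samples-per-pixel) vs channels first (pages)
        if arr.shape[-1] <= 4 < arr.shape[0]:
            arr = np.moveaxis(arr, -1, 0)
        elif arr.shape[0] <= 4:
            pass
        else:
            arr = np.moveaxis(arr, -1, 0)
    else:
        raise ValueError(f"unsupported image rank {arr.ndim} for {path}")
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        return arr.astype(np.float64) / scale
    return arr.astype(np.float64)


def write_image(path, img01: np.ndarray, bitdepth: int = 16) -> None:
    """Write a (C, H, W) [0, 1] image; TIFF as samples-per-pixel, PNG 8/16-bit."""
    path = Path(path)
    img01 = np.clip(np.asarray(img01, dtype=np.float64), 0.0, 1.0)
    if img01.ndim == 2:
        img01 = img01[None]
    dtype = np.uint16 if bitdepth == 16 else np.uint8
    scaled = np.round(img01 * np.iinfo(dtype).max).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.moveaxis(scaled, 0, -1))
    else:
        from PIL import Image as PILImage

        arr = np.moveaxis(scaled, 0, -1).squeeze()
        if bitdepth == 16 and arr.ndim == 3:
            # PNG 16-bit multichannel support is patchy; fall back to 8-bit
            arr = (arr // 257).astype(np.uint8)
        PILImage.fromarray(arr).save(path)
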