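"""Readers and writers for images and overlapping label sets.

Images travel as TIFF or PNG.  Labels travel in one of two dialects:

* **multi-page TIFF** — one binary page per instance, page order = mask order;
* **RLE JSON sidecar** — ``{"height": H, "width": W, "masks": [...]}`` where
  each mask is a list of ``[row, start_col, length]`` runs (0-based,
  row-major).  See ``docs/formats.md``.

Both dialects round-trip bit-exactly, preserving overlap and mask order.
Flat single-channel *integer-coded* label images (the conventional
non-overlapping format) are accepted on import only and split into one mask
per nonzero integer, in increasing integer order.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .datamodel import (
    FormatError,
    Image,
    InstanceLabelSet,
    InstanceMask,
    Scene,
    ShapeError,
    normalize_image,
)

_IMAGE_EXTS = {".tif", ".tiff", ".png"}


def read_image(path: str | Path) -> Image:
    """Load a TIFF/PNG image, normalizing each channel to [0, 1]."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _IMAGE_EXTS:
        raise FormatError(f"unsupported image extension {ext!r} (use TIFF or PNG)")
    if ext == ".png":
        arr = np.asarray(iio.imread(path))
    else:
        arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] <= 4 and arr.shape[0] < arr.shape[2]:
        # channels-first TIFF convention
        arr = np.moveaxis(arr, 0, -1)
    return Image(normalize_image(arr))


def write_image(image: Image, path: str | Path) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    px = image.pixels
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, px.astype(np.float32))
    elif ext == ".png":
        arr = np.clip(px * 255.0 + 0.5, 0, 255).astype(np.uint8)
        iio.imwrite(path, arr.squeeze())
    else:
        raise FormatError(f"unsupported image extension {ext!r}")


def masks_to_rle(labels: InstanceLabelSet) -> dict:
    """Encode a label set as the JSON-ready run-length dictionary."""
    if len(labels) == 0:
        raise ValueError("refusing to encode an empty label set")
    h, w = labels.shape
    masks = []
    for m in labels:
        runs = []
        for row in range(h):
            line = m.pixels[row]
            # run starts/ends via diff of the padded boolean line
            d = np.diff(np.concatenate(([0], line.view(np.int8), [0])))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            runs.extend(
                [int(row), int(s), int(e - s)] for s, e in zip(starts, ends)
            )
        masks.append(runs)
    return {"height": h, "width": w, "masks": masks}


def rle_to_masks(doc: dict) -> InstanceLabelSet:
    h, w = int(doc["height"]), int(doc["width"])
    masks = []
    for runs in doc["masks"]:
        px = np.zeros((h, w), dtype=bool)
        for row, start, length in runs:
            if not (0 <= row < h and 0 <= start and start + length <= w):
                raise FormatError("RLE run out of bounds")
            px[row, start : start + length] = True
        masks.append(InstanceMask(px))
    if not masks:
        raise FormatError("label file contains no masks")
    return InstanceLabelSet(tuple(masks))


def read_labels(path: str | Path) -> InstanceLabelSet:
    """Read labels from a multi-page TIFF stack or an RLE JSON sidecar."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".json":
        with open(path) as fh:
            return rle_to_masks(json.load(fh))
    if ext not in (".tif", ".tiff"):
        raise FormatError(f"unsupported label extension {ext!r}")
    arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return _import_flat(arr)
    if arr.ndim != 3:
        raise FormatError(f"label TIFF must be 2-D or a page stack, got {arr.shape}")
    if arr.shape[0] == 0:
        raise FormatError("label file contains no masks")
    if arr.shape[0] == 1 and np.issubdtype(arr.dtype, np.integer) and arr.max() > 1:
        return _import_flat(arr[0])
    masks = []
    for page in arr:
        if not page.any():
            raise FormatError("label stack contains an empty page")
        masks.append(InstanceMask(page > 0))
    return InstanceLabelSet(tuple(masks))


def _import_flat(arr: np.ndarray) -> InstanceLabelSet:
    """Split a flat integer-coded label image into one mask per nonzero value."""
    if not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int64)
    values = np.unique(arr)
    values = values[values != 0]
    if values.size == 0:
        raise FormatError("flat label image has no nonzero labels")
    return InstanceLabelSet(tuple(InstanceMask(arr == v) for v in values))


def write_labels(labels: InstanceLabelSet, path: str | Path) -> None:
    """Write a label set as multi-page TIFF (.tif) or RLE JSON (.json)."""
    path = Path(path)
    ext = path.suffix.lower()
    if len(labels) == 0:
        raise ValueError("refusing to write an empty label set")
    if ext in (".tif", ".tiff"):
        stack = labels.as_stack().astype(np.uint8)
        tifffile.imwrite(path, stack, photometric="minisblack")
    elif ext == ".json":
        with open(path, "w") as fh:
            json.dump(masks_to_rle(labels), fh)
    else:
        raise FormatError(f"unsupported label extension {ext!r}")


def read_scene(image_path: str | Path, labels_path: str | Path) -> Scene:
    """Load an image and its labels, checking that their shapes agree."""
    image = read_image(image_path)
    labels = read_labels(labels_path)
    if labels.shape != image.shape:
        raise ShapeError(
            f"label shape {labels.shape} does not match image shape {image.shape}"
        )
    return Scene(image=image, labels=labels)
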