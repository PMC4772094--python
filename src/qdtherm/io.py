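"""File I/O: multi-page TIFF images and JSON sidecars.

Two-channel images are stored as a 2-page TIFF, low band first, high
band second.  Z-stacks are plain multi-page TIFFs, one page per focal
plane.  Ground truth and reports travel as JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile


def write_two_channel_tiff(path, image_low: np.ndarray, image_high: np.ndarray) -> None:
    """Write a (low band, high band) image pair as a 2-page TIFF."""
    stack = np.stack([image_low, image_high]).astype(np.float32)
    tifffile.imwrite(path, stack)


def read_two_channel_tiff(path) -> tuple[np.ndarray, np.ndarray]:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"expected a 2-page TIFF, got shape {stack.shape}")
    return stack[0].astype(float), stack[1].astype(float)


def write_zstack_tiff(path, zstack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(zstack).astype(np.float32))


def read_zstack_tiff(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim != 3:
        raise ValueError(f"expected a 3-D z-stack, got shape {stack.shape}")
    return stack.astype(float)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (frozenset, set, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, obj) -> None:
    """Serialize dataclasses / arrays / plain objects to pretty JSON."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
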