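"""Multi-page TIFF image stacks with JSON metadata.

Stacks are written as 32-bit float multi-page TIFF with a JSON metadata
dictionary (pixel pitch, wavelength, times, ...) in the image
description tag; ``write_stack`` then ``read_stack`` round-trips
bitwise.  Integer input pages are promoted to float32 with a documented
scaling: uint16 by 1/65535, uint8 by 1/255.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .core import PhaseMap
from .errors import FormatError

__all__ = ["write_stack", "read_stack", "write_phase_stack", "read_phase_stack"]


def write_stack(
    path: str | Path, images: np.ndarray | list[np.ndarray], metadata: dict[str, Any]
) -> Path:
    """Write a (n, ny, nx) float32 stack with metadata in the description tag."""
    path = Path(path)
    stack = np.asarray(images, dtype=np.float32)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise FormatError(f"expected a 2-D or 3-D stack, got shape {stack.shape}")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        description=json.dumps(metadata, sort_keys=True),
    )
    return path


def read_stack(
    path: str | Path, require_pitch: bool = True
) -> tuple[np.ndarray, dict[str, Any]]:
    """Read a multi-page TIFF stack back as float32 plus its metadata.

    ``require_pitch`` enforces the presence of ``pixel_pitch_um`` in the
    metadata (the pitch is required for the dry-mass conversion).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = []
            for i, page in enumerate(tif.pages):
                try:
                    pages.append(page.asarray())
                except Exception as exc:  # pragma: no cover - corrupt page path
                    raise FormatError(f"malformed TIFF page {i} in {path}: {exc}") from exc
            description = tif.pages[0].description or ""
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"TIFF {path} contains no pages")
    stack = np.stack(pages)
    if stack.dtype == np.uint16:
        stack = stack.astype(np.float32) / 65535.0
    elif stack.dtype == np.uint8:
        stack = stack.astype(np.float32) / 255.0
    else:
        stack = stack.astype(np.float32)
    try:
        metadata = json.loads(description) if description else {}
    except json.JSONDecodeError as exc:
        raise FormatError(f"TIFF {path}: description tag is not valid JSON") from exc
    if not isinstance(metadata, dict):
        raise FormatError(f"TIFF {path}: metadata must be a JSON object")
    if require_pitch and "pixel_pitch_um" not in metadata:
        raise FormatError(
            f"TIFF {path}: missing required 'pixel_pitch_um' metadata"
        )
    return stack, metadata


def write_phase_stack(path: str | Path, maps: list[PhaseMap], **extra: Any) -> Path:
    """Write time-ordered phase maps of one FOV as a float TIFF stack."""
    if not maps:
        raise FormatError("no phase maps to write")
    meta: dict[str, Any] = {
        "kind": "phase",
        "pixel_pitch_um": maps[0].pixel_pitch_um,
        "wavelength_nm": (maps[0].wavelength_um or 0.0) * 1000.0 or None,
        "times_h": [m.time_h for m in maps],
        "background_corrected": all(m.background_corrected for m in maps),
    }
    meta.update(extra)
    return write_stack(path, [m.values for m in maps], meta)


def read_phase_stack(path: str | Path) -> tuple[list[PhaseMap], dict[str, Any]]:
    """Read a phase stack back into :class:`PhaseMap` objects."""
    stack, meta = read_stack(path, require_pitch=True)
    times = meta.get("times_h") or [None] * len(stack)
    wavelength_nm = meta.get("wavelength_nm")
    maps = [
        PhaseMap(
            frame,
            pixel_pitch_um=float(meta["pixel_pitch_um"]),
            wavelength_um=(wavelength_nm / 1000.0) if wavelength_nm else None,
            background_corrected=bool(meta.get("background_corrected", False)),
            time_h=times[i],
        )
        for i, frame in enumerate(stack)
    ]
    return maps, meta
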