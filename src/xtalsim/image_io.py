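"""Detector-image export: quantization, SMV files, and template grafting.

Simulated intensity rasters are floating point in arbitrary units; real
processing programs expect integer detector counts.  This module scales
and quantizes rasters to 16-bit, writes them as SMV (.img) files with the
standard 512-byte ASCII header, and can graft a quantized raster into the
data array of an existing detector file while preserving selected pixels
(beamstop / spacer regions) and every other byte of the template.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .photograph import Photograph

__all__ = [
    "QuantizedImage",
    "scale_and_quantize",
    "scan_scaling",
    "write_smv",
    "read_smv",
    "graft_into_template",
]

U16_MAX = 65535
#: value written at masked (not simulated) pixels
MASK_SENTINEL = 0


@dataclass
class QuantizedImage:
    """16-bit unsigned raster plus the header fields needed to describe it."""

    data: np.ndarray  # (n_slow, n_fast) uint16
    scale: float
    saturated: int
    header: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != np.uint16:
            raise ValueError("quantized raster must be uint16")


def scale_and_quantize(photo: Photograph, scale: float,
                       sentinel: int = MASK_SENTINEL,
                       header: dict | None = None) -> QuantizedImage:
    """round(scale * I) clamped to 16 bits; masked pixels get the sentinel."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    scaled = np.rint(photo.data * scale)
    saturated = int(np.count_nonzero(scaled[photo.mask] > U16_MAX))
    out = np.clip(scaled, 0, U16_MAX).astype(np.uint16)
    out[~photo.mask] = sentinel
    hdr = dict(header or {})
    lo, hi = photo.angle_range
    hdr.setdefault("OSC_START", lo)
    hdr.setdefault("OSC_RANGE", hi - lo)
    return QuantizedImage(out, scale, saturated, hdr)


def scan_scaling(photos: list[Photograph], grid=None,
                 max_saturated_fraction: float = 1e-4) -> tuple[float, pd.DataFrame]:
    """Pick one scale for a whole series by scanning a grid of constants.

    Each candidate is applied uniformly to all photographs; the report lists
    the saturated-pixel fraction and dynamic range per scale.  The chosen
    scale is the largest one whose saturated fraction stays below the
    threshold (a self-contained stand-in for tuning against an external
    integration program's feedback).
    """
    if not photos:
        raise ValueError("empty photograph list")
    grid = np.asarray(
        np.geomspace(0.1, 10.0, 25) if grid is None else grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty scale grid")
    if np.any(grid <= 0):
        raise ValueError("scales must be positive")
    valid_vals = np.concatenate([p.data[p.mask].ravel() for p in photos])
    n_valid = valid_vals.size
    peak = float(valid_vals.max()) if n_valid else 0.0
    rows = []
    for sc in np.sort(grid):
        sat = int(np.count_nonzero(np.rint(valid_vals * sc) > U16_MAX))
        quant = np.minimum(np.rint(valid_vals * sc), U16_MAX)
        rows.append({
            "scale": sc,
            "saturated_fraction": sat / n_valid if n_valid else 0.0,
            "max_count": int(quant.max()) if n_valid else 0,
            "nonzero_fraction": float(np.count_nonzero(quant)) / n_valid
            if n_valid else 0.0,
        })
    report = pd.DataFrame(rows)
    report.attrs["degenerate_input"] = peak == 0.0
    if peak == 0.0:  # nothing to scale; fall back to the gentlest constant
        return float(report["scale"].min()), report
    ok = report[report["saturated_fraction"] <= max_saturated_fraction]
    chosen = float(ok["scale"].max()) if len(ok) else float(report["scale"].min())
    return chosen, report


# --------------------------------------------------------------------------
# SMV format

_HEADER_BLOCK = 512


def write_smv(img: QuantizedImage, path) -> None:
    """Write an SMV image: padded ASCII header then little-endian uint16 data."""
    n_slow, n_fast = img.data.shape
    required = ("PIXEL_SIZE", "DISTANCE", "WAVELENGTH",
                "BEAM_CENTER_X", "BEAM_CENTER_Y", "OSC_START", "OSC_RANGE")
    missing = [k for k in required if k not in img.header]
    if missing:
        raise ValueError("missing header fields: " + ", ".join(missing))
    fields = {
        "HEADER_BYTES": _HEADER_BLOCK,
        "DIM": 2,
        "BYTE_ORDER": "little_endian",
        "TYPE": "unsigned_short",
        "SIZE1": n_fast,
        "SIZE2": n_slow,
        **img.header,
    }
    body = "".join(f"{k}={v};\n" for k, v in fields.items())
    header = "{\n" + body + "}\n"
    if len(header) > _HEADER_BLOCK:
        raise ValueError("header too long for the 512-byte block")
    blob = header.encode().ljust(_HEADER_BLOCK, b"\x20")
    with open(path, "wb") as fh:
        fh.write(blob)
        fh.write(img.data.astype("<u2").tobytes())


def read_smv(path) -> QuantizedImage:
    """Read back an SMV file written by write_smv (bit-exact round trip)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    m = re.match(rb"\{\n(.*?)\}", raw[:_HEADER_BLOCK * 4], re.S)
    if not m:
        raise ValueError("not an SMV file (no brace-delimited header)")
    header: dict = {}
    for line in m.group(1).decode().splitlines():
        if "=" in line:
            k, v = line.rstrip(";").split("=", 1)
            try:
                header[k] = int(v)
            except ValueError:
                try:
                    header[k] = float(v)
                except ValueError:
                    header[k] = v
    nbytes = int(header.get("HEADER_BYTES", _HEADER_BLOCK))
    n_fast, n_slow = int(header["SIZE1"]), int(header["SIZE2"])
    data = np.frombuffer(raw[nbytes:nbytes + 2 * n_fast * n_slow],
                         dtype="<u2").reshape(n_slow, n_fast).copy()
    extra = {k: v for k, v in header.items()
             if k not in ("HEADER_BYTES", "DIM", "BYTE_ORDER", "TYPE",
                          "SIZE1", "SIZE2")}
    return QuantizedImage(data, 1.0, 0, extra)


# --------------------------------------------------------------------------
# template grafting

def graft_into_template(template: bytes, img: QuantizedImage,
                        offset: int, length: int,
                        dtype: str = "<u2",
                        preserve_mask: np.ndarray | None = None) -> bytes:
    """Replace the data array inside a detector file with the simulated one.

    Everything outside [offset, offset+length) is copied verbatim; inside,
    simulated values are written except at preserve-mask pixels (screen
    spacer, beamstop, ...), which keep the template's original values.
    """
    itemsize = np.dtype(dtype).itemsize
    n_slow, n_fast = img.data.shape
    if offset < 0 or offset + length > len(template):
        raise ValueError("data-array descriptor overruns the template")
    if length != n_slow * n_fast * itemsize:
        raise ValueError(
            f"descriptor length {length} != raster bytes "
            f"{n_slow * n_fast * itemsize}")
    original = np.frombuffer(template[offset:offset + length],
                             dtype=dtype).reshape(n_slow, n_fast)
    new = img.data.astype(dtype)
    if preserve_mask is not None:
        preserve_mask = np.asarray(preserve_mask, dtype=bool)
        if preserve_mask.shape != img.data.shape:
            raise ValueError("preserve mask shape mismatch")
        new = np.where(preserve_mask, original, new)
    return template[:offset] + new.tobytes() + template[offset + length:]
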