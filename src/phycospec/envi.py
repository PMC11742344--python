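"""Generic ENVI header/raster reader and writer.

Supports the standard dialect: an ASCII ``.hdr`` with ``key = value`` lines
(braced lists may span lines) next to a flat binary raster in band
sequential (bsq), band interleaved by line (bil) or band interleaved by
pixel (bip) layout.  Wavelengths (nm) are required; write then read is the
identity on values, axis and interleave metadata.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .types import HyperspectralCube, WavelengthAxis

__all__ = [
    "EnviError",
    "EnviSizeMismatchError",
    "EnviInterleaveError",
    "EnviMissingWavelengthsError",
    "read_envi",
    "write_envi",
]

# ENVI data type codes -> numpy dtypes (little-endian subset we emit/accept)
_DTYPES = {1: "u1", 2: "<i2", 3: "<i4", 4: "<f4", 5: "<f8", 12: "<u2"}
_DTYPE_CODES = {np.dtype("float32"): 4, np.dtype("float64"): 5}


class EnviError(ValueError):
    """Base class for ENVI format errors."""


class EnviSizeMismatchError(EnviError):
    """Raster body size does not match the header's dimensions."""


class EnviInterleaveError(EnviError):
    """Unknown or unsupported interleave keyword."""


class EnviMissingWavelengthsError(EnviError):
    """Header lacks the wavelength list."""


def _header_path(path: Path) -> Path:
    return path.with_suffix(".hdr")


def _data_path(path: Path) -> Path:
    return path.with_suffix(".img")


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise EnviError("missing ENVI magic line in header")
    # join braced multi-line values before splitting into key = value pairs
    body = text.split("\n", 1)[1]
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _parse_list(value: str) -> list[float]:
    return [float(v) for v in value.strip("{} \n").replace("\n", " ").split(",") if v.strip()]


def read_envi(path: str | Path) -> HyperspectralCube:
    """Read an ENVI cube (``path`` may be the .hdr, the .img, or the stem)."""
    path = Path(path)
    hdr_file = _header_path(path)
    data_file = _data_path(path)
    fields = _parse_header(hdr_file.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviError(f"header missing required field: {exc.args[0]}") from exc
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviInterleaveError(f"unknown interleave {interleave!r}")
    if "wavelength" not in fields:
        raise EnviMissingWavelengthsError("header has no wavelength list")
    wavelengths = _parse_list(fields["wavelength"])
    if len(wavelengths) != bands:
        raise EnviError(
            f"wavelength list length {len(wavelengths)} != band count {bands}"
        )
    if dtype_code not in _DTYPES:
        raise EnviError(f"unsupported data type code {dtype_code}")
    dtype = np.dtype(_DTYPES[dtype_code])
    raw = data_file.read_bytes()
    expected = samples * lines * bands * dtype.itemsize
    if len(raw) != expected:
        raise EnviSizeMismatchError(
            f"raster body is {len(raw)} bytes, expected {expected} "
            f"({lines}x{samples}x{bands} of {dtype.itemsize}-byte samples)"
        )
    flat = np.frombuffer(raw, dtype=dtype)
    if interleave == "bsq":
        values = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        values = flat.reshape(lines, samples, bands)
    pixel_size = 80.0
    if "pixel size" in fields:
        pixel_size = _parse_list(fields["pixel size"])[0]
    return HyperspectralCube(
        WavelengthAxis(np.asarray(wavelengths)),
        np.ascontiguousarray(values, dtype=float),
        pixel_size_um=pixel_size,
    )


def write_envi(
    cube: HyperspectralCube,
    path: str | Path,
    interleave: str = "bsq",
    dtype: str = "float64",
) -> Path:
    """Write a cube as paired ``.hdr`` / ``.img`` files; returns the header path."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviInterleaveError(f"unknown interleave {interleave!r}")
    np_dtype = np.dtype(dtype)
    if np_dtype not in _DTYPE_CODES:
        raise EnviError(f"unsupported output dtype {dtype!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = cube.values.astype(np_dtype)
    if interleave == "bsq":
        body = values.transpose(2, 0, 1)
    elif interleave == "bil":
        body = values.transpose(0, 2, 1)
    else:
        body = values
    _data_path(path).write_bytes(np.ascontiguousarray(body).tobytes())
    # full double precision so the axis round-trips bit-exactly
    wavelengths = ", ".join(f"{w:.17g}" for w in cube.axis.centres)
    header = (
        "ENVI\n"
        "description = {phycospec hyperspectral cube}\n"
        f"samples = {cube.cols}\n"
        f"lines = {cube.rows}\n"
        f"bands = {cube.bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np_dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"pixel size = {{{cube.pixel_size_um:.3f}, {cube.pixel_size_um:.3f}}}\n"
        f"wavelength = {{{wavelengths}}}\n"
    )
    hdr_file = _header_path(path)
    hdr_file.write_text(header)
    return hdr_file
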