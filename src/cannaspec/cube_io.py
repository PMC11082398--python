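"""Hyperspectral cube container and I/O.

A cube is a ``rows x cols x bands`` reflectance array with a strictly
increasing wavelength axis (nominally 150 bands spanning 400-1000 nm) and
free-form metadata.  Two on-disk representations are supported:

* an ENVI-style header/binary pair (``.hdr`` text header + raw
  band-sequential binary) for interoperability with hyperspectral tooling;
* an HDF5 container (datasets ``reflectance`` and ``wavelengths_nm``,
  metadata as root attributes) used as the package's native format because
  it round-trips bit-exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np

__all__ = [
    "HyperspectralCube",
    "default_wavelength_grid",
    "read_cube",
    "write_cube",
    "nearest_band",
]

#: Reconstructed band-center grid: 150 bands, 400.53 + 4.0025 k nm.
#: Reproduces the instrument's quoted band centers (552.61, 556.61, 684.69,
#: 764.74, ...) to within 0.03 nm.
GRID_START_NM = 400.53
GRID_STEP_NM = 4.0025
N_BANDS = 150


def default_wavelength_grid(n_bands: int = N_BANDS) -> np.ndarray:
    """Default band-center wavelengths in nm (ascending, length ``n_bands``)."""
    return GRID_START_NM + GRID_STEP_NM * np.arange(n_bands, dtype=float)


@dataclass
class HyperspectralCube:
    """Reflectance cube with wavelength axis and free-form metadata.

    Parameters
    ----------
    reflectance
        ``(rows, cols, bands)`` float array of dimensionless reflectance.
    wavelengths_nm
        Strictly increasing band-center wavelengths, length equal to the
        band dimension.
    metadata
        Free-form key/value pairs (sample id, drying method, day, ...).
    allow_negative
        Accept negative reflectance values (off by default; negative values
        normally indicate a calibration problem upstream).
    """

    reflectance: np.ndarray
    wavelengths_nm: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValueError(
                f"reflectance must be 3-D (rows, cols, bands); got {self.reflectance.ndim}-D"
            )
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.reflectance.shape[2]:
            raise ValueError(
                f"wavelengths_nm length {self.wavelengths_nm.size} does not match "
                f"band dimension {self.reflectance.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if not self.allow_negative and np.any(self.reflectance < 0):
            raise ValueError(
                "negative reflectance values present; pass allow_negative=True to accept"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[2]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HyperspectralCube):
            return NotImplemented
        return (
            np.array_equal(self.reflectance, other.reflectance)
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and self.metadata == other.metadata
        )


def nearest_band(cube: HyperspectralCube, target_nm: float) -> int:
    """Index of the band whose center is nearest ``target_nm``.

    Ties (target exactly midway between two centers) resolve to the lower
    index.  Targets outside the wavelength range by more than half the local
    band spacing raise ``ValueError`` rather than silently extrapolating.
    """
    wl = cube.wavelengths_nm
    half_lo = (wl[1] - wl[0]) / 2 if wl.size > 1 else 0.0
    half_hi = (wl[-1] - wl[-2]) / 2 if wl.size > 1 else 0.0
    if target_nm < wl[0] - half_lo or target_nm > wl[-1] + half_hi:
        raise ValueError(
            f"target {target_nm} nm outside cube wavelength range "
            f"[{wl[0]}, {wl[-1]}] nm (± half band spacing)"
        )
    dist = np.abs(wl - target_nm)
    return int(np.argmin(dist))  # argmin returns the first (lower) index on ties


# ---------------------------------------------------------------------------
# HDF5 container

_META_PREFIX = "meta_"


def _write_h5(cube: HyperspectralCube, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("reflectance", data=cube.reflectance)
        f.create_dataset("wavelengths_nm", data=cube.wavelengths_nm)
        for key, value in cube.metadata.items():
            f.attrs[_META_PREFIX + key] = value


def _read_h5(path: Path, allow_negative: bool) -> HyperspectralCube:
    with h5py.File(path, "r") as f:
        if "wavelengths_nm" not in f:
            raise ValueError(f"{path}: container missing wavelength metadata")
        refl = f["reflectance"][()]
        wl = f["wavelengths_nm"][()]
        metadata: dict[str, Any] = {}
        for key, value in f.attrs.items():
            if key.startswith(_META_PREFIX):
                if isinstance(value, bytes):
                    value = value.decode()
                elif isinstance(value, np.generic):
                    value = value.item()
                metadata[key[len(_META_PREFIX):]] = value
    return HyperspectralCube(refl, wl, metadata, allow_negative=allow_negative)


# ---------------------------------------------------------------------------
# ENVI header/binary pair (band-sequential, float32/float64)

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _write_envi(cube: HyperspectralCube, hdr_path: Path) -> None:
    bin_path = hdr_path.with_suffix(".raw")
    data = cube.reflectance.astype(np.float64)
    rows, cols, bands = data.shape
    wl_str = ",\n".join(f"  {float(w)!r}" for w in cube.wavelengths_nm)
    lines = [
        "ENVI",
        "description = {cannaspec hyperspectral cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_DTYPE_CODES[data.dtype]}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {\n" + wl_str + "}",
    ]
    for key, value in cube.metadata.items():
        lines.append(f"{_META_PREFIX}{key} = {{{value}}}")
    hdr_path.write_text("\n".join(lines) + "\n")
    # BSQ: band-major on disk
    np.ascontiguousarray(np.moveaxis(data, 2, 0)).tofile(bin_path)


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    # collapse brace-delimited multi-line values first
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{.*?\}|[^\n]*)", re.S | re.M)
    pos = 0
    while pos < len(text):
        m = pattern.search(text, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        value = m.group(2).strip()
        if value.startswith("{") and not value.endswith("}"):
            end = text.find("}", m.start(2))
            if end == -1:
                raise ValueError("unterminated '{' in ENVI header")
            value = text[m.start(2): end + 1]
            pos = end + 1
        else:
            pos = m.end()
        fields[key] = value
    return fields


def _read_envi(hdr_path: Path, allow_negative: bool) -> HyperspectralCube:
    text = hdr_path.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError(f"{hdr_path}: not an ENVI header")
    fields = _parse_envi_header(text)
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields.get("data type", "4"))
    except KeyError as exc:
        raise ValueError(f"{hdr_path}: header missing required field {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError(f"{hdr_path}: header has no wavelength metadata; refusing to guess")
    wl = np.array(
        [float(tok) for tok in fields["wavelength"].strip("{}").replace("\n", " ").split(",") if tok.strip()]
    )
    if wl.size != bands:
        raise ValueError(
            f"{hdr_path}: wavelength list length {wl.size} does not match bands = {bands}"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"{hdr_path}: unsupported ENVI data type code {dtype_code}")
    dtype = _ENVI_DTYPES[dtype_code]
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"{hdr_path}: only BSQ interleave supported; got {interleave!r}")
    bin_path = hdr_path.with_suffix(".raw")
    raw = np.fromfile(bin_path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"{bin_path}: binary holds {raw.size} values, header claims "
            f"{rows}x{cols}x{bands} = {rows * cols * bands}"
        )
    data = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2)
    def _coerce(text_value: str):
        # header values are text; recover the obvious scalar types
        for cast in (int, float):
            try:
                return cast(text_value)
            except ValueError:
                continue
        return text_value

    metadata = {
        k[len(_META_PREFIX):]: _coerce(v.strip("{}").strip())
        for k, v in fields.items()
        if k.startswith(_META_PREFIX)
    }
    return HyperspectralCube(data.astype(float), wl, metadata, allow_negative=allow_negative)


# ---------------------------------------------------------------------------


def write_cube(cube: HyperspectralCube, path: str | Path) -> None:
    """Write a cube; format chosen by extension (``.hdr`` ENVI, else HDF5)."""
    path = Path(path)
    if path.suffix.lower() == ".hdr":
        _write_envi(cube, path)
    else:
        _write_h5(cube, path)


def read_cube(path: str | Path, allow_negative: bool = False) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube`.

    Raises ``ValueError`` on missing wavelength metadata or on a shape
    mismatch between header and binary, and ``FileNotFoundError`` if the
    path does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".hdr":
        return _read_envi(path, allow_negative)
    return _read_h5(path, allow_negative)
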