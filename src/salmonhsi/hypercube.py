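"""Hypercube container, ENVI/HDF5 I/O and black/white radiometric calibration.

A hypercube is a rank-3 reflectance array (rows x cols x bands) with an
ascending wavelength vector.  Raw sensor counts are converted to relative
reflectance (percent) against a white PTFE reference (~100 %) and a dark
frame (~0 %):

    R_c = (R_0 - B) / (W - B) * 100

Reference frames may be full-frame (same shape as the cube), per-column line
references of shape (cols, bands) — the natural product of a push-broom
scanner — or a single spectrum of shape (bands,); all broadcast to the cube.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Hypercube",
    "CalibrationFrames",
    "CalibrationError",
    "SPA_WAVELENGTHS_NM",
    "default_wavelength_grid",
    "read_cube",
    "write_cube",
    "radiometric_calibrate",
    "mean_spectrum",
]


class CalibrationError(ValueError):
    """White minus dark is non-positive somewhere; calibration undefined there."""


#: The 30 characteristic wavelengths (nm) retained by the successive
#: projections algorithm in the salmon freshness study this pipeline
#: re-implements; used to anchor the default instrument wavelength grid.
SPA_WAVELENGTHS_NM = np.array([
    372.66, 387.13, 394.37, 398.00, 401.63, 405.26, 412.52, 419.80,
    434.38, 449.00, 463.65, 504.14, 541.19, 556.07, 574.73, 589.70,
    600.95, 634.81, 722.21, 841.92, 912.44, 936.11, 955.91, 971.78,
    983.71, 995.66, 1003.63, 1011.62, 1023.62, 1039.65,
])

_N_BANDS_DEFAULT = 158


def default_wavelength_grid(n_bands: int = _N_BANDS_DEFAULT) -> np.ndarray:
    """Default 158-band wavelength grid (nm).

    The exact band centres of the instrument are not published; only the 30
    SPA-selected wavelengths are.  We fit a monotone quadratic dispersion
    model lambda(i) = a + b*i + c*i**2 to those 30 values (band indices
    estimated by alternating assignment / least squares, assuming the first
    and last selected wavelengths sit at the grid ends) and evaluate it on
    0..n_bands-1.  A stand-in for the instrument truth, config-overridable
    everywhere downstream.
    """
    lam = SPA_WAVELENGTHS_NM
    top = n_bands - 1
    # initial index assignment: linear interpolation between the extremes
    idx = (lam - lam[0]) / (lam[-1] - lam[0]) * top
    coeffs = None
    for _ in range(6):
        A = np.vander(idx, 3)  # columns i^2, i, 1
        coeffs, *_ = np.linalg.lstsq(A, lam, rcond=None)
        c, b, a = coeffs
        # re-assign: invert the quadratic for each printed wavelength
        disc = b * b - 4.0 * c * (a - lam)
        idx = np.clip((-b + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * c), 0, top)
    c, b, a = coeffs
    i = np.arange(n_bands, dtype=float)
    grid = a + b * i + c * i * i
    if np.any(np.diff(grid) <= 0):  # pragma: no cover - dispersion fit guard
        raise RuntimeError("dispersion model is not monotone")
    return grid


@dataclass
class Hypercube:
    """Rank-3 reflectance (or raw-count) array with wavelength metadata."""

    data: np.ndarray                      # rows x cols x bands
    wavelengths_nm: np.ndarray            # length-B, strictly increasing
    sample_id: str = ""
    side: str = "dorsal"                  # {dorsal, ventral}
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be rank-3, got shape {self.data.shape}")
        if self.data.shape[2] != self.wavelengths_nm.size:
            raise ValueError(
                f"band axis ({self.data.shape[2]}) does not match wavelength "
                f"vector ({self.wavelengths_nm.size})"
            )
        if self.wavelengths_nm.size < 2:
            raise ValueError("need at least 2 bands")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.side not in ("dorsal", "ventral"):
            raise ValueError(f"side must be dorsal or ventral, got {self.side!r}")
        if self.calibrated:
            if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
                raise ValueError("calibrated data must be finite and >= 0")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class CalibrationFrames:
    """White (PTFE, ~100 %) and dark (~0 %) reference frames.

    Shapes accepted: full cube (rows, cols, bands), per-column push-broom
    line reference (cols, bands), or a single spectrum (bands,).
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share a shape")

    def broadcast_to(self, cube_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        w, d = self.white, self.dark
        if w.ndim == 3:
            if w.shape != cube_shape:
                raise ValueError(f"frame shape {w.shape} != cube shape {cube_shape}")
            return w, d
        if w.ndim == 2:
            if w.shape != cube_shape[1:]:
                raise ValueError(
                    f"line-reference shape {w.shape} incompatible with cube {cube_shape}"
                )
            return w[None, :, :], d[None, :, :]
        if w.ndim == 1:
            if w.shape[0] != cube_shape[2]:
                raise ValueError("spectrum reference length != band count")
            return w[None, None, :], d[None, None, :]
        raise ValueError(f"unsupported reference rank {w.ndim}")


# --------------------------------------------------------------------------
# ENVI dialect: ASCII .hdr + raw binary raster
# --------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8")}
_ENVI_CODES = {np.dtype("float32"): 4, np.dtype("float64"): 5}


def _write_envi(cube: Hypercube, path: Path, interleave: str = "bip") -> None:
    interleave = interleave.lower()
    if interleave not in ("bip", "bil", "bsq"):
        raise ValueError(f"unknown interleave {interleave!r}")
    base = Path(path)
    hdr, raw = Path(str(base) + ".hdr"), Path(str(base) + ".raw")
    rows, cols, bands = cube.data.shape
    dtype = cube.data.dtype if cube.data.dtype in _ENVI_CODES else np.dtype("float64")
    arr = np.ascontiguousarray(cube.data, dtype=dtype)
    if interleave == "bip":      # (lines, samples, bands)
        out = arr
    elif interleave == "bil":    # (lines, bands, samples)
        out = arr.transpose(0, 2, 1)
    else:                        # bsq: (bands, lines, samples)
        out = arr.transpose(2, 0, 1)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths_nm)
    hdr.write_text(
        "ENVI\n"
        f"description = {{sample {cube.sample_id} side {cube.side} "
        f"calibrated {int(cube.calibrated)}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    out.astype(out.dtype.newbyteorder("<")).tofile(raw)


def _parse_envi_header(text: str) -> dict:
    # collapse {...} blocks to single logical values
    fields: dict[str, str] = {}
    text = text.replace("\r\n", "\n")
    pattern = re.compile(r"^([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(text):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _read_envi(path: Path) -> Hypercube:
    base = Path(path)
    if base.suffix == ".hdr":
        hdr, raw = base, Path(str(base)[: -len(".hdr")] + ".raw")
    else:
        hdr, raw = Path(str(base) + ".hdr"), Path(str(base) + ".raw")
    if not hdr.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr}")
    if not raw.exists():
        raise FileNotFoundError(f"missing ENVI raster {raw}")
    f = _parse_envi_header(hdr.read_text())
    rows, cols, bands = int(f["lines"]), int(f["samples"]), int(f["bands"])
    dtype = _ENVI_DTYPES[int(f["data type"])]
    interleave = f.get("interleave", "bip").lower()
    flat = np.fromfile(raw, dtype=dtype)
    if flat.size != rows * cols * bands:
        raise ValueError(
            f"raster size {flat.size} does not match header "
            f"{rows}x{cols}x{bands} (={rows * cols * bands})"
        )
    if interleave == "bip":
        data = flat.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    wl_field = f.get("wavelength", "")
    wavelengths = np.array(
        [float(x) for x in wl_field.strip("{}").replace("\n", " ").split(",") if x.strip()]
    )
    if wavelengths.size != bands:
        raise ValueError("wavelength list length does not match band count")
    desc = f.get("description", "")
    m = re.search(r"sample (\S+) side (\S+) calibrated (\d)", desc)
    sample_id, side, calibrated = ("", "dorsal", False)
    if m:
        sample_id, side, calibrated = m.group(1), m.group(2), bool(int(m.group(3)))
    return Hypercube(np.ascontiguousarray(data), wavelengths, sample_id, side, calibrated)


# --------------------------------------------------------------------------
# HDF5-container dialect
# --------------------------------------------------------------------------

def _write_hdf5(cube: Hypercube, path: Path) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("data", data=cube.data)
        h.create_dataset("wavelengths", data=cube.wavelengths_nm)
        h.attrs["sample_id"] = cube.sample_id
        h.attrs["side"] = cube.side
        h.attrs["calibrated"] = cube.calibrated


def _read_hdf5(path: Path) -> Hypercube:
    with h5py.File(path, "r") as h:
        return Hypercube(
            h["data"][()],
            h["wavelengths"][()],
            str(h.attrs.get("sample_id", "")),
            str(h.attrs.get("side", "dorsal")),
            bool(h.attrs.get("calibrated", False)),
        )


def write_cube(cube: Hypercube, path, dialect: str = "envi", interleave: str = "bip") -> None:
    """Persist a cube: ``envi`` (ASCII .hdr + .raw raster) or ``hdf5-container``."""
    if dialect == "envi":
        _write_envi(cube, Path(path), interleave)
    elif dialect in ("hdf5", "hdf5-container"):
        _write_hdf5(cube, Path(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_cube(path, dialect: str = "envi") -> Hypercube:
    """Read a cube written by :func:`write_cube`; round-trips bit-exactly."""
    if dialect == "envi":
        return _read_envi(Path(path))
    if dialect in ("hdf5", "hdf5-container"):
        return _read_hdf5(Path(path))
    raise ValueError(f"unknown dialect {dialect!r}")


# --------------------------------------------------------------------------
# Calibration and spectra
# --------------------------------------------------------------------------

def radiometric_calibrate(
    raw: Hypercube, refs: CalibrationFrames, eps: float = 1e-6
) -> Hypercube:
    """Black/white calibration: ``R_c = (R_0 - B) / (W - B) * 100`` (percent).

    Any (pixel, band) where W - B <= ``eps`` raw units is an error listing the
    offending coordinates — never a silent clamp, because downstream patch
    filters assume finite reflectance.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated")
    white, dark = refs.broadcast_to(raw.data.shape)
    denom = white - dark
    bad = denom <= eps
    if np.any(bad):
        coords = np.argwhere(np.broadcast_to(bad, raw.data.shape))
        head = ", ".join(map(str, map(tuple, coords[:5])))
        raise CalibrationError(
            f"white - dark <= {eps} at {coords.shape[0]} locations (first: {head})"
        )
    rc = (raw.data - dark) / denom * 100.0
    # negative reflectance can only arise from counts below the dark frame;
    # clip the tiny numerical undershoot at exactly 0
    rc = np.maximum(rc, 0.0)
    return Hypercube(rc, raw.wavelengths_nm, raw.sample_id, raw.side, calibrated=True)


def mean_spectrum(cube: Hypercube, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-band arithmetic mean over (optionally masked) pixels."""
    if mask is None:
        return cube.data.reshape(-1, cube.n_bands).mean(axis=0)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.spatial_shape:
        raise ValueError("mask shape does not match cube spatial shape")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return cube.data[mask].mean(axis=0)
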