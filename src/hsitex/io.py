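"""Hyperspectral cube, reference image, and texture-table I/O.

Cubes are stored band-sequential as ``(bands, rows, cols)`` float arrays with
a strictly increasing wavelength grid in nanometres.  Two on-disk formats are
supported:

* **portable** — a self-describing pair ``<base>.pchdr`` (JSON header) +
  ``<base>.pdat`` (flat float64 raster, band-sequential).  Lossless; used by
  the test-suite and the analysis scripts.
* **envi** — classic ENVI ASCII ``.hdr`` + raw raster.  BSQ/BIL/BIP
  interleaves are accepted on read; BSQ float32 or float64 is written.

Texture tables are plain CSV with one row per (sample, region) and one column
per texture indicator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    FormatError,
    GeometryError,
    ParameterError,
    SchemaError,
    VocabularyError,
)

#: The four skin/muscle regions sampled on each fish.
REGIONS = ("dorsal", "pectoral", "abdominal", "gluteal")

#: The eight texture-profile-analysis indicators measured per muscle block.
INDICATORS = (
    "gumminess",
    "springiness",
    "cohesiveness",
    "resilience",
    "hardness",
    "brittleness",
    "adhesiveness",
    "chewiness",
)

#: Default band grid: 600 evenly spaced bands on [400, 1000) nm.
DEFAULT_N_BANDS = 600
WAVELENGTH_MIN = 400.0
WAVELENGTH_MAX = 1000.0


def default_wavelengths(n_bands: int = DEFAULT_N_BANDS) -> np.ndarray:
    """Band-centre wavelengths: ``n_bands`` evenly spaced on [400, 1000) nm."""
    return np.linspace(WAVELENGTH_MIN, WAVELENGTH_MAX, n_bands, endpoint=False)


@dataclass
class SpectralCube:
    """A 3-D reflectance (or raw-intensity) raster with its wavelength grid.

    Parameters
    ----------
    data:
        Array of shape ``(bands, rows, cols)``.
    wavelengths:
        Strictly increasing band-centre wavelengths in nm, one per band.
    kind:
        ``"raw"`` (camera counts) or ``"reflectance"`` (percent scale,
        nominally 0-100; slightly out-of-range values are permitted).
    meta:
        Free-form provenance map (JSON-serialisable).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "reflectance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ConsistencyError(
                f"cube data must be (bands, rows, cols); got ndim={self.data.ndim}"
            )
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[0]:
            raise ConsistencyError(
                f"{len(self.wavelengths)} wavelengths for {self.data.shape[0]} bands"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ConsistencyError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise VocabularyError(f"unknown cube kind {self.kind!r}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ConsistencyError("reflectance cube contains non-finite values")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReferencePair:
    """White (100 % reflectance) and dark (0 %) reference rasters.

    Both share the cube's ``(bands, rows, cols)`` shape and must satisfy
    ``white > dark`` everywhere, otherwise calibration is undefined.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        if self.white.shape != self.dark.shape:
            raise ConsistencyError("white and dark references differ in shape")


@dataclass(frozen=True)
class ROISpec:
    """A rectangular pixel window, half-open: rows ``[row0, row0+height)``."""

    row0: int
    col0: int
    height: int = 200
    width: int = 200

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ParameterError("ROI height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise GeometryError("ROI origin must be non-negative")

    def check_inside(self, rows: int, cols: int) -> None:
        if self.row0 + self.height > rows or self.col0 + self.width > cols:
            raise GeometryError(
                f"ROI {self} exceeds raster of {rows} rows x {cols} cols"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )


# ---------------------------------------------------------------------------
# Texture tables
# ---------------------------------------------------------------------------

class TextureTable:
    """Per-(sample, region) values of the eight texture indicators.

    Thin validated wrapper around a pandas DataFrame with columns
    ``sample_id``, ``region`` and the eight indicator columns, in
    instrument units (carried opaquely; modelling standardises targets).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ("sample_id", "region", *INDICATORS) if c not in df.columns]
        if missing:
            raise SchemaError(f"texture table missing columns: {missing}")
        bad = set(df["region"]) - set(REGIONS)
        if bad:
            raise VocabularyError(f"unknown region labels: {sorted(bad)}")
        values = df.loc[:, list(INDICATORS)].to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(values)):
            raise SchemaError("texture table contains non-finite indicator values")
        if df.duplicated(subset=["sample_id", "region"]).any():
            raise ConsistencyError("duplicate (sample_id, region) rows")
        self.df = df.loc[:, ["sample_id", "region", *INDICATORS]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def region(self, region: str) -> pd.DataFrame:
        """Rows of one region, sorted by sample_id."""
        if region not in REGIONS:
            raise VocabularyError(f"unknown region {region!r}")
        sub = self.df[self.df["region"] == region]
        return sub.sort_values("sample_id").reset_index(drop=True)

    def indicator_vector(self, region: str, indicator: str) -> tuple[np.ndarray, np.ndarray]:
        """(sample_ids, values) for one indicator in one region, sorted by id."""
        if indicator not in INDICATORS:
            raise VocabularyError(f"unknown indicator {indicator!r}")
        sub = self.region(region)
        return sub["sample_id"].to_numpy(), sub[indicator].to_numpy(dtype=np.float64)


def read_texture_table(path: str | Path) -> TextureTable:
    """Read a texture CSV (header row, '.' decimal, UTF-8)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such texture table: {path}")
    return TextureTable(pd.read_csv(path))


def write_texture_table(table: TextureTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Portable cube format
# ---------------------------------------------------------------------------

_PORTABLE_MAGIC = "hsitex-cube"
_PORTABLE_VERSION = 1


def _portable_paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (".pchdr", ".pdat"):
        base = base.with_suffix("")
    return base.with_suffix(".pchdr"), base.with_suffix(".pdat")


def _write_portable(cube: SpectralCube, path: str | Path) -> None:
    hdr_path, dat_path = _portable_paths(path)
    hdr_path.parent.mkdir(parents=True, exist_ok=True)
    bands, rows, cols = cube.shape
    header = {
        "format": _PORTABLE_MAGIC,
        "version": _PORTABLE_VERSION,
        "bands": bands,
        "rows": rows,
        "cols": cols,
        "dtype": "float64",
        "interleave": "bsq",
        "kind": cube.kind,
        "wavelengths": cube.wavelengths.tolist(),
        "meta": cube.meta,
    }
    hdr_path.write_text(json.dumps(header, indent=1), encoding="utf-8")
    cube.data.astype("<f8").tofile(dat_path)


def _read_portable(path: str | Path) -> SpectralCube:
    hdr_path, dat_path = _portable_paths(path)
    if not hdr_path.exists() or not dat_path.exists():
        raise FormatError(f"portable cube incomplete: need {hdr_path} and {dat_path}")
    try:
        header = json.loads(hdr_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"garbled portable header {hdr_path}: {exc}") from exc
    if header.get("format") != _PORTABLE_MAGIC:
        raise FormatError(f"{hdr_path} is not a portable cube header")
    if header.get("version", 0) > _PORTABLE_VERSION:
        raise FormatError(f"portable cube version {header['version']} is newer than supported")
    bands, rows, cols = header["bands"], header["rows"], header["cols"]
    wavelengths = np.asarray(header["wavelengths"], dtype=np.float64)
    if len(wavelengths) != bands:
        raise ConsistencyError(
            f"header declares {bands} bands but {len(wavelengths)} wavelengths"
        )
    data = np.fromfile(dat_path, dtype="<f8")
    if data.size != bands * rows * cols:
        raise ConsistencyError(
            f"raster holds {data.size} values, header implies {bands * rows * cols}"
        )
    return SpectralCube(
        data.reshape(bands, rows, cols),
        wavelengths,
        kind=header.get("kind", "reflectance"),
        meta=header.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# ENVI compatibility layer
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: "u1", 2: "<i2", 3: "<i4", 4: "<f4", 5: "<f8", 12: "<u2"}
_ENVI_DTYPE_CODES = {"float32": 4, "float64": 5}


def _parse_envi_header(text: str) -> dict:
    """Parse ENVI 'key = value' header text, honouring {...} blocks."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("missing ENVI magic line")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pos = 0
    while pos < len(body):
        eq = body.find("=", pos)
        if eq < 0:
            break
        key = body[pos:eq].strip().lower()
        rest = body[eq + 1:]
        stripped = rest.lstrip()
        if stripped.startswith("{"):
            close = stripped.find("}")
            if close < 0:
                raise FormatError(f"unterminated {{}} block for key {key!r}")
            value = stripped[1:close].strip()
            consumed = (len(rest) - len(stripped)) + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            value = rest[:nl].strip()
            consumed = nl
        if key:
            fields[key] = value
        pos = eq + 1 + consumed
    return fields


def _read_envi(path: str | Path) -> SpectralCube:
    hdr_path = Path(path)
    if hdr_path.suffix != ".hdr":
        hdr_path = hdr_path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"no ENVI header: {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text(encoding="utf-8", errors="replace"))
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing key {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    if "wavelength" not in fields:
        raise FormatError("ENVI header lacks a wavelength block")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace("\n", ",").split(",") if tok.strip()]
    )
    if len(wavelengths) != bands:
        raise ConsistencyError(
            f"header declares {bands} bands but {len(wavelengths)} wavelength entries"
        )
    img_path = None
    for suffix in ("", ".img", ".dat", ".raw"):
        cand = hdr_path.with_suffix(suffix) if suffix else hdr_path.with_suffix("")
        if cand.exists() and cand != hdr_path:
            img_path = cand
            break
    if img_path is None:
        raise FormatError(f"no raster file alongside {hdr_path}")
    raw = np.fromfile(img_path, dtype=_ENVI_DTYPES[dtype_code])
    if raw.size != bands * lines * samples:
        raise ConsistencyError(
            f"raster holds {raw.size} values, header implies {bands * lines * samples}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(1, 0, 2)
    else:  # bip
        data = raw.reshape(lines, samples, bands).transpose(2, 0, 1)
    kind = fields.get("hsitex kind", "reflectance")
    return SpectralCube(np.ascontiguousarray(data, dtype=np.float64), wavelengths, kind=kind)


def _write_envi(cube: SpectralCube, path: str | Path, dtype: str = "float32") -> None:
    if dtype not in _ENVI_DTYPE_CODES:
        raise ParameterError(f"ENVI write supports float32/float64, not {dtype!r}")
    hdr_path = Path(path)
    if hdr_path.suffix != ".hdr":
        hdr_path = hdr_path.with_suffix(".hdr")
    hdr_path.parent.mkdir(parents=True, exist_ok=True)
    img_path = hdr_path.with_suffix(".img")
    bands, rows, cols = cube.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {hsitex export}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_DTYPE_CODES[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"hsitex kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(header, encoding="utf-8")
    cube.data.astype("<f4" if dtype == "float32" else "<f8").tofile(img_path)


# ---------------------------------------------------------------------------
# Public cube API
# ---------------------------------------------------------------------------

def read_cube(path: str | Path, format: str = "portable") -> SpectralCube:
    """Read a hyperspectral cube.

    ``format`` is ``"portable"`` (this package's lossless pair) or ``"envi"``.
    """
    if format == "portable":
        return _read_portable(path)
    if format == "envi":
        return _read_envi(path)
    raise ParameterError(f"unknown cube format {format!r}")


def write_cube(cube: SpectralCube, path: str | Path, format: str = "portable",
               envi_dtype: str = "float32") -> None:
    """Write a cube; the portable format round-trips bitwise."""
    if format == "portable":
        _write_portable(cube, path)
    elif format == "envi":
        _write_envi(cube, path, dtype=envi_dtype)
    else:
        raise ParameterError(f"unknown cube format {format!r}")
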