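"""Raw cube -> calibrated, smoothed ROI mean spectra.

The chain is: reflectance calibration against white/dark references,
Savitzky-Golay smoothing along the spectral axis, ROI averaging, and assembly
of the per-region sample x band matrix that every regression model consumes.
Smoothing and ROI averaging are both linear and act on different axes, so
their order is interchangeable; calibration always comes first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import (
    CalibrationError,
    ConsistencyError,
    ParameterError,
)
from .io import REGIONS, ROISpec, ReferencePair, SpectralCube
from .errors import VocabularyError

#: Savitzky-Golay defaults (window length, polynomial order) for Vis-NIR spectra.
SG_WINDOW = 11
SG_POLYORDER = 2

#: Minimum admissible white-minus-dark difference, in raw intensity units.
W_MINUS_D_EPS = 1e-9


@dataclass
class SpectraMatrix:
    """n_samples x n_bands matrix of mean ROI reflectance (%) for one region."""

    X: np.ndarray
    wavelengths: np.ndarray
    sample_ids: np.ndarray
    region: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.region not in REGIONS:
            raise VocabularyError(f"unknown region {self.region!r}")
        if self.X.ndim != 2:
            raise ConsistencyError("X must be 2-D (samples x bands)")
        if self.X.shape[1] != len(self.wavelengths):
            raise ConsistencyError(
                f"{self.X.shape[1]} bands vs {len(self.wavelengths)} wavelengths"
            )
        if self.X.shape[0] != len(self.sample_ids):
            raise ConsistencyError("one sample_id per row required")
        if not np.all(np.isfinite(self.X)):
            raise ConsistencyError("spectra matrix contains non-finite values")
        if len(set(self.sample_ids.tolist())) != len(self.sample_ids):
            raise ConsistencyError("duplicate sample_id in spectra matrix")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """First column sample_id, then one column per band named by wavelength."""
        df = pd.DataFrame(self.X, columns=[f"{w:.4f}" for w in self.wavelengths])
        df.insert(0, "sample_id", self.sample_ids)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, region: str) -> "SpectraMatrix":
        df = pd.read_csv(path)
        wavelengths = np.array([float(c) for c in df.columns[1:]])
        return cls(
            df.iloc[:, 1:].to_numpy(dtype=np.float64),
            wavelengths,
            df["sample_id"].to_numpy(),
            region,
        )


def calibrate_reflectance(raw: SpectralCube, refs: ReferencePair) -> SpectralCube:
    """Black/white correction: reflectance % = (raw - dark)/(white - dark) * 100.

    The dark image maps to 0 % and the white reference to 100 %.  Any pixel
    with ``white - dark`` below a small epsilon makes the division undefined
    and raises :class:`CalibrationError` (no silent clamping).
    """
    if refs.white.shape != raw.shape:
        raise ConsistencyError(
            f"reference shape {refs.white.shape} != cube shape {raw.shape}"
        )
    denom = refs.white - refs.dark
    n_bad = int(np.count_nonzero(denom <= W_MINUS_D_EPS))
    if n_bad:
        raise CalibrationError(
            f"white <= dark at {n_bad} pixel(s); calibration undefined"
        )
    reflectance = (raw.data - refs.dark) / denom * 100.0
    meta = dict(raw.meta)
    meta["calibration"] = "black/white correction, percent reflectance"
    return SpectralCube(reflectance, raw.wavelengths, kind="reflectance", meta=meta)


def uncalibrate(cube: SpectralCube, refs: ReferencePair) -> SpectralCube:
    """Invert the calibration equation: raw = reflectance/100 * (W - D) + D."""
    if refs.white.shape != cube.shape:
        raise ConsistencyError("reference shape mismatch")
    raw = cube.data / 100.0 * (refs.white - refs.dark) + refs.dark
    return SpectralCube(raw, cube.wavelengths, kind="raw", meta=dict(cube.meta))


def _check_sg_params(window: int, polyorder: int, n_bands: int) -> None:
    if window % 2 == 0:
        raise ParameterError(f"SG window must be odd, got {window}")
    if window <= polyorder:
        raise ParameterError(
            f"SG window ({window}) must exceed polyorder ({polyorder})"
        )
    if window > n_bands:
        raise ParameterError(f"SG window {window} exceeds {n_bands} bands")


def sg_smooth(obj: SpectralCube | SpectraMatrix | np.ndarray,
              window: int = SG_WINDOW,
              polyorder: int = SG_POLYORDER):
    """Savitzky-Golay smoothing along the spectral axis only.

    Accepts a cube (smooths each pixel spectrum), a spectra matrix (each
    row), or a bare 1-D/2-D array whose last axis is spectral.  Shape is
    preserved; a polynomial of degree <= ``polyorder`` passes unchanged.
    """
    if isinstance(obj, SpectralCube):
        _check_sg_params(window, polyorder, obj.n_bands)
        smoothed = savgol_filter(obj.data, window, polyorder, axis=0)
        return SpectralCube(smoothed, obj.wavelengths, kind=obj.kind, meta=dict(obj.meta))
    if isinstance(obj, SpectraMatrix):
        _check_sg_params(window, polyorder, obj.n_bands)
        smoothed = savgol_filter(obj.X, window, polyorder, axis=1)
        return SpectraMatrix(smoothed, obj.wavelengths, obj.sample_ids, obj.region)
    arr = np.asarray(obj, dtype=np.float64)
    _check_sg_params(window, polyorder, arr.shape[-1])
    return savgol_filter(arr, window, polyorder, axis=-1)


def extract_roi_mean(cube: SpectralCube, roi: ROISpec) -> np.ndarray:
    """Per-band arithmetic mean spectrum over the ROI pixels."""
    _, rows, cols = cube.shape
    roi.check_inside(rows, cols)
    rs, cs = roi.slices()
    return cube.data[:, rs, cs].mean(axis=(1, 2))


def build_spectra_matrix(
    spectra: dict | list[tuple[object, np.ndarray]],
    wavelengths: np.ndarray,
    region: str,
) -> SpectraMatrix:
    """Assemble per-sample spectra into a canonical matrix, sorted by sample_id.

    ``spectra`` maps sample_id -> 1-D spectrum (or is a list of such pairs);
    all spectra must share the wavelength grid length.
    """
    items = list(spectra.items()) if isinstance(spectra, dict) else list(spectra)
    ids = [sid for sid, _ in items]
    if len(set(ids)) != len(ids):
        raise ConsistencyError("duplicate sample_id")
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    rows = []
    for sid, spec in items:
        spec = np.asarray(spec, dtype=np.float64)
        if spec.shape != wavelengths.shape:
            raise ConsistencyError(
                f"sample {sid!r}: spectrum length {spec.shape} != grid {wavelengths.shape}"
            )
        rows.append(spec)
    order = np.argsort(np.asarray(ids, dtype=object))
    X = np.vstack(rows)[order]
    sample_ids = np.asarray(ids, dtype=object)[order]
    return SpectraMatrix(X, wavelengths, sample_ids, region)
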