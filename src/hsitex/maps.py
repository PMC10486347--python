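"""Pixel-wise texture prediction maps and their rendering.

A fitted calibration model is applied to every pixel spectrum of a calibrated
cube; the resulting raster is colour-coded on a linear blue (low) to orange
(high) scale and written as a PNG with a colour-ramp strip plus a sidecar
JSON carrying the scale endpoints.  Rendering goes through Pillow directly so
re-rendering identical inputs yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConsistencyError, ParameterError
from .io import SpectralCube
from .models import FittedModel, predict

#: Linear colour ramp anchors (RGB in [0,1]): blue at vmin, orange at vmax.
COLOR_LOW = (0.13, 0.25, 0.80)
COLOR_HIGH = (1.00, 0.55, 0.10)
#: Colour of masked-out / background pixels.
COLOR_MASKED = (0.15, 0.15, 0.15)


@dataclass
class PredictionMap:
    """Per-pixel predicted indicator values with the linear colour scale."""

    values: np.ndarray            # (rows, cols), NaN outside the mask
    indicator: str
    mask: np.ndarray | None = None
    colormap: dict = field(default_factory=lambda: {
        "low": COLOR_LOW, "high": COLOR_HIGH})
    vmin: float = 0.0
    vmax: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ParameterError("map values must be 2-D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ConsistencyError("mask shape differs from map shape")
            if not self.mask.any():
                raise ParameterError("mask excludes every pixel")
        inside = self.values[self.mask] if self.mask is not None else self.values
        if not np.all(np.isfinite(inside)):
            raise ConsistencyError("non-finite values inside the mask")
        if self.vmin == self.vmax == 0.0:
            self.vmin = float(inside.min())
            self.vmax = float(inside.max())
        if self.vmin > self.vmax:
            raise ParameterError("vmin must not exceed vmax")

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask] if self.mask is not None else self.values.ravel()


def predict_pixelwise(cube: SpectralCube, model: FittedModel,
                      mask: np.ndarray | None = None,
                      indicator: str = "") -> PredictionMap:
    """Apply a model to every pixel spectrum; the contract is pointwise.

    Each pixel is predicted independently (literally one ``predict`` call per
    pixel), so the map is exactly what per-pixel prediction would give -
    batched linear algebra can differ in the last float bit and is avoided.
    Masked-out pixels are NaN and excluded from the colour-scale range.
    """
    if cube.n_bands != model.n_bands_full:
        raise ConsistencyError(
            f"cube has {cube.n_bands} bands; model expects {model.n_bands_full}"
        )
    bands, rows, cols = cube.shape
    flat = cube.data.reshape(bands, rows * cols).T
    values = np.empty(rows * cols)
    for i in range(rows * cols):
        values[i] = predict(model, flat[i][None, :])[0]
    values = values.reshape(rows, cols)
    if mask is not None:
        values = np.where(np.asarray(mask, dtype=bool), values, np.nan)
    return PredictionMap(values, indicator=indicator, mask=mask)


def reflectance_mask(cube: SpectralCube, threshold: float) -> np.ndarray:
    """Foreground mask: pixels whose mean reflectance exceeds ``threshold`` %."""
    return cube.data.mean(axis=0) > threshold


def _to_rgb(pmap: PredictionMap) -> np.ndarray:
    """Linear value -> colour mapping; constant maps render mid-ramp."""
    rows, cols = pmap.values.shape
    low = np.array(pmap.colormap["low"])
    high = np.array(pmap.colormap["high"])
    span = pmap.vmax - pmap.vmin
    if span > 0:
        t = np.clip((pmap.values - pmap.vmin) / span, 0.0, 1.0)
    else:
        t = np.full((rows, cols), 0.5)
    rgb = low[None, None, :] + t[..., None] * (high - low)[None, None, :]
    if pmap.mask is not None:
        rgb[~pmap.mask] = COLOR_MASKED
    rgb = np.where(np.isnan(rgb), np.array(COLOR_MASKED)[None, None, :], rgb)
    return np.round(rgb * 255).astype(np.uint8)


def render_map(pmap: PredictionMap, path: str | Path,
               colorbar_height: int = 12) -> Path:
    """Write the map as a PNG (value raster + colour-ramp strip) + sidecar JSON.

    The sidecar ``<path>.json`` records vmin, vmax, indicator and colour
    anchors.  Deterministic: identical inputs give byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rgb = _to_rgb(pmap)
    rows, cols = pmap.values.shape
    if colorbar_height > 0:
        low = np.array(pmap.colormap["low"])
        high = np.array(pmap.colormap["high"])
        ramp = np.linspace(0.0, 1.0, cols)[None, :, None]
        bar = low[None, None, :] + ramp * (high - low)[None, None, :]
        bar = np.round(np.repeat(bar, colorbar_height, axis=0) * 255).astype(np.uint8)
        sep = np.zeros((2, cols, 3), dtype=np.uint8)
        rgb = np.vstack([rgb, sep, bar])
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "indicator": pmap.indicator,
        "vmin": pmap.vmin,
        "vmax": pmap.vmax,
        "colormap": {k: list(v) for k, v in pmap.colormap.items()},
        "shape": [rows, cols],
    }, indent=1), encoding="utf-8")
    return path


def map_statistics(pmap: PredictionMap,
                   quantiles: tuple[float, ...] = (0.9,)) -> dict:
    """Mean, sd, range and above-quantile fractions over the masked pixels."""
    v = pmap.masked_values()
    if v.size == 0:
        raise ParameterError("empty mask")
    out = {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=0)),
        "min": float(v.min()),
        "max": float(v.max()),
        "n_pixels": int(v.size),
    }
    for q in quantiles:
        thr = float(np.quantile(v, q))
        out[f"frac_above_q{int(round(q * 100))}"] = float((v > thr).mean())
    return out
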