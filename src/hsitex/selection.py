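"""Regression-coefficient (RC) wavelength selection and interval partitions.

The RC method fits a full-spectrum PLSR model on standardized variables and
reads band relevance off the magnitude of its beta-coefficient vector:
peaks and valleys of beta (positive and negative association with the
target) whose magnitude clears a threshold are kept, or simply the top-k
bands by |beta|.  Standardization matters - unstandardized coefficients
confound band scale with relevance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, SelectionError
from .models import fit_plsr
from .preprocessing import SpectraMatrix


@dataclass
class RCProfile:
    """Per-band beta coefficients of a full-spectrum PLSR fit (standardized)."""

    beta: np.ndarray
    wavelengths: np.ndarray
    n_latent_used: int

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.beta.shape != self.wavelengths.shape:
            raise ParameterError("beta and wavelengths must have equal length")


@dataclass
class WavelengthSubset:
    """A sorted, unique set of band indices with its selection provenance."""

    indices: np.ndarray
    wavelengths: np.ndarray
    method: str = "rc"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if len(self.indices) < 1:
            raise SelectionError("wavelength subset must contain at least one band")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ParameterError("subset indices must be unique")
        if not np.all(np.diff(self.indices) > 0):
            raise ParameterError("subset indices must be sorted")
        if len(self.wavelengths) != len(self.indices):
            raise ParameterError("one wavelength per index required")

    def __len__(self) -> int:
        return len(self.indices)

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps({
            "indices": self.indices.tolist(),
            "wavelengths": self.wavelengths.tolist(),
            "method": self.method,
            "provenance": self.provenance,
        }, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "WavelengthSubset":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(np.array(d["indices"]), np.array(d["wavelengths"]),
                   d.get("method", "rc"), d.get("provenance", {}))

    @classmethod
    def full(cls, wavelengths: np.ndarray) -> "WavelengthSubset":
        wavelengths = np.asarray(wavelengths, dtype=np.float64)
        return cls(np.arange(len(wavelengths)), wavelengths, method="full")


def compute_rc_profile(X, y, n_latent: int | str = "cv",
                       max_latent: int = 15, cv_folds: int = 5) -> RCProfile:
    """Beta-coefficient profile of the full-spectrum PLSR model.

    With ``n_latent="cv"`` the component count is the CV-selected one of the
    full-spectrum fit, mirroring how the full model itself is built.
    """
    if isinstance(X, SpectraMatrix):
        wavelengths = X.wavelengths
    else:
        wavelengths = np.arange(np.asarray(X).shape[1], dtype=np.float64)
    model = fit_plsr(X, y, n_latent=n_latent, max_latent=max_latent, cv_folds=cv_folds)
    return RCProfile(model.params["beta"], wavelengths,
                     n_latent_used=model.hyperparams["n_latent"])


def _local_extrema(beta: np.ndarray) -> np.ndarray:
    """Indices of local maxima/minima of beta, plateau-aware, endpoints included."""
    n = len(beta)
    if n <= 2:
        return np.arange(n, dtype=np.intp)
    d = np.sign(np.diff(beta))
    # slope sign in force to the left/right of each interior point, looking
    # through zero-slope plateaus
    left = np.zeros(n - 1)
    cur = 0.0
    for i, s in enumerate(d):
        if s != 0:
            cur = s
        left[i] = cur
    right = np.zeros(n - 1)
    cur = 0.0
    for i in range(n - 2, -1, -1):
        if d[i] != 0:
            cur = d[i]
        right[i] = cur
    keep = [0, n - 1]
    for i in range(1, n - 1):
        if left[i - 1] != 0 and right[i] != 0 and left[i - 1] != right[i]:
            keep.append(i)
    return np.unique(np.asarray(keep, dtype=np.intp))


def select_by_rc(profile: RCProfile, mode: str = "peak_threshold",
                 param: float = 0.1, provenance: dict | None = None) -> WavelengthSubset:
    """Select bands from an RC profile.

    ``top_k``: the ``param`` bands of largest |beta| (ties to the lowest
    index).  ``peak_threshold``: local extrema of beta whose magnitude exceeds
    ``param`` x max|beta|.
    """
    beta = profile.beta
    absb = np.abs(beta)
    if mode == "top_k":
        k = int(param)
        if k < 1:
            raise ParameterError("top_k requires k >= 1")
        k = min(k, len(beta))
        # stable sort on -|beta| -> ties broken by lowest index
        order = np.argsort(-absb, kind="stable")
        idx = np.sort(order[:k])
    elif mode == "peak_threshold":
        if param <= 0:
            raise ParameterError("peak_threshold requires threshold > 0")
        extrema = _local_extrema(beta)
        idx = extrema[absb[extrema] > param * absb.max()]
        if len(idx) == 0:
            raise SelectionError(
                "no RC peak clears the threshold; lower the threshold or use top_k"
            )
    else:
        raise ParameterError(f"unknown selection mode {mode!r}")
    prov = dict(provenance or {})
    prov.update({"mode": mode, "param": param, "n_latent_used": profile.n_latent_used})
    return WavelengthSubset(idx, profile.wavelengths[idx], method="rc", provenance=prov)


def make_intervals(n_bands: int, n_intervals: int) -> list[tuple[int, int]]:
    """Partition ``range(n_bands)`` into contiguous half-open intervals.

    Sizes differ by at most one; the longer intervals come first (remainder
    rule).  Returns ``[(lo, hi), ...]`` covering all indices disjointly.
    """
    if not 1 <= n_intervals <= n_bands:
        raise ParameterError(
            f"n_intervals must lie in [1, n_bands={n_bands}], got {n_intervals}"
        )
    base, extra = divmod(n_bands, n_intervals)
    intervals = []
    lo = 0
    for i in range(n_intervals):
        hi = lo + base + (1 if i < extra else 0)
        intervals.append((lo, hi))
        lo = hi
    return intervals
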