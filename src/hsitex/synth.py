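"""Synthetic skin spectra, cubes, and linked texture tables.

No public dataset accompanies the study design this package implements, so
every downstream stage is exercised on generated data with the same gross
structure: 400-1000 nm reflectance spectra on a 600-band grid whose region
baselines show the characteristic trough near 430 nm, a 600-780 nm plateau
and a water-related dip near 980 nm; and eight muscle texture indicators
driven by a small number of latent "chemistry" components that also shape
the spectra.  The generator returns full ground truth (latent model, scores,
noise-free signals) so recovery can be tested quantitatively.

The latent spectral basis is sparse by construction - Gaussian absorption
bumps near 500, 780 and 980 nm plus one broad slope - which gives wavelength
selection a meaningful ground truth: the informative bands are the bump
supports.  Noise is i.i.d. Gaussian per band (no spatial correlation except
through the latent field in cubes); a simplification, stated openly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

from .errors import ParameterError, VocabularyError
from .io import INDICATORS, REGIONS, ReferencePair, SpectralCube, TextureTable, default_wavelengths
from .preprocessing import SpectraMatrix, uncalibrate

# ---------------------------------------------------------------------------
# Region baselines
# ---------------------------------------------------------------------------

# Control points (wavelength nm -> reflectance %) for the three "trough +
# plateau + dip" regions.  Values chosen to respect the observed ordering of
# mean reflectance: gluteal > pectoral > abdominal > dorsal.
_BASELINE_CONTROL = {
    # start(400), min(430), rise(520), plateau(600=690=780), mid-fall(875),
    # trough(970), end(1000)
    "gluteal":   (30.0, 22.0, 45.0, 62.0, 54.0, 47.0, 53.0),
    "pectoral":  (24.0, 17.0, 37.0, 52.0, 45.0, 39.0, 44.0),
    "abdominal": (20.0, 14.0, 30.0, 43.0, 38.0, 33.0, 37.0),
}

# Dorsal skin: monotone non-decreasing reflectance from the 430 nm trough out
# to 1000 nm, at the lowest overall level.
_DORSAL_CONTROL = ((400.0, 7.0), (430.0, 5.0), (600.0, 13.0), (780.0, 20.0), (1000.0, 28.0))


def make_region_baseline(region: str, n_bands: int = 600) -> np.ndarray:
    """Mean reflectance curve (%) of one skin region on the default grid.

    Gluteal/pectoral/abdominal curves have their global minimum at 430 nm,
    an exactly flat plateau over 600-780 nm, a decline to 970 nm and a final
    rise; the dorsal curve is non-decreasing from 430 nm onwards.
    """
    wl = default_wavelengths(n_bands)
    if region == "dorsal":
        xs, ys = zip(*_DORSAL_CONTROL)
    elif region in _BASELINE_CONTROL:
        start, vmin, rise, plat, midfall, trough, end = _BASELINE_CONTROL[region]
        xs = (400.0, 430.0, 520.0, 600.0, 690.0, 780.0, 875.0, 970.0, 1000.0)
        ys = (start, vmin, rise, plat, plat, plat, midfall, trough, end)
    else:
        raise VocabularyError(f"unknown region {region!r}")
    # PCHIP preserves monotonicity between control points and is exactly
    # constant across runs of equal control values (the plateau).
    return PchipInterpolator(np.array(xs), np.array(ys))(wl)


# ---------------------------------------------------------------------------
# Latent model
# ---------------------------------------------------------------------------

#: Centres/widths (nm) of the Gaussian absorption-feature bumps; the first
#: basis component is a broad linear slope across the whole range.
_BUMP_CENTERS = (500.0, 780.0, 980.0, 560.0, 650.0, 850.0, 920.0)
_BUMP_WIDTHS = (25.0, 35.0, 20.0, 30.0, 30.0, 30.0, 25.0)
#: Reflectance-% amplitude of a one-sigma latent score, per component.
_AMPLITUDES = (2.0, 3.0, 2.5, 2.0, 2.0, 2.0, 2.0, 2.0)

# Linear mixing weights (indicator x latent component, truncated to
# n_latent).  Sparse by design: each indicator depends on one or two
# components, so "the bands that matter for indicator k" is well defined.
# Springiness/resilience share a component, as do cohesiveness/chewiness,
# giving the indicator table a correlated structure.
_MIXING_RAW = {
    "gumminess":    (0.3, 0.95, 0.0, 0.0),
    "springiness":  (0.0, 0.0, 1.0, 0.0),
    "cohesiveness": (0.0, 0.5, 0.0, 0.85),
    "resilience":   (0.0, 0.0, 0.9, 0.45),
    "hardness":     (0.8, 0.0, 0.6, 0.0),
    "brittleness":  (0.55, 0.0, 0.0, 0.8),
    "adhesiveness": (-0.45, 0.0, 0.0, 0.9),
    "chewiness":    (0.0, 0.75, 0.0, 0.65),
}

#: Indicators carrying the quadratic (nonlinear) term when nonlinearity > 0;
#: mirrors springiness/resilience being the hardest to predict linearly.
NONLINEAR_INDICATORS = ("springiness", "resilience")

# Instrument-unit location (per region) and scale per indicator; gluteal
# highest for most indicators, lowest for adhesiveness, pectoral hardness
# lowest - the qualitative region contrasts of the texture tables.
_UNIT_MU = {  # region order: dorsal, pectoral, abdominal, gluteal
    "gumminess":    (950.0, 900.0, 980.0, 1100.0),
    "springiness":  (0.82, 0.80, 0.83, 0.88),
    "cohesiveness": (0.55, 0.54, 0.56, 0.55),
    "resilience":   (0.30, 0.29, 0.31, 0.36),
    "hardness":     (1810.0, 1660.0, 1890.0, 2010.53),
    "brittleness":  (1200.0, 1150.0, 1250.0, 1400.0),
    "adhesiveness": (95.0, 100.0, 105.0, 70.0),
    "chewiness":    (780.0, 740.0, 800.0, 920.0),
}
_UNIT_SIGMA = {
    "gumminess": 120.0, "springiness": 0.08, "cohesiveness": 0.06,
    "resilience": 0.05, "hardness": 260.0, "brittleness": 150.0,
    "adhesiveness": 25.0, "chewiness": 180.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the study design: 387 fish, 600 bands on [400, 1000) nm,
    all four regions, four latent components, mild spectral noise (reflectance
    % units) and texture noise of 0.1 standardized units.  ``nonlinearity``
    in [0, 1] routes part of the springiness/resilience signal through a
    quadratic term in one latent score.  ``seed`` fully determines output.
    """

    n_samples: int = 387
    n_bands: int = 600
    regions: tuple[str, ...] = REGIONS
    n_latent: int = 4
    noise_sd_spectral: float = 0.2
    noise_sd_texture: float = 0.1
    nonlinearity: float = 0.25
    two_cluster: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_latent < 1:
            raise ParameterError("n_latent must be >= 1")
        if self.noise_sd_spectral < 0 or self.noise_sd_texture < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if not 0.0 <= self.nonlinearity <= 1.0:
            raise ParameterError("nonlinearity must lie in [0, 1]")
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise VocabularyError(f"unknown regions: {sorted(unknown)}")


@dataclass
class LatentModel:
    """Ground-truth generative model: basis curves, mixing map, baselines."""

    basis: np.ndarray                      # (n_latent, n_bands), amplitude-scaled
    mixing: np.ndarray                     # (8, n_latent) unit-norm rows
    quad_component: int                    # latent index carrying the quadratic term
    nonlinearity: float
    region_baseline: dict[str, np.ndarray]
    wavelengths: np.ndarray

    def active_bands(self, threshold: float = 0.5, include_slope: bool = False) -> np.ndarray:
        """Bands where an absorption bump exceeds ``threshold`` x its own peak.

        The broad slope component (basis row 0) touches every band and is
        excluded by default so the result is the sparse bump support that
        wavelength selection is expected to recover.
        """
        basis = self.basis if include_slope else self.basis[1:]
        if basis.shape[0] == 0:
            return np.arange(self.basis.shape[1])
        rel = np.abs(basis) / np.abs(basis).max(axis=1, keepdims=True)
        return np.where((rel > threshold).any(axis=0))[0]

    def active_bands_for(self, indicator: str, threshold: float = 0.5) -> np.ndarray:
        """Bump-support bands of the components driving one indicator.

        Union of the supports (>= ``threshold`` x own peak) of every
        absorption bump the indicator has nonzero mixing weight on; the broad
        slope component is excluded as in :meth:`active_bands`.
        """
        k = INDICATORS.index(indicator)
        comps = [j for j in range(1, self.basis.shape[0])
                 if self.mixing[k, j] != 0.0]
        if not comps:
            return np.arange(self.basis.shape[1])
        rel = np.abs(self.basis[comps]) / np.abs(self.basis[comps]).max(axis=1, keepdims=True)
        return np.where((rel > threshold).any(axis=0))[0]

    def indicator_signal(self, scores: np.ndarray) -> np.ndarray:
        """Noise-free standardized indicator signals for latent ``scores``.

        Linear part has unit variance under N(0,1) scores; for the nonlinear
        indicators a variance-preserving fraction is routed through
        ``(s_q^2 - 1)/sqrt(2)``.
        """
        z = scores @ self.mixing.T
        c = self.nonlinearity
        if c > 0:
            quad = (scores[:, self.quad_component] ** 2 - 1.0) / np.sqrt(2.0)
            for name in NONLINEAR_INDICATORS:
                k = INDICATORS.index(name)
                z[:, k] = np.sqrt(1.0 - c**2) * z[:, k] + c * quad
        return z


def _make_basis(n_latent: int, n_bands: int) -> np.ndarray:
    wl = default_wavelengths(n_bands)
    if n_latent > 1 + len(_BUMP_CENTERS):
        raise ParameterError(f"n_latent must be <= {1 + len(_BUMP_CENTERS)}")
    curves = [np.linspace(-1.0, 1.0, n_bands)]
    for c, w in zip(_BUMP_CENTERS, _BUMP_WIDTHS):
        curves.append(np.exp(-0.5 * ((wl - c) / w) ** 2))
    basis = np.array(curves[:n_latent])
    return basis * np.array(_AMPLITUDES[:n_latent])[:, None]


def _make_mixing(n_latent: int) -> np.ndarray:
    W = np.array([_MIXING_RAW[name][:min(n_latent, 4)] for name in INDICATORS])
    if n_latent > 4:
        W = np.hstack([W, np.zeros((8, n_latent - 4))])
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    return W / norms


def build_latent_model(config: GeneratorConfig) -> LatentModel:
    return LatentModel(
        basis=_make_basis(config.n_latent, config.n_bands),
        mixing=_make_mixing(config.n_latent),
        quad_component=min(1, config.n_latent - 1),
        nonlinearity=config.nonlinearity,
        region_baseline={r: make_region_baseline(r, config.n_bands) for r in config.regions},
        wavelengths=default_wavelengths(config.n_bands),
    )


@dataclass
class GroundTruth:
    """Everything a recovery test needs about a generated dataset."""

    model: LatentModel
    scores: dict[str, np.ndarray]     # region -> (n_samples, n_latent)
    clean_signal: dict[str, np.ndarray]  # region -> (n_samples, 8), standardized
    linear_indicators: tuple[str, ...]


def _draw_scores(rng: np.random.Generator, n: int, n_latent: int, two_cluster: bool) -> np.ndarray:
    scores = rng.standard_normal((n, n_latent))
    if two_cluster:
        # Bimodal means on the first component reproduce the two-cluster
        # structure seen in indicator PCA.
        assign = rng.integers(0, 2, size=n)
        scores[:, 0] += np.where(assign == 0, -1.8, 1.8)
    return scores


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[dict[str, SpectraMatrix], TextureTable, GroundTruth]:
    """Generate linked ROI spectra and texture tables for each region.

    Spectra: region baseline + scores @ basis + Gaussian band noise.
    Indicators: standardized latent signal + Gaussian noise, mapped to
    instrument units per (region, indicator).  Fully reproducible from
    ``config.seed``.
    """
    if config.n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    rng = np.random.default_rng(config.seed)
    model = build_latent_model(config)
    sample_ids = np.array([f"fish{i:04d}" for i in range(config.n_samples)], dtype=object)

    spectra: dict[str, SpectraMatrix] = {}
    scores_by_region: dict[str, np.ndarray] = {}
    clean_by_region: dict[str, np.ndarray] = {}
    table_rows = []
    for region in config.regions:
        scores = _draw_scores(rng, config.n_samples, config.n_latent, config.two_cluster)
        X = model.region_baseline[region] + scores @ model.basis
        if config.noise_sd_spectral > 0:
            X = X + rng.normal(0.0, config.noise_sd_spectral, size=X.shape)
        spectra[region] = SpectraMatrix(X, model.wavelengths, sample_ids, region)

        z = model.indicator_signal(scores)
        z_noisy = z + rng.normal(0.0, config.noise_sd_texture, size=z.shape) \
            if config.noise_sd_texture > 0 else z
        region_idx = REGIONS.index(region)
        for i, sid in enumerate(sample_ids):
            row = {"sample_id": sid, "region": region}
            for k, name in enumerate(INDICATORS):
                row[name] = _UNIT_MU[name][region_idx] + _UNIT_SIGMA[name] * z_noisy[i, k]
            table_rows.append(row)
        scores_by_region[region] = scores
        clean_by_region[region] = z

    table = TextureTable(pd.DataFrame(table_rows))
    linear = tuple(n for n in INDICATORS
                   if config.nonlinearity == 0 or n not in NONLINEAR_INDICATORS)
    truth = GroundTruth(model, scores_by_region, clean_by_region, linear)
    return spectra, table, truth


# ---------------------------------------------------------------------------
# Cubes
# ---------------------------------------------------------------------------

def generate_cube(
    config: GeneratorConfig,
    rows: int,
    cols: int,
    region: str = "dorsal",
    field_sd: float = 1.0,
    field_smoothness: float = 5.0,
) -> tuple[SpectralCube, dict[str, np.ndarray], GroundTruth]:
    """One synthetic skin image: per-pixel spectra over a smooth latent field.

    Latent scores vary across pixels as Gaussian-filtered white noise with
    pointwise standard deviation ``field_sd`` (``field_sd=0`` gives a
    spatially constant cube).  Returns the reflectance cube, per-pixel
    noise-free indicator rasters in instrument units, and the ground truth
    (scores stored as a ``(rows*cols, n_latent)`` matrix).
    """
    if region not in REGIONS:
        raise VocabularyError(f"unknown region {region!r}")
    rng = np.random.default_rng(config.seed)
    model = build_latent_model(
        GeneratorConfig(**{**config.__dict__, "regions": (region,)})
    )
    fields = np.empty((config.n_latent, rows, cols))
    for j in range(config.n_latent):
        if field_sd == 0:
            fields[j] = 0.0
            continue
        white = rng.standard_normal((rows, cols))
        smooth = gaussian_filter(white, sigma=field_smoothness, mode="reflect")
        sd = smooth.std()
        fields[j] = smooth / sd * field_sd if sd > 0 else smooth
    scores = fields.reshape(config.n_latent, -1).T          # (pixels, n_latent)

    pixel_spectra = model.region_baseline[region] + scores @ model.basis
    if config.noise_sd_spectral > 0:
        pixel_spectra = pixel_spectra + rng.normal(
            0.0, config.noise_sd_spectral, size=pixel_spectra.shape
        )
    data = pixel_spectra.T.reshape(config.n_bands, rows, cols)
    cube = SpectralCube(data, model.wavelengths, kind="reflectance",
                        meta={"region": region, "synthetic": True})

    z = model.indicator_signal(scores)
    region_idx = REGIONS.index(region)
    truth_maps = {
        name: (_UNIT_MU[name][region_idx]
               + _UNIT_SIGMA[name] * z[:, k]).reshape(rows, cols)
        for k, name in enumerate(INDICATORS)
    }
    truth = GroundTruth(model, {region: scores}, {region: z},
                        tuple(n for n in INDICATORS
                              if config.nonlinearity == 0 or n not in NONLINEAR_INDICATORS))
    return cube, truth_maps, truth


def make_reference_pair(cube: SpectralCube, rng: np.random.Generator | None = None,
                        white_level: float = 4000.0, dark_level: float = 120.0) -> ReferencePair:
    """Plausible white/dark reference rasters matching ``cube``'s shape."""
    rng = rng or np.random.default_rng(0)
    shape = cube.shape
    white = white_level * (1.0 + 0.02 * rng.standard_normal(shape))
    dark = dark_level * (1.0 + 0.05 * rng.standard_normal(shape))
    return ReferencePair(white=white, dark=dark)


def raw_intensity_cube(cube: SpectralCube, refs: ReferencePair) -> SpectralCube:
    """Raw-intensity variant of a reflectance cube (inverse calibration)."""
    return uncalibrate(cube, refs)
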