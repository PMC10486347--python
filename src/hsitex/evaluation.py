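"""Splitting, target standardization, accuracy metrics, and model ranking.

Metrics follow the chemometrics conventions used throughout the package:

* RMSEC uses the ``sqrt(1/(N-1-R) * sum(residual^2))`` form, where ``R`` is
  the number of model factors (latent variables for the PLS family; by
  convention 2 for LS-SVM's two kernel hyperparameters and 1 for the
  network).
* RMSEP is the plain root-mean-square prediction residual.
* ``r`` (r_c on the calibration set, r_p on the prediction set) is the
  squared Pearson correlation between predicted and measured values, bounded
  in [0, 1].  An alternative "printed" mode computes the residual-ratio form
  ``sum((yhat - y)^2) / sum((yhat - mean(y))^2)`` sometimes seen in print;
  note that form goes to 0, not 1, for a perfect model, so the squared
  correlation is the default.

All error metrics are reported in standardized-target units: targets are
z-scored on calibration-set statistics and the same scaler is applied,
unchanged, to the prediction set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import (
    DegenerateTargetError,
    ParameterError,
    VocabularyError,
)
from .io import INDICATORS, TextureTable

#: Canonical tie-break order of model names in rank_models.
MODEL_NAME_ORDER = ("bipls", "bpann", "ipls", "lssvm", "plsr", "sipls")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Calibration/prediction split: fraction, seed, and strategy."""

    fraction_calibration: float = 0.75
    seed: int = 0
    strategy: str = "random"

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_calibration < 1.0:
            raise ParameterError("fraction_calibration must lie in (0, 1)")
        if self.strategy not in ("random", "kennard_stone"):
            raise VocabularyError(f"unknown split strategy {self.strategy!r}")


def _kennard_stone(X: np.ndarray, n_cal: int) -> np.ndarray:
    """Classic Kennard-Stone max-min design: returns calibration indices."""
    d = np.sqrt(np.maximum(
        (X ** 2).sum(1)[:, None] + (X ** 2).sum(1)[None, :] - 2 * X @ X.T, 0.0))
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(len(X)) if k not in selected]
    mindist = d[remaining][:, selected].min(axis=1)
    while len(selected) < n_cal and remaining:
        pick = int(np.argmax(mindist))
        selected.append(remaining.pop(pick))
        mindist = np.delete(mindist, pick)
        if remaining:
            mindist = np.minimum(mindist, d[remaining, selected[-1]])
    return np.array(sorted(selected), dtype=np.intp)


def split_dataset(n_samples: int, spec: SplitSpec,
                  X: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, covering (calibration, prediction) index sets.

    ``strategy="random"`` shuffles with the spec's seed; ``"kennard_stone"``
    needs the design matrix ``X`` and picks calibration samples by the
    max-min distance rule (the two most mutually distant points first).
    """
    if n_samples < 4:
        raise ParameterError("need at least 4 samples to split")
    n_cal = int(round(n_samples * spec.fraction_calibration))
    if n_cal < 1 or n_cal >= n_samples:
        raise ParameterError(
            f"fraction {spec.fraction_calibration} leaves an empty set for n={n_samples}"
        )
    if spec.strategy == "kennard_stone":
        if X is None:
            raise ParameterError("kennard_stone requires the design matrix X")
        cal = _kennard_stone(np.asarray(X, dtype=np.float64), n_cal)
    else:
        perm = np.random.default_rng(spec.seed).permutation(n_samples)
        cal = np.sort(perm[:n_cal])
    mask = np.ones(n_samples, dtype=bool)
    mask[cal] = False
    return cal, np.where(mask)[0]


# ---------------------------------------------------------------------------
# Target standardization
# ---------------------------------------------------------------------------

@dataclass
class TargetScaler:
    """z-scoring of a target on calibration statistics (population sd)."""

    mean: float
    sd: float

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=np.float64) - self.mean) / self.sd

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=np.float64) * self.sd + self.mean


def standardize_targets(y_calibration: np.ndarray,
                        ddof: int = 0) -> tuple[TargetScaler, np.ndarray]:
    """Fit a z-score scaler on the calibration targets and apply it.

    The same scaler must be applied, unchanged, to prediction-set targets.
    ``ddof`` selects population (0) or sample (1) standard deviation.
    """
    y = np.asarray(y_calibration, dtype=np.float64)
    sd = float(y.std(ddof=ddof))
    if sd <= 0:
        raise DegenerateTargetError("calibration target has zero variance")
    scaler = TargetScaler(float(y.mean()), sd)
    return scaler, scaler.transform(y)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmsec(y_ref: np.ndarray, y_pred: np.ndarray, R: int) -> float:
    """Calibration RMSE with the N-1-R denominator (R = model factor count)."""
    y_ref = np.asarray(y_ref, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    N = len(y_ref)
    if N <= R + 1:
        raise ParameterError(f"RMSEC undefined: N={N} <= R+1={R + 1}")
    return float(np.sqrt(((y_ref - y_pred) ** 2).sum() / (N - 1 - R)))


def rmsep(y_ref: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square prediction residual."""
    y_ref = np.asarray(y_ref, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if len(y_ref) < 1:
        raise ParameterError("RMSEP needs at least one sample")
    return float(np.sqrt(((y_ref - y_pred) ** 2).mean()))


def r_coefficient(y_ref: np.ndarray, y_pred: np.ndarray,
                  mode: str = "squared_pearson") -> float:
    """Coefficient of determination between predicted and measured values.

    Default: squared Pearson correlation, in [0, 1].  ``mode="printed"``
    computes the residual-sum ratio form (see module docstring); it is kept
    for transparency, not as the default.
    """
    y_ref = np.asarray(y_ref, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_ref.std() == 0 or y_pred.std() == 0:
        raise DegenerateTargetError("r undefined for zero-variance input")
    if mode == "squared_pearson":
        r = np.corrcoef(y_ref, y_pred)[0, 1]
        return float(r * r)
    if mode == "printed":
        denom = ((y_pred - y_ref.mean()) ** 2).sum()
        if denom == 0:
            raise DegenerateTargetError("printed-form denominator is zero")
        return float(((y_pred - y_ref) ** 2).sum() / denom)
    raise ParameterError(f"unknown r mode {mode!r}")


# ---------------------------------------------------------------------------
# Reports and ranking
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Accuracy of one model on one (region, indicator) cell."""

    region: str
    indicator: str
    model_kind: str
    r_c: float
    r_p: float
    rmsec: float
    rmsep: float
    n_c: int
    n_p: int
    n_wavelengths: int
    hyperparams: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "region": self.region,
            "indicator": self.indicator,
            "model": self.model_kind,
            "n_wavelengths": self.n_wavelengths,
            "r_c": self.r_c,
            "rmsec": self.rmsec,
            "r_p": self.r_p,
            "rmsep": self.rmsep,
            "n_c": self.n_c,
            "n_p": self.n_p,
        }


def evaluate_fit(model, X, y, cal_idx: np.ndarray, pred_idx: np.ndarray,
                 region: str, indicator: str) -> EvaluationReport:
    """Score a fitted model on a calibration/prediction split.

    Error metrics are computed on z-scored targets (calibration statistics);
    r values are scale-invariant.
    """
    from .models import _factor_count, predict
    from .preprocessing import SpectraMatrix

    if isinstance(X, SpectraMatrix):
        X = X.X
    y = np.asarray(y, dtype=np.float64)
    scaler, _ = standardize_targets(y[cal_idx])
    yhat = predict(model, X)
    z_ref_c = scaler.transform(y[cal_idx])
    z_hat_c = scaler.transform(yhat[cal_idx])
    z_ref_p = scaler.transform(y[pred_idx])
    z_hat_p = scaler.transform(yhat[pred_idx])
    return EvaluationReport(
        region=region,
        indicator=indicator,
        model_kind=model.kind,
        r_c=r_coefficient(z_ref_c, z_hat_c),
        r_p=r_coefficient(z_ref_p, z_hat_p),
        rmsec=rmsec(z_ref_c, z_hat_c, _factor_count(model)),
        rmsep=rmsep(z_ref_p, z_hat_p),
        n_c=len(cal_idx),
        n_p=len(pred_idx),
        n_wavelengths=model.n_bands_used,
        hyperparams=dict(model.hyperparams),
    )


def rank_models(reports: list[EvaluationReport]) -> dict[tuple[str, str], EvaluationReport]:
    """Best model per (region, indicator): highest r_p, ties to lower RMSEP,
    then alphabetical model name.  Invariant to report ordering."""
    if not reports:
        raise ParameterError("no reports to rank")
    best: dict[tuple[str, str], EvaluationReport] = {}
    for rep in reports:
        key = (rep.region, rep.indicator)
        cur = best.get(key)
        if cur is None:
            best[key] = rep
            continue
        a = (-rep.r_p, rep.rmsep, MODEL_NAME_ORDER.index(rep.model_kind)
             if rep.model_kind in MODEL_NAME_ORDER else len(MODEL_NAME_ORDER))
        b = (-cur.r_p, cur.rmsep, MODEL_NAME_ORDER.index(cur.model_kind)
             if cur.model_kind in MODEL_NAME_ORDER else len(MODEL_NAME_ORDER))
        if a < b:
            best[key] = rep
    return best


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Long-format report table, canonically sorted."""
    df = pd.DataFrame([r.as_row() for r in reports])
    return df.sort_values(["region", "indicator", "model"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Indicator structure
# ---------------------------------------------------------------------------

def _indicator_matrix(table: TextureTable, region: str) -> np.ndarray:
    sub = table.region(region)
    return sub.loc[:, list(INDICATORS)].to_numpy(dtype=np.float64)


def indicator_pca(table: TextureTable, region: str) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the standardized 8-indicator matrix for one region.

    Returns (variance-explained fractions summing to 1, sample scores).
    """
    M = _indicator_matrix(table, region)
    if M.shape[0] < 3:
        raise ParameterError("indicator PCA needs at least 3 samples")
    sd = M.std(axis=0, ddof=0)
    Z = (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA()
    scores = pca.fit_transform(Z)
    return pca.explained_variance_ratio_, scores


def indicator_spearman(table: TextureTable, region: str,
                       alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spearman correlation matrix of the eight indicators in one region.

    Returns (rho 8x8 symmetric with unit diagonal, two-sided p-values,
    boolean significance flags at ``alpha``; no multiplicity correction).
    Ties are handled by average ranks (scipy default).
    """
    M = _indicator_matrix(table, region)
    if M.shape[0] < 5:
        raise ParameterError("Spearman matrix needs at least 5 samples")
    rho, p = stats.spearmanr(M)
    rho = np.asarray(rho)
    p = np.asarray(p)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    flags = p < alpha
    np.fill_diagonal(flags, False)
    return rho, p, flags
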