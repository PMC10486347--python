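"""The six spectral calibration models behind one fit/predict contract.

* ``fit_plsr`` — single-response NIPALS partial least squares, with the number
  of latent variables chosen by cross-validation when requested.
* ``fit_ipls`` / ``fit_sipls`` / ``fit_bipls`` — interval PLS variants that
  search equidistant sub-intervals of the band grid by cross-validated
  calibration RMSE (single best interval, best combination, backward
  elimination).
* ``fit_lssvm`` — least-squares SVM regression with an RBF kernel, solved
  exactly through its bias-constrained dual linear system; (gamma, sigma^2)
  optionally chosen by cross-validated grid search.
* ``fit_bpann`` — single-hidden-layer backpropagation network (sigmoid
  hidden, linear output) trained full-batch with momentum: at most 1000
  epochs, learning goal 1e-5, learning rate and momentum factor 0.01.

Every model standardizes X and the target on its calibration data and stores
the scaler, so predictions come back in raw target units and all models are
scale-equivariant in the target.  Fits are deterministic given their inputs
(and, for the network, its seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .errors import (
    BudgetError,
    ConsistencyError,
    DegenerateTargetError,
    FormatError,
    ParameterError,
    SolverError,
    TrainingError,
)
from .preprocessing import SpectraMatrix

MODEL_KINDS = ("plsr", "ipls", "sipls", "bipls", "lssvm", "bpann")
ARCHIVE_VERSION = 1

#: Default grid for the LS-SVM search: log-spaced within (1e-3, 1000].
LSSVM_GRID = tuple(np.logspace(-3, 3, 20))

#: Cap on the number of interval combinations SiPLS will enumerate.
SIPLS_BUDGET = 20000


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass
class Scaler:
    """Column-wise z-scoring fitted on calibration data."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, A: np.ndarray) -> "Scaler":
        A = np.atleast_2d(A)
        mean = A.mean(axis=0)
        sd = A.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)  # constant columns stay centred at 0
        return cls(mean, sd)

    def transform(self, A: np.ndarray) -> np.ndarray:
        return (A - self.mean) / self.sd

    def inverse(self, A: np.ndarray) -> np.ndarray:
        return A * self.sd + self.mean


def _fit_y_scaler(y: np.ndarray) -> tuple[float, float]:
    y = np.asarray(y, dtype=np.float64)
    mu = float(y.mean())
    sd = float(y.std(ddof=0))
    if sd <= 0:
        raise DegenerateTargetError("target is constant")
    return mu, sd


# ---------------------------------------------------------------------------
# Fitted-model container
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A trained calibration model with its scaling and wavelength subset.

    ``band_indices`` is ``None`` for full-spectrum models, otherwise the
    sorted indices (into the full grid) the model consumes.  ``params`` holds
    the model-specific arrays, ``hyperparams`` the scalar settings.  Stateless
    prediction: :func:`predict` applied to the training design reproduces the
    stored training fit exactly.
    """

    kind: str
    n_bands_full: int
    band_indices: np.ndarray | None
    x_scaler: Scaler
    y_mean: float
    y_sd: float
    hyperparams: dict
    params: dict[str, np.ndarray]
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_bands_used(self) -> int:
        return self.n_bands_full if self.band_indices is None else len(self.band_indices)


def _as_xy(X, y, subset):
    """Normalise inputs: full-grid design, 1-D target, optional subset."""
    if isinstance(X, SpectraMatrix):
        X = X.X
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ConsistencyError(f"X {X.shape} not aligned with y of length {len(y)}")
    indices = None
    if subset is not None:
        indices = np.asarray(getattr(subset, "indices", subset), dtype=np.intp)
        if len(indices) == 0:
            raise ParameterError("empty wavelength subset")
        if indices.min() < 0 or indices.max() >= X.shape[1]:
            raise ConsistencyError("subset indices outside band grid")
    return X, y, indices


def _apply_subset(X: np.ndarray, indices: np.ndarray | None) -> np.ndarray:
    return X if indices is None else X[:, indices]


# ---------------------------------------------------------------------------
# NIPALS PLS core
# ---------------------------------------------------------------------------

def _nipals(Xs: np.ndarray, ys: np.ndarray, n_components: int):
    """Single-response NIPALS on standardized data.

    Returns (W, P, q, T, betas) where ``betas[:, a-1]`` is the regression
    vector using the first ``a`` components: beta_a = W_a (P_a' W_a)^-1 q_a.
    Stops early if X or y is exhausted; the returned arrays are truncated.
    """
    n, p = Xs.shape
    A = min(n_components, n - 1 if n > 1 else 1, p)
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    Xk = Xs.copy()
    yk = ys.copy()
    used = 0
    for a in range(A):
        w = Xk.T @ yk
        wn = np.linalg.norm(w)
        if wn < 1e-12:
            break
        w /= wn
        t = Xk @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        P[:, a] = Xk.T @ t / tt
        q[a] = float(yk @ t) / tt
        W[:, a] = w
        T[:, a] = t
        Xk -= np.outer(t, P[:, a])
        yk = yk - q[a] * t
        used += 1
    W, P, q, T = W[:, :used], P[:, :used], q[:used], T[:, :used]
    betas = np.zeros((p, used))
    for a in range(1, used + 1):
        # P' W is unit upper triangular for NIPALS; small solve is cheap.
        coef = np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
        betas[:, a - 1] = W[:, :a] @ coef
    return W, P, q, T, betas


def _cv_folds(n: int, k: int) -> list[np.ndarray]:
    """Deterministic contiguous k-fold partition of range(n)."""
    k = max(2, min(k, n))
    return [np.arange(n)[i::k] for i in range(k)]


def _cv_sse(X_raw: np.ndarray, y_raw: np.ndarray,
            max_latent: int, cv_folds: int) -> np.ndarray:
    """Cross-validated squared-error sums per PLS component count (1..A_cap).

    Deterministic contiguous folds; scalers are refitted inside each training
    fold.  Components a fold cannot support reuse its deepest available one.
    """
    n = len(y_raw)
    folds = _cv_folds(n, cv_folds)
    A_cap = min(max_latent, n - 1 - max(len(f) for f in folds), X_raw.shape[1])
    A_cap = max(A_cap, 1)
    sse = np.zeros(A_cap)
    for val_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        Xtr, ytr = X_raw[mask], y_raw[mask]
        xs = Scaler.fit(Xtr)
        ymu, ysd = float(ytr.mean()), float(ytr.std(ddof=0))
        if ysd <= 0:
            continue
        *_, betas = _nipals(xs.transform(Xtr), (ytr - ymu) / ysd, A_cap)
        if betas.shape[1] == 0:
            sse += ((y_raw[val_idx] - ymu) ** 2).sum()
            continue
        preds = xs.transform(X_raw[val_idx]) @ betas * ysd + ymu   # (n_val, A_used)
        resid = preds - y_raw[val_idx][:, None]
        a_used = betas.shape[1]
        sse[:a_used] += (resid ** 2).sum(axis=0)
        if a_used < A_cap:
            sse[a_used:] += (resid[:, -1] ** 2).sum()
    return sse


def _select_n_latent_cv(X_raw: np.ndarray, y_raw: np.ndarray,
                        max_latent: int, cv_folds: int) -> int:
    """Number of PLS components minimising k-fold CV RMSE (1..max_latent)."""
    return int(np.argmin(_cv_sse(X_raw, y_raw, max_latent, cv_folds))) + 1


def fit_plsr(X, y, n_latent: int | str = "cv", subset=None,
             max_latent: int = 15, cv_folds: int = 5) -> FittedModel:
    """NIPALS partial least-squares regression on standardized X and y.

    ``n_latent="cv"`` selects the component count minimising deterministic
    k-fold cross-validated RMSE over 1..``max_latent``.
    """
    X_full, y, indices = _as_xy(X, y, subset)
    Xsub = _apply_subset(X_full, indices)
    n, p = Xsub.shape
    if isinstance(n_latent, str):
        if n_latent != "cv":
            raise ParameterError(f"n_latent must be an int or 'cv', got {n_latent!r}")
        A = _select_n_latent_cv(Xsub, y, max_latent, cv_folds)
    else:
        A = int(n_latent)
        if A < 1 or A > min(n - 1, p):
            raise ParameterError(
                f"n_latent={A} outside [1, min(n_samples-1, n_bands)={min(n - 1, p)}]"
            )
    xs = Scaler.fit(Xsub)
    ymu, ysd = _fit_y_scaler(y)
    W, P, q, T, betas = _nipals(xs.transform(Xsub), (y - ymu) / ysd, A)
    if betas.shape[1] == 0:
        raise DegenerateTargetError("PLS found no usable component")
    beta = betas[:, -1]
    return FittedModel(
        kind="plsr",
        n_bands_full=X_full.shape[1],
        band_indices=indices,
        x_scaler=xs,
        y_mean=ymu,
        y_sd=ysd,
        hyperparams={"n_latent": int(betas.shape[1])},
        params={"beta": beta, "weights": W, "loadings": P, "q": q, "x_scores": T},
    )


# ---------------------------------------------------------------------------
# Interval PLS family
# ---------------------------------------------------------------------------

def _interval_indices(interval: tuple[int, int]) -> np.ndarray:
    lo, hi = interval
    return np.arange(lo, hi)


def _score_bands(X_full: np.ndarray, y: np.ndarray, band_idx: np.ndarray,
                 max_latent: int, cv_folds: int) -> tuple[float, int]:
    """Interval-search criterion for a candidate band set.

    Cross-validated calibration residuals plugged into the RMSEC form
    ``sqrt(sum(resid^2) / (N - 1 - R))`` with R = the CV-selected component
    count (capped by the band-set width).  Returns (criterion, n_latent).
    Out-of-fold residuals (rather than refit residuals) are what lets the
    search discard uninformative intervals instead of rewarding sheer width.
    """
    ysd = y.std(ddof=0)
    cap = min(max_latent, len(band_idx))
    sse = _cv_sse(X_full[:, band_idx], y, cap, cv_folds)
    A = int(np.argmin(sse)) + 1
    N = len(y)
    if N <= A + 1:
        raise ParameterError(f"too few samples (N={N}) for {A} components")
    # standardized-target units so criteria are comparable across targets
    return float(np.sqrt(sse[A - 1] / (N - 1 - A)) / ysd), A


def _factor_count(model: FittedModel) -> int:
    """The R of the RMSEC denominator: latent count for the PLS family,
    2 for LS-SVM (gamma, sigma^2), 1 nominal for the network."""
    if model.kind in ("plsr", "ipls", "sipls", "bipls"):
        return int(model.hyperparams["n_latent"])
    if model.kind == "lssvm":
        return 2
    return 1


def _final_fit(X_full: np.ndarray, y: np.ndarray, band_idx: np.ndarray,
               n_latent: int) -> FittedModel:
    return fit_plsr(X_full, y, n_latent=n_latent, subset=band_idx)


def fit_ipls(X, y, n_intervals: int, max_latent: int = 10,
             cv_folds: int = 5) -> FittedModel:
    """Interval PLS: one PLSR per equidistant interval, keep the best interval.

    Intervals are scored by cross-validated calibration RMSE (N-1-R form);
    ties break to the lowest interval index.  The latent count per interval
    is CV-selected, capped by the interval width.
    """
    from .selection import make_intervals

    X_full, y, _ = _as_xy(X, y, None)
    intervals = make_intervals(X_full.shape[1], n_intervals)
    best = None
    for idx, interval in enumerate(intervals):
        band_idx = _interval_indices(interval)
        score, A = _score_bands(X_full, y, band_idx, max_latent, cv_folds)
        if best is None or score < best[0]:
            best = (score, idx, band_idx, A)
    score, idx, band_idx, A = best
    model = _final_fit(X_full, y, band_idx, A)
    model.kind = "ipls"
    model.meta["interval"] = idx
    model.meta["n_intervals"] = n_intervals
    model.meta["cv_rmsec"] = score
    return model


def fit_sipls(X, y, n_intervals: int, combo_size: int, max_latent: int = 10,
              cv_folds: int = 5, budget: int = SIPLS_BUDGET) -> FittedModel:
    """Synergy interval PLS: exhaustive search over interval combinations,
    scored like :func:`fit_ipls`; ties break to the lexicographically first
    combination."""
    from math import comb

    from .selection import make_intervals

    if combo_size < 1 or combo_size > n_intervals:
        raise ParameterError("combo_size must lie in [1, n_intervals]")
    if comb(n_intervals, combo_size) > budget:
        raise BudgetError(
            f"{comb(n_intervals, combo_size)} combinations exceed budget {budget}; "
            "reduce n_intervals or combo_size"
        )
    X_full, y, _ = _as_xy(X, y, None)
    intervals = make_intervals(X_full.shape[1], n_intervals)
    best = None
    for combo in combinations(range(n_intervals), combo_size):
        band_idx = np.concatenate([_interval_indices(intervals[i]) for i in combo])
        score, A = _score_bands(X_full, y, band_idx, max_latent, cv_folds)
        if best is None or score < best[0]:
            best = (score, combo, band_idx, A)
    score, combo, band_idx, A = best
    model = _final_fit(X_full, y, band_idx, A)
    model.kind = "sipls"
    model.meta["combination"] = list(combo)
    model.meta["n_intervals"] = n_intervals
    model.meta["cv_rmsec"] = score
    return model


def fit_bipls(X, y, n_intervals: int, max_latent: int = 10,
              cv_folds: int = 5) -> FittedModel:
    """Backward interval PLS.

    Each surviving interval is omitted in turn; the omission giving the
    lowest cross-validated calibration RMSE is made permanent, and removal
    continues until no omission improves the criterion (or one interval
    remains).  Returns the PLSR on the surviving bands plus the elimination
    trace.
    """
    from .selection import make_intervals

    if n_intervals < 2:
        raise ParameterError("BiPLS needs n_intervals >= 2")
    X_full, y, _ = _as_xy(X, y, None)
    intervals = make_intervals(X_full.shape[1], n_intervals)

    def score_of(surviving: list[int]) -> tuple[float, int, np.ndarray]:
        band_idx = np.concatenate([_interval_indices(intervals[i]) for i in surviving])
        s, A = _score_bands(X_full, y, band_idx, max_latent, cv_folds)
        return s, A, band_idx

    surviving = list(range(n_intervals))
    current, A_best, bands_best = score_of(surviving)
    trace: list[dict] = []
    while len(surviving) > 1:
        candidates = []
        for drop in surviving:
            remain = [i for i in surviving if i != drop]
            s, A, band_idx = score_of(remain)
            candidates.append((s, drop, remain, A, band_idx))
        s, drop, remain, A, band_idx = min(candidates, key=lambda c: (c[0], c[1]))
        if s < current:
            surviving, current, A_best, bands_best = remain, s, A, band_idx
            trace.append({"dropped": drop, "cv_rmsec": s})
        else:
            break
    model = _final_fit(X_full, y, bands_best, A_best)
    model.kind = "bipls"
    model.meta["surviving_intervals"] = surviving
    model.meta["n_intervals"] = n_intervals
    model.meta["trace"] = trace
    model.meta["cv_rmsec"] = current
    return model


# ---------------------------------------------------------------------------
# LS-SVM
# ---------------------------------------------------------------------------

def _rbf_kernel_sq(sqdist: np.ndarray, sigma2: float) -> np.ndarray:
    return np.exp(-sqdist / sigma2)


def _pairwise_sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    d = (A ** 2).sum(axis=1)[:, None] + (B ** 2).sum(axis=1)[None, :] - 2.0 * A @ B.T
    return np.maximum(d, 0.0)


def _solve_lssvm_dual(K: np.ndarray, ys: np.ndarray, gamma: float):
    """Solve the bias-constrained LS-SVM dual: [[0 1'],[1 K+I/g]][b;a]=[0;y]."""
    n = len(ys)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], ys])
    try:
        z = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        z = None
    if z is None or np.linalg.norm(A @ z - rhs) > 1e-6 * (1.0 + np.linalg.norm(rhs)):
        # jitter-and-retry once, then give up
        A[1:, 1:] += 1e-10 * np.eye(n)
        try:
            z = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise SolverError("LS-SVM dual system is singular") from exc
        if np.linalg.norm(A @ z - rhs) > 1e-6 * (1.0 + np.linalg.norm(rhs)):
            raise SolverError("LS-SVM dual residual above tolerance")
    return float(z[0]), z[1:]


def fit_lssvm(X, y, gamma: float | str = "grid", sigma2: float | str = "grid",
              subset=None, grid: tuple = LSSVM_GRID, cv_folds: int = 5) -> FittedModel:
    """LS-SVM regression with an RBF kernel, exact dual solve.

    ``"grid"`` for either hyperparameter triggers a cross-validated search
    over log-spaced values in (1e-3, 1000] (both axes searched jointly when
    both are ``"grid"``).
    """
    X_full, y, indices = _as_xy(X, y, subset)
    Xsub = _apply_subset(X_full, indices)
    xs = Scaler.fit(Xsub)
    ymu, ysd = _fit_y_scaler(y)
    Xs = xs.transform(Xsub)
    ys = (y - ymu) / ysd
    n = len(ys)

    gammas = list(grid) if isinstance(gamma, str) else [float(gamma)]
    sigmas = list(grid) if isinstance(sigma2, str) else [float(sigma2)]
    if any(g <= 0 for g in gammas) or any(s <= 0 for s in sigmas):
        raise ParameterError("gamma and sigma2 must be positive")

    if len(gammas) * len(sigmas) > 1:
        folds = _cv_folds(n, cv_folds)
        sqd = _pairwise_sqdist(Xs, Xs)
        best = None
        for s2 in sigmas:
            Kfull = _rbf_kernel_sq(sqd, s2)
            for g in gammas:
                sse = 0.0
                for val_idx in folds:
                    mask = np.ones(n, dtype=bool)
                    mask[val_idx] = False
                    tr = np.where(mask)[0]
                    b, alpha = _solve_lssvm_dual(Kfull[np.ix_(tr, tr)], ys[tr], g)
                    pred = Kfull[np.ix_(val_idx, tr)] @ alpha + b
                    sse += float(((pred - ys[val_idx]) ** 2).sum())
                rmse = np.sqrt(sse / n)
                if best is None or rmse < best[0]:
                    best = (rmse, g, s2)
        _, g_best, s2_best = best
    else:
        g_best, s2_best = gammas[0], sigmas[0]

    K = _rbf_kernel_sq(_pairwise_sqdist(Xs, Xs), s2_best)
    b, alpha = _solve_lssvm_dual(K, ys, g_best)
    return FittedModel(
        kind="lssvm",
        n_bands_full=X_full.shape[1],
        band_indices=indices,
        x_scaler=xs,
        y_mean=ymu,
        y_sd=ysd,
        hyperparams={"gamma": float(g_best), "sigma2": float(s2_best)},
        params={"alphas": alpha, "bias": np.array([b]), "support": Xs},
    )


# ---------------------------------------------------------------------------
# BP-ANN
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def fit_bpann(X, y, hidden_size: int = 10, seed: int = 0, subset=None,
              max_epochs: int = 1000, goal: float = 1e-5,
              learning_rate: float = 0.01, momentum: float = 0.01) -> FittedModel:
    """Single-hidden-layer backpropagation network (sigmoid hidden, linear out).

    Full-batch gradient descent with momentum on standardized data; training
    stops when the mean-squared training loss reaches ``goal`` or after
    ``max_epochs`` epochs.  Deterministic given ``seed``.
    """
    if hidden_size < 1:
        raise ParameterError("hidden_size must be >= 1")
    X_full, y, indices = _as_xy(X, y, subset)
    Xsub = _apply_subset(X_full, indices)
    xs = Scaler.fit(Xsub)
    ymu, ysd = _fit_y_scaler(y)
    Xs = xs.transform(Xsub)
    ys = (y - ymu) / ysd
    n, p = Xs.shape

    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-1.0, 1.0, size=(p, hidden_size)) / np.sqrt(p)
    b1 = np.zeros(hidden_size)
    W2 = rng.uniform(-1.0, 1.0, size=hidden_size) / np.sqrt(hidden_size)
    b2 = 0.0
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = 0.0

    def forward(A):
        H = _sigmoid(A @ W1 + b1)
        return H, H @ W2 + b2

    H, out = forward(Xs)
    loss = float(np.mean((out - ys) ** 2))
    epochs_run = 0
    for epoch in range(max_epochs):
        if loss <= goal:
            break
        err = out - ys                              # (n,)
        gW2 = H.T @ err * (2.0 / n)
        gb2 = float(err.mean() * 2.0)
        dH = np.outer(err, W2) * H * (1.0 - H)      # (n, h)
        gW1 = Xs.T @ dH * (2.0 / n)
        gb1 = dH.sum(axis=0) * (2.0 / n)
        vW2 = momentum * vW2 - learning_rate * gW2
        vb2 = momentum * vb2 - learning_rate * gb2
        vW1 = momentum * vW1 - learning_rate * gW1
        vb1 = momentum * vb1 - learning_rate * gb1
        W2 = W2 + vW2
        b2 = b2 + vb2
        W1 = W1 + vW1
        b1 = b1 + vb1
        H, out = forward(Xs)
        loss = float(np.mean((out - ys) ** 2))
        epochs_run = epoch + 1
        if not np.isfinite(loss):
            raise TrainingError(f"BP-ANN diverged (loss NaN) at epoch {epochs_run}")

    return FittedModel(
        kind="bpann",
        n_bands_full=X_full.shape[1],
        band_indices=indices,
        x_scaler=xs,
        y_mean=ymu,
        y_sd=ysd,
        hyperparams={"hidden_size": hidden_size, "max_epochs": max_epochs,
                     "goal": goal, "learning_rate": learning_rate,
                     "momentum": momentum, "epochs_run": epochs_run,
                     "final_loss": loss},
        params={"W1": W1, "b1": b1, "W2": W2, "b2": np.array([b2])},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Prediction and serialization
# ---------------------------------------------------------------------------

def predict(model: FittedModel, X_new) -> np.ndarray:
    """Apply a fitted model to new full-grid spectra; pure function.

    The model's wavelength subset and scalers are applied internally; output
    is in raw target units.
    """
    if isinstance(X_new, SpectraMatrix):
        X_new = X_new.X
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    if X_new.shape[1] != model.n_bands_full:
        raise ConsistencyError(
            f"X has {X_new.shape[1]} bands; model expects {model.n_bands_full}"
        )
    Xs = model.x_scaler.transform(_apply_subset(X_new, model.band_indices))
    if model.kind in ("plsr", "ipls", "sipls", "bipls"):
        z = Xs @ model.params["beta"]
    elif model.kind == "lssvm":
        K = _rbf_kernel_sq(
            _pairwise_sqdist(Xs, model.params["support"]),
            model.hyperparams["sigma2"],
        )
        z = K @ model.params["alphas"] + model.params["bias"][0]
    elif model.kind == "bpann":
        H = _sigmoid(Xs @ model.params["W1"] + model.params["b1"])
        z = H @ model.params["W2"] + model.params["b2"][0]
    else:
        raise ParameterError(f"unknown model kind {model.kind!r}")
    return z * model.y_sd + model.y_mean


def save_model(model: FittedModel, path: str | Path) -> None:
    """Single-file .npz archive with a format-version tag."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "archive_version": ARCHIVE_VERSION,
        "kind": model.kind,
        "n_bands_full": model.n_bands_full,
        "y_mean": model.y_mean,
        "y_sd": model.y_sd,
        "hyperparams": model.hyperparams,
        "seed": model.seed,
        "meta": model.meta,
        "param_keys": sorted(model.params),
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays["x_mean"] = model.x_scaler.mean
    arrays["x_sd"] = model.x_scaler.sd
    if model.band_indices is not None:
        arrays["band_indices"] = model.band_indices
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path) -> FittedModel:
    with np.load(path, allow_pickle=False) as archive:
        header = json.loads(bytes(archive["header"]).decode())
        if header["archive_version"] > ARCHIVE_VERSION:
            raise FormatError(
                f"model archive version {header['archive_version']} is newer "
                f"than supported ({ARCHIVE_VERSION})"
            )
        params = {k: archive[f"param_{k}"] for k in header["param_keys"]}
        band_indices = archive["band_indices"] if "band_indices" in archive else None
        return FittedModel(
            kind=header["kind"],
            n_bands_full=header["n_bands_full"],
            band_indices=band_indices,
            x_scaler=Scaler(archive["x_mean"], archive["x_sd"]),
            y_mean=header["y_mean"],
            y_sd=header["y_sd"],
            hyperparams=header["hyperparams"],
            params=params,
            seed=header["seed"],
            meta=header["meta"],
        )
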