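"""Single-response partial least squares regression (NIPALS) with k-fold
cross-validation and delete-a-group jackknife coefficient variances.

Standardization uses the population (divide-by-n) standard deviation.  In
standardized space the intercept is zero; predictions on the raw scale are
recovered through the stored standardization parameters.  Cross-validation
standardizes within the training part of each fold only, so held-out rows
never leak into the scaling.

The number of components, when not given, is the smallest A whose pooled
cross-validated R² comes within ``component_tol`` (default 0.002) of the
maximum over A = 1..min(15, rank).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MAX_COMPONENTS = 15
COMPONENT_TOL = 0.002
DEFAULT_CV_SEED = 20140206


@dataclass(frozen=True)
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def inverse(self, Xz: np.ndarray) -> np.ndarray:
        return Xz * self.sd + self.mean


@dataclass
class PLSModel:
    n_components: int
    x_weights: np.ndarray   # p x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    beta: np.ndarray        # p, standardized space
    beta0: float            # standardized space (0 up to numerical tolerance)
    x_standardization: StandardizationParams | None = None
    y_standardization: StandardizationParams | None = None
    predictor_names: tuple[str, ...] | None = None

    def predict_z(self, Xz: np.ndarray) -> np.ndarray:
        return Xz @ self.beta + self.beta0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict on the raw scale (requires stored standardization)."""
        if self.x_standardization is None or self.y_standardization is None:
            raise ValueError("model has no standardization parameters")
        Xz = self.x_standardization.transform(np.asarray(X, float))
        yz = self.predict_z(Xz)
        return self.y_standardization.inverse(yz)

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = {
            "n_components": self.n_components,
            "beta": self.beta.tolist(),
            "beta0": self.beta0,
            "predictor_names": list(self.predictor_names or []),
            "x_mean": self.x_standardization.mean.tolist()
            if self.x_standardization
            else None,
            "x_sd": self.x_standardization.sd.tolist()
            if self.x_standardization
            else None,
            "y_mean": float(self.y_standardization.mean)
            if self.y_standardization
            else None,
            "y_sd": float(self.y_standardization.sd)
            if self.y_standardization
            else None,
        }
        payload.update(extra or {})
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class CVResult:
    k: int
    fold_assignment: np.ndarray          # per-row fold id
    cv_r2: float
    per_fold_beta: np.ndarray            # k x p, standardized space, chosen A
    seed: int
    n_components: int
    cv_r2_by_components: np.ndarray      # indexed by A-1


@dataclass(frozen=True)
class JackknifeEstimates:
    se: np.ndarray
    t_like: np.ndarray


# ---------------------------------------------------------------------------

def standardize(
    X: np.ndarray | pd.DataFrame, y: np.ndarray | pd.Series
) -> tuple[np.ndarray, np.ndarray, tuple[StandardizationParams, StandardizationParams]]:
    """z-score X columns and y with the population-sd convention."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    mx, sx = Xa.mean(axis=0), Xa.std(axis=0)
    if np.any(sx == 0):
        if names is not None:
            bad = [names[i] for i in np.flatnonzero(sx == 0)]
        else:
            bad = list(np.flatnonzero(sx == 0))
        raise ValueError(f"zero-variance column(s): {bad}")
    my, sy = ya.mean(), ya.std()
    if sy == 0:
        raise ValueError("zero-variance response")
    xp = StandardizationParams(mean=mx, sd=sx)
    yp = StandardizationParams(mean=np.array(my), sd=np.array(sy))
    return xp.transform(Xa), (ya - my) / sy, (xp, yp)


def _nipals_path(Xz: np.ndarray, yz: np.ndarray, a_max: int):
    """Sequential PLS1 components; returns per-A coefficient vectors.

    betas[a-1] reconstructs the fitted linear map with a components.
    """
    n, p = Xz.shape
    X = Xz.copy()
    y = yz.copy()
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    q = np.zeros(a_max)
    R = np.zeros((p, a_max))   # R = W (P'W)^-1, built recursively
    betas = np.zeros((a_max, p))
    beta = np.zeros(p)
    a_eff = 0
    for a in range(a_max):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pa = X.T @ t / tt
        qa = float(y @ t) / tt
        X = X - np.outer(t, pa)
        y = y - qa * t
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        W[:, a], P[:, a], q[a], R[:, a] = w, pa, qa, r
        beta = beta + qa * r
        betas[a] = beta
        a_eff = a + 1
    # pad with the last attainable map if rank ran out early
    for a in range(a_eff, a_max):
        betas[a] = betas[a_eff - 1] if a_eff else 0.0
    return betas, W[:, :a_eff], P[:, :a_eff], q[:a_eff], a_eff


def fit_pls(
    Xz: np.ndarray,
    yz: np.ndarray,
    n_components: int,
    predictor_names: Sequence[str] | None = None,
) -> PLSModel:
    """NIPALS PLS1 on standardized data."""
    Xz = np.asarray(Xz, float)
    yz = np.asarray(yz, float)
    rank = min(Xz.shape[0] - 1, Xz.shape[1])
    if not (1 <= n_components <= max(rank, 1)):
        raise ValueError(
            f"n_components {n_components} outside 1..rank ({rank})"
        )
    betas, W, P, q, a_eff = _nipals_path(Xz, yz, n_components)
    beta = betas[min(n_components, a_eff) - 1]
    return PLSModel(
        n_components=min(n_components, a_eff),
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        beta=beta,
        beta0=0.0,
        predictor_names=tuple(predictor_names) if predictor_names is not None else None,
    )


def fit_pls_raw(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_components: int,
) -> PLSModel:
    """Standardize then fit; stores the transform for raw-scale prediction."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xz, yz, (xp, yp) = standardize(X, y)
    model = fit_pls(Xz, yz, n_components, predictor_names=names)
    model.x_standardization = xp
    model.y_standardization = yp
    return model


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded random partition into k near-equal folds."""
    rng = np.random.default_rng(seed)
    assignment = np.arange(n) % k  # sizes differ by at most one
    rng.shuffle(assignment)
    return assignment


def cross_validate(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_components: int | None = None,
    k: int = 10,
    seed: int = DEFAULT_CV_SEED,
    max_components: int = MAX_COMPONENTS,
    component_tol: float = COMPONENT_TOL,
) -> CVResult:
    """k-fold CV with within-fold standardization and pooled held-out R².

    When ``n_components`` is None the component count is chosen as the
    smallest A whose pooled CV R² is within ``component_tol`` of the maximum.
    """
    Xa = np.asarray(X, float)
    ya = np.asarray(y, float)
    n, p = Xa.shape
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if n < 2 * k:
        raise ValueError(f"need n >= 2k rows (n={n}, k={k})")
    folds = make_folds(n, k, seed)
    a_max = (
        n_components
        if n_components is not None
        else min(max_components, p, n - n // k - 1)
    )
    a_max = max(a_max, 1)

    preds = np.zeros((n, a_max))
    fold_betas_all = np.zeros((k, a_max, p))
    for f in range(k):
        tr = folds != f
        te = ~tr
        mx, sx = Xa[tr].mean(axis=0), Xa[tr].std(axis=0)
        sx = np.where(sx == 0, 1.0, sx)
        my, sy = ya[tr].mean(), ya[tr].std()
        Xz_tr = (Xa[tr] - mx) / sx
        yz_tr = (ya[tr] - my) / sy
        betas, *_ = _nipals_path(Xz_tr, yz_tr, a_max)
        Xz_te = (Xa[te] - mx) / sx
        preds[te] = my + sy * (Xz_te @ betas.T)
        fold_betas_all[f] = betas

    sst = float(((ya - ya.mean()) ** 2).sum())
    r2_by_a = 1.0 - ((ya[:, None] - preds) ** 2).sum(axis=0) / sst

    if n_components is None:
        best = float(r2_by_a.max())
        a_star = int(np.argmax(r2_by_a >= best - component_tol)) + 1
    else:
        a_star = n_components
    return CVResult(
        k=k,
        fold_assignment=folds,
        cv_r2=float(r2_by_a[a_star - 1]),
        per_fold_beta=fold_betas_all[:, a_star - 1, :],
        seed=seed,
        n_components=a_star,
        cv_r2_by_components=r2_by_a,
    )


def jackknife_se(per_fold_beta: np.ndarray) -> JackknifeEstimates:
    """Delete-a-group jackknife over CV folds.

    se_j = sqrt(((k-1)/k) * sum_i (beta_ij - mean_j)^2)
    """
    B = np.asarray(per_fold_beta, float)
    k = B.shape[0]
    if k < 2:
        raise ValueError("jackknife needs at least 2 folds")
    mean = B.mean(axis=0)
    se = np.sqrt((k - 1) / k * ((B - mean) ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, np.abs(mean) / se, np.where(mean == 0, 0.0, np.inf))
    return JackknifeEstimates(se=se, t_like=t)
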