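"""Stepwise backward elimination over the design table.

Starting from all predictors, each step fits a cross-validated PLS model,
computes jackknife t-like statistics |beta|/se for every coefficient, and
proposes removing the predictor with the smallest t (ties broken by smaller
|beta|, then lexicographic name).  A removal is accepted when the
cross-validated R² of the reduced model does not drop by more than ``tol``;
otherwise the predictor is shielded for the current pass and the next
candidate is tried.  The procedure terminates when no predictor can be
removed.  One predictor is removed per accepted step, and the PLS component
count is re-chosen after every removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pls_regression import (
    COMPONENT_TOL,
    DEFAULT_CV_SEED,
    MAX_COMPONENTS,
    CVResult,
    PLSModel,
    cross_validate,
    fit_pls_raw,
    jackknife_se,
)


@dataclass(frozen=True)
class SelectionConfig:
    k: int = 10
    seed: int = DEFAULT_CV_SEED
    tol: float = 0.002
    protected: frozenset[str] = frozenset()
    max_components: int = MAX_COMPONENTS
    component_tol: float = COMPONENT_TOL


@dataclass
class StepRecord:
    removed: str
    cv_r2_before: float
    cv_r2_after: float


@dataclass
class SelectionResult:
    surviving: list[str]
    trajectory: list[StepRecord]
    final_model: PLSModel
    final_cv: CVResult
    initial_cv_r2: float

    @property
    def final_cv_r2(self) -> float:
        return self.final_cv.cv_r2

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(1, len(self.trajectory) + 1),
                "removed": [s.removed for s in self.trajectory],
                "cv_r2_before": [s.cv_r2_before for s in self.trajectory],
                "cv_r2_after": [s.cv_r2_after for s in self.trajectory],
            }
        )

    def write_trajectory(self, path: str | Path) -> None:
        self.trajectory_frame().to_csv(path, sep="\t", index=False)


def _cv(X: pd.DataFrame, y, cfg: SelectionConfig) -> CVResult:
    return cross_validate(
        X,
        y,
        n_components=None,
        k=cfg.k,
        seed=cfg.seed,
        max_components=cfg.max_components,
        component_tol=cfg.component_tol,
    )


def backward_eliminate(
    table,
    response: Sequence[float] | np.ndarray,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Eliminate uninformative predictors while preserving CV R².

    ``table`` is a :class:`~seq2abundance.feature_catalog.FeatureTable` or a
    plain DataFrame of predictors.  ``response`` is the (raw-scale) response
    vector, typically log10 protein abundance.  Deterministic given the
    config seed.
    """
    cfg = config or SelectionConfig()
    X = table.data if hasattr(table, "data") else table
    if not isinstance(X, pd.DataFrame):
        raise TypeError("table must be a FeatureTable or DataFrame")
    if X.shape[1] == 0 or X.shape[0] == 0:
        raise ValueError("empty design table")
    y = np.asarray(response, float)
    if len(y) != X.shape[0]:
        raise ValueError("response length does not match table rows")

    current = list(X.columns)
    trajectory: list[StepRecord] = []
    cv_cur = _cv(X[current], y, cfg)
    initial_cv_r2 = cv_cur.cv_r2

    # constant predictors carry no information and cannot be standardized;
    # drop them immediately (recorded as ordinary removals)
    sds = X[current].std(ddof=0)
    for name in [c for c in current if sds[c] == 0 and c not in cfg.protected]:
        trajectory.append(
            StepRecord(removed=name, cv_r2_before=cv_cur.cv_r2,
                       cv_r2_after=cv_cur.cv_r2)
        )
        current.remove(name)
    if trajectory:
        cv_cur = _cv(X[current], y, cfg)

    while len(current) > 1:
        jk = jackknife_se(cv_cur.per_fold_beta)
        beta = cv_cur.per_fold_beta.mean(axis=0)
        order = sorted(
            range(len(current)),
            key=lambda i: (jk.t_like[i], abs(beta[i]), current[i]),
        )
        accepted = False
        for idx in order:
            name = current[idx]
            if name in cfg.protected:
                continue
            reduced = [c for c in current if c != name]
            cv_new = _cv(X[reduced], y, cfg)
            if cv_new.cv_r2 >= cv_cur.cv_r2 - cfg.tol:
                trajectory.append(
                    StepRecord(
                        removed=name,
                        cv_r2_before=cv_cur.cv_r2,
                        cv_r2_after=cv_new.cv_r2,
                    )
                )
                current = reduced
                cv_cur = cv_new
                accepted = True
                break
        if not accepted:
            break

    final_model = fit_pls_raw(X[current], y, cv_cur.n_components)
    return SelectionResult(
        surviving=current,
        trajectory=trajectory,
        final_model=final_model,
        final_cv=cv_cur,
        initial_cv_r2=initial_cv_r2,
    )
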