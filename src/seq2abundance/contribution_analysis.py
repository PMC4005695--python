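"""Per-gene decomposition of predictions into mRNA / TIR / CDS contributions,
variance attribution by predictor group, and the expression-profile views.

For a linear model in standardized space, the contribution of a predictor
group g to gene i's prediction is sum_{j in g} beta_j * xz_ij, so group
contributions plus the intercept reproduce the prediction exactly.  Variance
attribution uses a normalized covariance decomposition: the raw share of
group g is sum_{j in g} beta_j * r(xz_j, yz); shares are rescaled so they sum
exactly to the model R² (squared correlation of prediction with response),
which reduces to per-predictor r² under orthogonality.  An alternative
sequential-R² attribution is available for sensitivity analysis.

The model's transcription estimate is the mRNA contribution; its translation
efficiency estimate is the aggregated TIR + CDS contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pls_regression import PLSModel

GROUPS = ("mRNA", "TIR", "CDS")


@dataclass(frozen=True)
class VarianceShares:
    share: dict[str, float]
    model_r2: float
    raw: dict[str, float]

    @property
    def negative_groups(self) -> list[str]:
        return [g for g, v in self.raw.items() if v < 0]


def _model_arrays(model: PLSModel, Xz: pd.DataFrame):
    if model.predictor_names is not None:
        missing = [c for c in model.predictor_names if c not in Xz.columns]
        if missing:
            raise ValueError(f"table lacks model predictors {missing}")
        Xz = Xz[list(model.predictor_names)]
    return Xz, np.asarray(Xz, float), model.beta


def group_contribution(
    model: PLSModel,
    Xz: pd.DataFrame,
    group_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per-gene contribution of each predictor group, standardized-response units.

    Returns a frame indexed like ``Xz`` with one column per group plus
    ``prediction``; contributions + beta0 = prediction exactly.
    """
    Xz, Xa, beta = _model_arrays(model, Xz)
    groups = {}
    for j, col in enumerate(Xz.columns):
        g = group_of.get(col)
        if g is None or g not in GROUPS:
            raise ValueError(f"unknown group label for column {col!r}: {g!r}")
        groups.setdefault(g, []).append(j)
    out = pd.DataFrame(index=Xz.index)
    for g in GROUPS:
        idx = groups.get(g, [])
        out[g] = Xa[:, idx] @ beta[idx] if idx else 0.0
    out["prediction"] = Xa @ beta + model.beta0
    return out


def variance_shares(
    model: PLSModel,
    Xz: pd.DataFrame,
    yz: np.ndarray | pd.Series,
    group_of: Mapping[str, str],
    method: str = "covariance",
) -> VarianceShares:
    """Attribute the model R² to predictor groups.

    ``method="covariance"`` (default): normalized covariance decomposition.
    ``method="sequential"``: incremental R² adding groups in the order
    mRNA, CDS, TIR (sensitivity alternative).
    """
    Xz, Xa, beta = _model_arrays(model, Xz)
    ya = np.asarray(yz, float)
    ya = (ya - ya.mean()) / ya.std()
    pred = Xa @ beta + model.beta0
    if pred.std() == 0:
        raise ValueError("degenerate model: constant prediction")
    model_r2 = float(np.corrcoef(pred, ya)[0, 1] ** 2)

    cols_by_group: dict[str, list[int]] = {g: [] for g in GROUPS}
    for j, col in enumerate(Xz.columns):
        cols_by_group[group_of[col]].append(j)

    if method == "sequential":
        share = {}
        used: list[int] = []
        prev = 0.0
        for g in GROUPS:
            used += cols_by_group[g]
            sub = Xa[:, used]
            bsub = np.linalg.lstsq(sub, ya, rcond=None)[0]
            r2 = float(np.corrcoef(sub @ bsub, ya)[0, 1] ** 2)
            share[g] = r2 - prev
            prev = r2
        return VarianceShares(share=share, model_r2=prev, raw=dict(share))

    zx = (Xa - Xa.mean(axis=0)) / np.where(Xa.std(axis=0) == 0, 1, Xa.std(axis=0))
    r = zx.T @ ya / len(ya)
    raw = {g: float(np.sum(beta[idx] * r[idx])) for g, idx in cols_by_group.items()}
    total = sum(raw.values())
    if total == 0:
        raise ValueError("degenerate model: covariance decomposition sums to zero")
    share = {g: v / total * model_r2 for g, v in raw.items()}
    return VarianceShares(share=share, model_r2=model_r2, raw=raw)


def abundance_groups(
    protein_means: Sequence[float] | np.ndarray,
    quartiles: tuple[float, float] = (0.25, 0.75),
) -> np.ndarray:
    """Label genes low / medium / high by the lower and upper quartiles.

    Quantiles use linear interpolation; boundary ties go to ``medium``
    (strict inequalities).
    """
    x = np.asarray(protein_means, float)
    if len(x) < 4:
        raise ValueError("need at least 4 genes")
    q1, q3 = np.quantile(x, quartiles)
    labels = np.full(len(x), "medium", dtype=object)
    labels[x < q1] = "low"
    labels[x > q3] = "high"
    return labels


def efficiency_estimates(
    contributions: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Transcription (mRNA contribution) vs translation efficiency (TIR + CDS).

    Returns (transcription, translation_efficiency, pearson_r); r is NaN when
    either vector is constant.
    """
    for g in GROUPS:
        if g not in contributions.columns:
            raise ValueError(f"missing group column {g!r}")
    transcription = contributions["mRNA"].to_numpy()
    translation = (contributions["TIR"] + contributions["CDS"]).to_numpy()
    if transcription.std() == 0 or translation.std() == 0:
        return transcription, translation, math.nan
    r = float(np.corrcoef(transcription, translation)[0, 1])
    return transcription, translation, r


def contribution_histogram2d(
    contributions: pd.DataFrame,
    x_group: str = "mRNA",
    y_group: str = "CDS",
    bins: int = 10,
) -> pd.DataFrame:
    """Gene-count matrix over binned group contributions (heatmap export)."""
    x = contributions[x_group]
    y = contributions[y_group]
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    return pd.DataFrame(
        counts.astype(int),
        index=pd.Index(np.round(xe[:-1], 4), name=f"{x_group}_bin"),
        columns=np.round(ye[:-1], 4),
    )
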