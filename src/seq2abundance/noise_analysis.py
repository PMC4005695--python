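"""Expression-noise statistics.

The coefficient of variation CoV = sigma/mu measures cell-to-cell protein
variability.  Because CoV falls with mean abundance, a gene's *noise
differential* is its CoV minus the median CoV of genes with similar
abundance — estimated with a centered rank window (default 51 genes,
truncated at the edges) after sorting by mean.  Group comparisons use the
Mann-Whitney rank test (exact enumeration for pooled n <= 12, otherwise a
tie- and continuity-corrected normal approximation); association tests use
(partial) Pearson/Spearman correlations with Benjamini-Hochberg FDR
adjustment for report tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_LIMIT = 12
SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class NoiseRecord:
    gene_id: str
    mean: float
    variance: float
    cov: float = math.nan
    noise_differential: float = math.nan


def coefficient_of_variation(mean: float, variance: float) -> float:
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if variance < 0:
        raise ValueError(f"variance must be nonnegative, got {variance}")
    return math.sqrt(variance) / mean


def make_noise_records(
    gene_ids: Sequence[str],
    means: Sequence[float],
    variances: Sequence[float] | None = None,
    covs: Sequence[float] | None = None,
) -> list[NoiseRecord]:
    """Build records from (mean, variance) or directly from a CoV column."""
    if covs is None:
        if variances is None:
            raise ValueError("provide variances or covs")
        covs = [coefficient_of_variation(m, v) for m, v in zip(means, variances)]
        vs = list(variances)
    else:
        vs = [(c * m) ** 2 for c, m in zip(covs, means)]
    return [
        NoiseRecord(gene_id=g, mean=float(m), variance=float(v), cov=float(c))
        for g, m, v, c in zip(gene_ids, means, vs, covs)
    ]


def noise_differential(
    records: Sequence[NoiseRecord], window: int = 51
) -> list[NoiseRecord]:
    """CoV minus the running-median CoV of similarly abundant genes.

    Genes are sorted by mean; each gene's expected CoV is the median CoV in a
    centered rank window of ``window`` genes (odd, truncated at the edges).
    Returns records in the input order with ``noise_differential`` filled in.
    """
    n = len(records)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not (3 <= window <= n):
        raise ValueError(f"need n >= window >= 3 (n={n}, window={window})")
    order = np.argsort([r.mean for r in records], kind="stable")
    covs_sorted = np.array([records[i].cov for i in order])
    half = window // 2
    nd_sorted = np.empty(n)
    for pos in range(n):
        lo, hi = max(0, pos - half), min(n, pos + half + 1)
        nd_sorted[pos] = covs_sorted[pos] - np.median(covs_sorted[lo:hi])
    out: list[NoiseRecord] = [None] * n  # type: ignore[list-item]
    for pos, i in enumerate(order):
        out[i] = replace(records[i], noise_differential=float(nd_sorted[pos]))
    return out


def quartile_noise_groups(
    records: Sequence[NoiseRecord],
    quartiles: tuple[float, float] = (0.25, 0.75),
) -> np.ndarray:
    """Label genes low_nd / mid / high_nd by noise-differential quartiles.

    Linear-interpolation quantiles; boundary ties go to ``mid``.
    """
    nd = np.array([r.noise_differential for r in records])
    if len(nd) < 4:
        raise ValueError("need at least 4 genes")
    q1, q3 = np.quantile(nd, quartiles)
    labels = np.full(len(nd), "mid", dtype=object)
    labels[nd < q1] = "low_nd"
    labels[nd > q3] = "high_nd"
    return labels


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """min(U_a, U_b) with midrank ties."""
    ua = 0.0
    for x in a:
        ua += np.sum(x > b) + 0.5 * np.sum(x == b)
    ub = len(a) * len(b) - ua
    return float(min(ua, ub))


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; U = min(U_a, U_b).

    Exact enumeration over all C(n, |a|) group assignments when the pooled
    size is at most 12; otherwise a normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(a, b)
    if n1 + n2 <= EXACT_LIMIT:
        return u, _exact_p(a, b, u)
    return u, _normal_p(a, b, u)


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    pooled = np.concatenate([a, b])
    n, n1 = len(pooled), len(a)
    idx = range(n)
    count = total = 0
    for comb in combinations(idx, n1):
        mask = np.zeros(n, bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if u <= u_obs + 1e-12:
            count += 1
    return count / total


def _normal_p(a: np.ndarray, b: np.ndarray, u: float) -> float:
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (u - mu + 0.5) / math.sqrt(sigma2)  # continuity correction; u <= mu
    return float(min(1.0, 2.0 * sps.norm.cdf(z)))


# ---------------------------------------------------------------------------
# Correlations and FDR
# ---------------------------------------------------------------------------

def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    method: str = "pearson",
) -> tuple[float, float]:
    """First-order partial correlation of x and y given z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); Spearman
    applies the same formula to midranks.  When the denominator is
    numerically zero (z collinear with x or y) the convention is r = 0.
    The p-value comes from a t statistic with n - 3 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if not (len(x) == len(y) == len(z)):
        raise ValueError("x, y, z must have equal lengths")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if method == "spearman":
        x, y, z = (sps.rankdata(v) for v in (x, y, z))
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom2 = (1 - rxz**2) * (1 - ryz**2)
    if denom2 < 1e-12:
        return 0.0, 1.0
    r = float((rxy - rxz * ryz) / math.sqrt(denom2))
    r = max(-1.0, min(1.0, r))
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1 - r**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def significance_stars(p: float, levels=SIGNIFICANCE_LEVELS) -> str:
    return "*" * sum(p <= lv for lv in levels)


def correlation_report(
    predictors: pd.DataFrame,
    response: Sequence[float],
    control: Sequence[float],
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-feature correlation and partial correlation (given the control)
    with the response, FDR-adjusted significance stars."""
    y = np.asarray(response, float)
    z = np.asarray(control, float)
    rows = []
    for col in predictors.columns:
        x = predictors[col].to_numpy(float)
        if x.std() == 0:
            rows.append((col, math.nan, 1.0, math.nan, 1.0))
            continue
        if method == "spearman":
            r, p = sps.spearmanr(x, y)
        else:
            r, p = sps.pearsonr(x, y)
        pr, pp = partial_correlation(x, y, z, method=method)
        rows.append((col, float(r), float(p), pr, pp))
    df = pd.DataFrame(
        rows, columns=["feature", "r", "p", "partial_r", "partial_p"]
    ).set_index("feature")
    df["p_adj"] = bh_fdr(df["p"].fillna(1.0))
    df["partial_p_adj"] = bh_fdr(df["partial_p"].fillna(1.0))
    df["stars"] = [significance_stars(p) for p in df["p_adj"]]
    df["partial_stars"] = [significance_stars(p) for p in df["partial_p_adj"]]
    return df


def noise_table(records: Sequence[NoiseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "mean": [r.mean for r in records],
            "variance": [r.variance for r in records],
            "cov": [r.cov for r in records],
            "noise_differential": [r.noise_differential for r in records],
        }
    ).set_index("gene_id")
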