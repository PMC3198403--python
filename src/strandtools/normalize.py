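"""Count normalization factors and a replicate-homogeneity diagnostic.

Four ways to estimate the relative sequencing depth d_j of technical
replicates: total read count, upper quartile (Q3) of the nonzero counts,
trimmed mean of M-values (TMM, the edgeR method with its published
defaults: 30% log-ratio trim, 5% intensity trim, precision weighting,
reference = the column whose upper quartile is closest to the mean), and
spike-in totals.  All factor vectors are rescaled to geometric mean 1.

The goodness-of-fit diagnostic asks whether, given the factors, the
replicate counts of each gene look like a multinomial split of its pooled
count: per gene the chi-square homogeneity statistic is computed against
expected counts d_j * Y_g. / sum(d); under pure technical (Poisson)
variation and correct factors the statistics follow chi-square(n-1), so a
QQ comparison of observed versus theoretical quantiles reveals which
normalization leaves the least unexplained between-replicate signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormFactors",
    "GofResult",
    "normalization_factors",
    "tmm_factors",
    "gof_statistics",
]

METHODS = ("total", "upper_quartile", "tmm", "spikein")


@dataclass
class NormFactors:
    """Per-replicate depth factors d_j for one method, geometric mean 1."""

    method: str
    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")


def _geomean_scale(x: np.ndarray) -> np.ndarray:
    return x / np.exp(np.mean(np.log(x)))


def _quantile_factor(counts: np.ndarray, lib_size: np.ndarray, p: float = 0.75
                     ) -> np.ndarray:
    """edgeR's calcFactorQuantile: per-column p-quantile of count/libsize."""
    scaled = counts / lib_size[None, :]
    return np.quantile(scaled, p, axis=0)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> float:
    """TMM factor of one column against the reference (edgeR algorithm)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    sel = (
        (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    )
    if not sel.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[sel] / v[sel]) / np.sum(1.0 / v[sel])
    else:
        f = np.mean(log_r[sel])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    lib_size: pd.Series | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """TMM normalization factors (relative to library size), geometric
    mean 1 — the same convention and algorithm as edgeR's
    ``calcNormFactors(method="TMM")``."""
    x = counts.to_numpy(dtype=float)
    if lib_size is None:
        n = x.sum(axis=0)
    else:
        n = lib_size.to_numpy(dtype=float)
    if np.any(n <= 0):
        raise ValueError("every column needs a positive library size")
    f75 = _quantile_factor(x, n)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    f = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref], n[j], n[ref], logratio_trim, sum_trim)
            for j in range(x.shape[1])
        ]
    )
    return pd.Series(_geomean_scale(f), index=counts.columns, name="tmm_factor")


def normalization_factors(
    counts: pd.DataFrame,
    method: str,
    spikein_ids: Sequence[str] | None = None,
) -> NormFactors:
    """Relative depth factors d_j for the chosen method, scaled to
    geometric mean 1.

    ``total``: column sums.  ``upper_quartile``: 75th percentile of each
    column's nonzero counts.  ``tmm``: library size times the TMM
    correction factor (effective library size).  ``spikein``: column sums
    over the spike-in rows only.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if counts.shape[1] < 2:
        raise ValueError("need at least two replicates")
    x = counts.to_numpy(dtype=float)
    col_sums = x.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValueError("a replicate column is all zero")

    if method == "total":
        d = col_sums
    elif method == "upper_quartile":
        d = np.array(
            [np.quantile(col[col > 0], 0.75) for col in x.T]
        )
        if np.any(d <= 0):
            raise ValueError("upper quartile of nonzero counts is zero")
    elif method == "tmm":
        d = col_sums * tmm_factors(counts).to_numpy()
    else:  # spikein
        if spikein_ids is None:
            raise ValueError("spikein method requires spikein_ids")
        missing = [s for s in spikein_ids if s not in counts.index]
        if missing:
            raise ValueError(f"spike-ins absent from the table: {missing[:5]}")
        d = counts.loc[list(spikein_ids)].to_numpy(dtype=float).sum(axis=0)
        if np.any(d == 0):
            raise ValueError("a replicate has zero spike-in counts")
    return NormFactors(
        method=method,
        factors=pd.Series(_geomean_scale(d), index=counts.columns, name=method),
    )


@dataclass
class GofResult:
    """Chi-square homogeneity statistics per gene plus QQ pairs."""

    statistics: pd.Series
    dof: int
    qq: pd.DataFrame  # columns: theoretical, observed


def gof_statistics(
    counts: pd.DataFrame,
    factors: NormFactors,
    n_qq: int = 200,
) -> GofResult:
    """Per-gene chi-square statistic of replicate counts against the
    factor-implied expectation, with chi-square(n-1) QQ pairs.

    Expected counts: ``Y_hat_gj = d_j * Y_g. / sum_k d_k``.  Genes with a
    pooled count of zero are skipped; the statistic is invariant under a
    global rescaling of the factors.
    """
    d = factors.factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(d)):
        raise ValueError("factors do not match the count-table columns")
    y = counts.to_numpy(dtype=float)
    pooled = y.sum(axis=1)
    keep = pooled > 0
    if not keep.any():
        raise ValueError("all genes have zero pooled counts")
    expected = pooled[keep, None] * (d / d.sum())[None, :]
    bad = (expected == 0) & (y[keep] > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.any(axis=1).sum())} gene(s) with zero expected but "
            "observed counts skipped",
            stacklevel=2,
        )
        ok = ~bad.any(axis=1)
    else:
        ok = np.ones(keep.sum(), dtype=bool)
    stat = np.sum((y[keep][ok] - expected[ok]) ** 2 / expected[ok], axis=1)
    idx = counts.index[keep][ok]
    statistics = pd.Series(stat, index=idx, name="gof")

    dof = counts.shape[1] - 1
    probs = (np.arange(1, n_qq + 1) - 0.5) / n_qq
    qq = pd.DataFrame(
        {
            "theoretical": stats.chi2.ppf(probs, dof),
            "observed": np.quantile(stat, probs),
        }
    )
    return GofResult(statistics=statistics, dof=dof, qq=qq)
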