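"""Empirical Bayes Poisson-Gamma test for significantly expressed units.

Model
-----
For unit g (a gene's sense counts, its antisense counts, or an intron)
with exonic length L_g, the replicate-pooled read count is modelled as

    Y_g ~ Poisson(L_g * lambda_g).

Under the null the unit is silent and lambda_g equals the background rate
lambda0 estimated from non-coding regions; under the alternative lambda_g
is drawn from a Gamma(a, b) prior (shape/rate, mean a/b), so the marginal
of Y_g under H1 is negative binomial:

    P(Y=y | H1) = Gamma(y+a) / (Gamma(a) y!) * (b/(b+L))^a * (L/(b+L))^y.

With prior null proportion pi0 the posterior odds of the null are

    B_g = pi0 * Poisson(y; L*lambda0) / ((1-pi0) * NB(y; L, a, b)),

and a unit is declared expressed when B_g < 1.  The posterior null
probability is p0 = B/(1+B) and the estimated FDR of a detected set is the
mean of p0 over that set.

All probability arithmetic is done in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "PriorEstimate",
    "DetectionSummary",
    "nb_log_marginal",
    "nb_marginal",
    "estimate_pi0",
    "fit_gamma_prior",
    "log_posterior_odds",
    "posterior_odds",
    "detect_expressed",
    "fdr_curve",
]


@dataclass
class PriorEstimate:
    """Mixture parameters of the detection model.

    ``pi0``: prior proportion of non-expressed units; ``shape``/``rate``:
    Gamma prior (a, b) on the expression rate of expressed units, prior
    mean ``shape/rate`` in reads/bp; ``lambda0``: background rate reads/bp.
    """

    pi0: float
    shape: float
    rate: float
    lambda0: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in [0, 1]")
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError("shape must be finite positive")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise ValueError("rate must be finite positive")

    @property
    def prior_mean(self) -> float:
        return self.shape / self.rate


@dataclass
class DetectionSummary:
    n_detected: int
    fdr: float | None
    curve: pd.DataFrame  # columns: threshold, n_detected, fdr


def nb_log_marginal(y, L, shape: float, rate: float) -> np.ndarray:
    """log of the H1 marginal: the Poisson-Gamma (negative binomial) mixture
    integrated over the Gamma(shape, rate) prior, with exposure L."""
    y = np.asarray(y)
    L = np.asarray(L, dtype=float)
    if np.any(y != np.floor(y)) or np.any(np.asarray(y) < 0):
        raise ValueError("counts must be non-negative integers")
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be positive")
    if np.any(L <= 0):
        raise ValueError("exposure L must be positive")
    y = y.astype(float)
    # NB with size=shape, success prob p = rate/(rate+L)
    return (
        special.gammaln(y + shape)
        - special.gammaln(shape)
        - special.gammaln(y + 1.0)
        + shape * (np.log(rate) - np.log(rate + L))
        + y * (np.log(L) - np.log(rate + L))
    )


def nb_marginal(y, L, shape: float, rate: float) -> np.ndarray:
    return np.exp(nb_log_marginal(y, L, shape, rate))


def estimate_pi0(counts, lengths, lambda0: float) -> float:
    """Prior null proportion: the fraction of units whose LNC (count/length)
    is below the background rate."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.size == 0:
        raise ValueError("no units")
    return float(np.mean(counts / lengths < lambda0))


def _moment_start(counts: np.ndarray, lengths: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (a, b) from the high-LNC units.

    Var(y/L) = E[lam]/L + Var(lam) per unit; subtracting the mean Poisson
    term leaves an estimate of the Gamma variance.
    """
    lam_hat = counts / lengths
    m = lam_hat.mean()
    v = lam_hat.var()
    v_excess = v - m * np.mean(1.0 / lengths)
    if not np.isfinite(v_excess) or v_excess <= 0:
        v_excess = max(m * m, 1e-12)  # fall back to shape ~ 1
    a0 = max(m * m / v_excess, 1e-3)
    b0 = max(a0 / max(m, 1e-12), 1e-9)
    return a0, b0


def fit_gamma_prior(
    counts,
    lengths,
    lambda0: float,
    pi0: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> PriorEstimate:
    """Fit (a, b) by maximising the negative-binomial marginal likelihood
    over the units with LNC >= lambda0 (the putatively expressed stratum).

    Optimisation runs in log-parameter space from a method-of-moments
    start; ``pi0`` defaults to :func:`estimate_pi0` on the full input.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if pi0 is None:
        pi0 = estimate_pi0(counts, lengths, lambda0)
    mask = counts / lengths >= lambda0
    y = counts[mask]
    L = lengths[mask]
    if y.size < 10:
        raise ValueError(
            f"only {y.size} units with LNC >= lambda0; cannot fit the prior"
        )
    if np.all(y == 0):
        raise ValueError("all high-LNC units have zero counts; degenerate fit")

    def nll(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        return -float(np.sum(nb_log_marginal(y, L, a, b)))

    a0, b0 = _moment_start(y, L)
    x0 = np.log([a0, b0])
    res = optimize.minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"fatol": tol, "xatol": 1e-8, "maxiter": max_iter * 4},
    )
    if not res.success:
        raise RuntimeError(
            f"gamma prior fit did not converge: {res.message}; "
            f"last iterate (a, b) = {tuple(np.exp(res.x))}"
        )
    if nll(res.x) > nll(x0) + 1e-9:
        raise RuntimeError("optimizer ended above its starting objective")
    a, b = np.exp(res.x)
    return PriorEstimate(pi0=float(pi0), shape=float(a), rate=float(b),
                         lambda0=float(lambda0))


def log_posterior_odds(y, L, prior: PriorEstimate) -> np.ndarray:
    """log B = log pi0 + logPois(y; L*lambda0) - log(1-pi0) - logNB(y; L, a, b).

    pi0 = 1 gives +inf (nothing can be detected); pi0 = 0 gives -inf with a
    warning (everything detected).
    """
    y = np.asarray(y, dtype=float)
    L = np.asarray(L, dtype=float)
    if prior.pi0 == 1.0:
        return np.full(np.broadcast(y, L).shape, np.inf)
    if prior.pi0 == 0.0:
        warnings.warn("pi0 = 0: posterior odds are 0 for every unit", stacklevel=2)
        return np.full(np.broadcast(y, L).shape, -np.inf)
    log_null = stats.poisson.logpmf(y, L * prior.lambda0)
    log_alt = nb_log_marginal(y, L, prior.shape, prior.rate)
    return (
        np.log(prior.pi0) - np.log1p(-prior.pi0) + log_null - log_alt
    )


def posterior_odds(y, L, prior: PriorEstimate) -> np.ndarray:
    return np.exp(log_posterior_odds(y, L, prior))


def fdr_curve(log_b: np.ndarray, n_points: int = 200) -> pd.DataFrame:
    """Estimated FDR of the detected set as a function of the B threshold.

    At threshold t the detected set is {B < t} and its estimated FDR is the
    mean posterior null probability p0 = B/(1+B) over the set.  Evaluated at
    the observed B values (subsampled to ``n_points``), which is where the
    curve changes.
    """
    order = np.argsort(log_b)
    sorted_log_b = np.asarray(log_b)[order]
    p0 = special.expit(sorted_log_b)
    cum_fdr = np.cumsum(p0) / np.arange(1, p0.size + 1)
    n_det = np.arange(1, p0.size + 1)
    # detected set at threshold just above each sorted B value
    thresholds = np.exp(sorted_log_b)
    df = pd.DataFrame(
        {"threshold": thresholds, "n_detected": n_det, "fdr": cum_fdr}
    )
    if len(df) > n_points:
        idx = np.unique(
            np.linspace(0, len(df) - 1, n_points).round().astype(int)
        )
        df = df.iloc[idx].reset_index(drop=True)
    return df


def detect_expressed(
    counts,
    lengths,
    prior: PriorEstimate,
    threshold: float = 1.0,
    ids=None,
) -> tuple[pd.DataFrame, DetectionSummary]:
    """Score every unit and call those with posterior odds B < threshold.

    Returns a per-unit DataFrame (Y, L, B, p0, detected) and a
    :class:`DetectionSummary` whose FDR is the mean p0 of the detected set
    (None when nothing is detected).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must align")
    log_b = log_posterior_odds(counts, lengths, prior)
    b = np.exp(log_b)
    p0 = special.expit(log_b)
    detected = b < threshold
    if ids is None:
        ids = pd.RangeIndex(counts.size)
    df = pd.DataFrame(
        {
            "Y": counts.astype(int),
            "L": lengths.astype(int),
            "B": b,
            "p0": p0,
            "detected": detected,
        },
        index=pd.Index(ids, name="unit"),
    )
    fdr = float(p0[detected].mean()) if detected.any() else None
    summary = DetectionSummary(
        n_detected=int(detected.sum()), fdr=fdr, curve=fdr_curve(log_b)
    )
    return df, summary


def run_detection(
    counts,
    lengths,
    lambda0: float,
    threshold: float = 1.0,
    ids=None,
) -> tuple[PriorEstimate, pd.DataFrame, DetectionSummary]:
    """Full detection pipeline on one count column (sense or antisense):
    estimate pi0, fit the Gamma prior on the high-LNC stratum, then score
    and call every unit.  The antisense test is this function applied to
    the antisense counts, with its own (pi0, a, b)."""
    pi0 = estimate_pi0(counts, lengths, lambda0)
    prior = fit_gamma_prior(counts, lengths, lambda0, pi0=pi0)
    df, summary = detect_expressed(counts, lengths, prior, threshold, ids=ids)
    return prior, df, summary
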