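"""Empirical Bayes test for intron retention.

Intronic read density is expected to scale with the host gene's
expression (pre-mRNA and retained isoforms are sampled in proportion to
transcription), so the retention rate is normalised by gene expression.
For intron i of gene g with length L_i and host-gene expression proxy E_g
(the sum of the gene's RPKM values across replicates), the pooled intron
count is modelled as

    X_gi ~ Poisson(L_i * lambda_gi),

with H0: lambda_gi = lambda0 (the NCR background) and, under H1,
lambda_gi = E_g * r_gi with retention rate r_gi ~ Gamma(a, b).  The H1
marginal is then negative binomial with exposure L_i * E_g, so the same
machinery as the gene test applies with that offset.  An additive variant
(H1 mean L_i * (E_g * r + lambda0), a Poisson (+) NB convolution) is
available behind a flag.

Introns of genes with E_g at or below the expression floor cannot be
normalised and are reported untestable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .detect import (
    DetectionSummary,
    PriorEstimate,
    detect_expressed,
    estimate_pi0,
    fdr_curve,
    fit_gamma_prior,
    nb_log_marginal,
)

__all__ = [
    "intron_log_posterior_odds",
    "intron_posterior_odds",
    "fit_intron_prior",
    "detect_retained_introns",
]


def _additive_log_marginal(
    x: np.ndarray, offset: np.ndarray, lam_bg: np.ndarray,
    shape: float, rate: float
) -> np.ndarray:
    """log P(x) for X = X_bg + X_sig, X_bg ~ Poisson(lam_bg),
    X_sig ~ NB(shape, rate/(rate+offset)), by exact finite convolution."""
    x = np.atleast_1d(x).astype(int)
    offset = np.broadcast_to(np.asarray(offset, dtype=float), x.shape)
    lam_bg = np.broadcast_to(np.asarray(lam_bg, dtype=float), x.shape)
    out = np.empty(x.shape, dtype=float)
    for i, xi in enumerate(x):
        k = np.arange(xi + 1)
        terms = stats.poisson.logpmf(k, lam_bg[i]) + nb_log_marginal(
            xi - k, offset[i], shape, rate
        )
        out[i] = special.logsumexp(terms)
    return out


def intron_log_posterior_odds(
    x,
    intron_length,
    gene_expression,
    prior: PriorEstimate,
    additive_background: bool = False,
) -> np.ndarray:
    """log posterior odds of no retention for each intron.

    H0: X ~ Poisson(L_i * lambda0).  H1 (default, multiplicative):
    X ~ NB with exposure L_i * E_g and Gamma(a, b) prior on the retention
    rate.  With ``additive_background=True`` the H1 mean carries the
    background additively: L_i * (E_g * r + lambda0).
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(intron_length, dtype=float)
    E = np.asarray(gene_expression, dtype=float)
    if np.any(E <= 0):
        raise ValueError("gene_expression must be positive for testable introns")
    if prior.pi0 == 1.0:
        return np.full(np.broadcast(x, L).shape, np.inf)
    if prior.pi0 == 0.0:
        return np.full(np.broadcast(x, L).shape, -np.inf)
    log_null = stats.poisson.logpmf(x, L * prior.lambda0)
    if additive_background:
        log_alt = _additive_log_marginal(
            x, L * E, L * prior.lambda0, prior.shape, prior.rate
        )
    else:
        log_alt = nb_log_marginal(x, L * E, prior.shape, prior.rate)
    return np.log(prior.pi0) - np.log1p(-prior.pi0) + log_null - log_alt


def intron_posterior_odds(
    x, intron_length, gene_expression, prior: PriorEstimate,
    additive_background: bool = False,
) -> np.ndarray:
    return np.exp(
        intron_log_posterior_odds(
            x, intron_length, gene_expression, prior, additive_background
        )
    )


def fit_intron_prior(
    x,
    intron_length,
    gene_expression,
    lambda0: float,
) -> PriorEstimate:
    """Estimate (pi0', a, b) for the retention test, mirroring the gene
    test: pi0' is the fraction of testable introns with LNC below lambda0,
    and (a, b) maximise the NB marginal likelihood over the high-LNC
    introns with exposure offsets L_i * E_g."""
    x = np.asarray(x, dtype=float)
    L = np.asarray(intron_length, dtype=float)
    E = np.asarray(gene_expression, dtype=float)
    pi0 = estimate_pi0(x, L, lambda0)
    mask = x / L >= lambda0
    prior = fit_gamma_prior(x[mask], (L * E)[mask], lambda0=0.0, pi0=pi0)
    return PriorEstimate(pi0=pi0, shape=prior.shape, rate=prior.rate,
                         lambda0=lambda0)


def detect_retained_introns(
    intron_table: pd.DataFrame,
    lambda0: float,
    threshold: float = 1.0,
    expression_floor: float = 0.0,
    additive_background: bool = False,
    prior: PriorEstimate | None = None,
) -> tuple[pd.DataFrame, DetectionSummary, PriorEstimate]:
    """Run the retention test over an intron table.

    ``intron_table`` must carry columns ``X`` (pooled intron count),
    ``L`` (intron length, bp) and ``E`` (host-gene expression, summed
    RPKM), indexed by intron id.  Introns with E <= ``expression_floor``
    are marked untestable and excluded from fitting and detection.

    Returns (per-intron results, detection summary, fitted prior).  The
    results frame has columns X, L, E, testable, B, p0, detected.
    """
    for col in ("X", "L", "E"):
        if col not in intron_table.columns:
            raise ValueError(f"intron table lacks required column {col!r}")
    x = intron_table["X"].to_numpy(dtype=float)
    L = intron_table["L"].to_numpy(dtype=float)
    E = intron_table["E"].to_numpy(dtype=float)
    testable = E > expression_floor
    if not testable.any():
        raise ValueError("no testable introns (all below the expression floor)")

    if prior is None:
        prior = fit_intron_prior(
            x[testable], L[testable], E[testable], lambda0
        )

    log_b = np.full(x.shape, np.nan)
    log_b[testable] = intron_log_posterior_odds(
        x[testable], L[testable], E[testable], prior, additive_background
    )
    b = np.exp(log_b)
    p0 = special.expit(log_b)
    detected = np.zeros(x.shape, dtype=bool)
    detected[testable] = b[testable] < threshold

    out = intron_table.copy()
    out["testable"] = testable
    out["B"] = b
    out["p0"] = p0
    out["detected"] = detected
    fdr = float(p0[detected].mean()) if detected.any() else None
    summary = DetectionSummary(
        n_detected=int(detected.sum()),
        fdr=fdr,
        curve=fdr_curve(log_b[testable]),
    )
    return out, summary, prior
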