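"""Information-theoretic methylation summaries per analysis region.

Given the exact pattern distribution g(x) of an analysis region with K CpG
sites (a :class:`~cpelmeth.model.ChainDistribution`), this module computes

* MML  mu = (1/K) sum_k Pr[X_k = 1], the mean methylation level;
* NME  h = -(1/K) sum_x g(x) log2 g(x), the normalized methylation entropy
  (0 for a single deterministic pattern, 1 when all 2^K patterns are
  equally likely);
* CMD  d12 = [D(g1||gbar) + D(g2||gbar)] / [H(g1,gbar) + H(g2,gbar)], the
  coefficient of methylation divergence between two conditions, where gbar
  is the distribution of the CPEL model whose potential is the average of
  the two conditions' potentials.

All divergences are in bits.  Sums over the 2^K patterns are evaluated in
O(K) through the Markov chain-rule decomposition, never by enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ChainDistribution, CpelParams, marginal_chain
from .regions import AnalysisRegion, EstimationRegion


@dataclass
class AnalysisSummary:
    """MML/NME of one analysis region under one fitted model."""

    analysis_region: AnalysisRegion
    mml: float
    nme: float
    chain: ChainDistribution


def mml(chain: ChainDistribution) -> float:
    """Mean methylation level: average per-site marginal Pr[X_k = 1]."""
    if chain is None or chain.K < 1:
        raise ValueError("mml requires a chain with K >= 1 sites")
    return float(chain.site_marginals()[:, 1].mean())


def nme(chain: ChainDistribution) -> float:
    """Normalized methylation entropy in [0, 1] (pattern entropy / K bits)."""
    if chain is None or chain.K < 1:
        raise ValueError("nme requires a chain with K >= 1 sites")
    return chain.entropy_bits() / chain.K


def average_potential_model(theta1: CpelParams, theta2: CpelParams) -> CpelParams:
    """Model whose potential is the average of two potentials.

    V is linear in (alpha, beta, gamma), so the averaged-potential model
    is exactly the componentwise parameter average.
    """
    return CpelParams(
        (theta1.alpha + theta2.alpha) / 2,
        (theta1.beta + theta2.beta) / 2,
        (theta1.gamma + theta2.gamma) / 2,
    )


def _expected_log2(g1: ChainDistribution, g2: ChainDistribution) -> float:
    """E_{g1}[log2 g2(X)] via the chain rule; -inf on support violation."""
    if g1.K != g2.K:
        raise ValueError("chains must have equal length")
    total = 0.0
    with np.errstate(divide="ignore"):
        log_init = np.log2(g2.init)
        mask = g1.init > 0
        if np.any(np.isneginf(log_init[mask])):
            return -np.inf
        total += float((g1.init[mask] * log_init[mask]).sum())
        pair = g1.pair_marginals()  # (K-1, 2, 2)
        for k in range(g1.K - 1):
            log_t = np.log2(g2.trans[k])
            m = pair[k] > 0
            if np.any(np.isneginf(log_t[m])):
                return -np.inf
            total += float((pair[k][m] * log_t[m]).sum())
    return total


def kl_divergence(g1: ChainDistribution, g2: ChainDistribution) -> float:
    """D(g1 || g2) in bits; +inf when g1 is not absolutely continuous wrt g2."""
    cross = _expected_log2(g1, g2)
    if np.isneginf(cross):
        return np.inf
    return max(0.0, -g1.entropy_bits() - cross)


def cross_entropy(g1: ChainDistribution, g2: ChainDistribution) -> float:
    """H(g1, g2) = -sum_x g1(x) log2 g2(x), in bits."""
    return -_expected_log2(g1, g2)


def cmd(
    theta1: CpelParams,
    theta2: CpelParams,
    region: EstimationRegion,
    analysis_region: AnalysisRegion,
) -> float:
    """Coefficient of methylation divergence between two fitted models.

    Returns NaN for analysis regions without CpG sites or with a
    degenerate zero denominator.  Symmetric in (theta1, theta2) and 0
    when the two distributions coincide.
    """
    g1 = marginal_chain(region, theta1, analysis_region)
    g2 = marginal_chain(region, theta2, analysis_region)
    if g1 is None or g2 is None:
        return float("nan")
    gbar = marginal_chain(region, average_potential_model(theta1, theta2), analysis_region)
    num = kl_divergence(g1, gbar) + kl_divergence(g2, gbar)
    den = cross_entropy(g1, gbar) + cross_entropy(g2, gbar)
    if den <= 0 or not np.isfinite(den):
        return float("nan")
    return num / den


def summarize_region(
    region: EstimationRegion, theta: CpelParams
) -> list[AnalysisSummary]:
    """MML/NME for every analysis region of a fitted estimation region.

    Analysis regions without CpG sites are omitted.
    """
    out = []
    for ar in region.analysis_regions:
        chain = marginal_chain(region, theta, ar)
        if chain is None:
            continue
        out.append(
            AnalysisSummary(analysis_region=ar, mml=mml(chain), nme=nme(chain), chain=chain)
        )
    return out
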