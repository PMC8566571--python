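"""Maximum-likelihood estimation of CPEL parameters from read emissions.

Each read is one molecule whose hidden methylation state follows the CPEL
model; the observed evidence y enters through per-CG-group emission
log-likelihoods q(y | x).  The observed-data likelihood of a read is

    p(y; theta) = sum_x q(y | x) p(x; theta)

with the sum restricted to group-consistent states, and is computed exactly
by a single transfer-matrix pass with the emission log-likelihoods folded
into the site potentials (uncovered groups contribute a factor of 1).

The fit maximizes the total observed-data log-likelihood by EM: the E-step
yields per-read posterior expected sufficient statistics (the gradient of
the emission-weighted log-partition), and the M-step solves the concave
subproblem max_theta [theta . S - R log Z(theta)] over the parameter box.

Two comparator estimators mirror the benchmark baselines: ``direct_ml_fit``
fits the model directly to hard methylation calls (delta emissions, no
noise model), and ``empirical_estimates`` tallies per-site frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .config import DEFAULT_PARAM_BOUND, DEFAULT_RIDGE, EM_MAX_ITER, EM_REL_TOL
from .emissions import BinaryCalls, Call, ReadEmission
from .model import (
    CpelParams,
    chain_log_partition,
    chain_log_partition_grad,
    chain_potentials,
)
from .regions import EstimationRegion

#: log emission factor for the state ruled out by a hard call
_DELTA_LL = -1.0e4


@dataclass
class FitResult:
    theta_hat: CpelParams
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    n_reads: int = 0


def _emission_offsets(
    region: EstimationRegion, reads: Sequence[ReadEmission]
) -> np.ndarray:
    """Per-read log emission factors, shape (R, G, 2); zeros where uncovered."""
    G = region.n_groups
    e = np.zeros((len(reads), G, 2))
    for r, read in enumerate(reads):
        for g, ll_m, ll_u in read.entries:
            if not 0 <= g < G:
                raise ValueError(
                    f"read {read.read_id} references group {g} outside region"
                )
            e[r, g, 0] = ll_u
            e[r, g, 1] = ll_m
    return e


def read_loglik(region: EstimationRegion, theta: CpelParams, read: ReadEmission) -> float:
    """log p(y; theta) = log sum over group-consistent x of q(y|x) p(x; theta)."""
    h, J, _, _ = chain_potentials(region, theta, group_consistent=True)
    e = _emission_offsets(region, [read])
    log_zy = chain_log_partition(h[None] + e, J)
    log_z = chain_log_partition(h, J)
    return float(log_zy[0] - log_z)


def e_step(
    region: EstimationRegion, theta: CpelParams, reads: Sequence[ReadEmission]
) -> tuple[float, np.ndarray]:
    """Total observed-data log-likelihood and summed posterior E[T(x) | y].

    The posterior over group states given emissions is again an Ising
    chain, so sum_r E[T | y_r] is the summed gradient of the
    emission-weighted log-partitions.
    """
    if not reads:
        raise ValueError("e_step requires at least one read")
    h, J, dh, dJ = chain_potentials(region, theta, group_consistent=True)
    e = _emission_offsets(region, reads)
    log_zy, grads = chain_log_partition_grad(h[None] + e, J, dh, dJ)
    log_z = chain_log_partition(h, J)
    total_ll = float(log_zy.sum() - len(reads) * log_z)
    return total_ll, grads.sum(axis=0)


def m_step(
    posterior_stats: np.ndarray,
    region: EstimationRegion,
    n_reads: int,
    bound: float = DEFAULT_PARAM_BOUND,
    theta0: CpelParams | None = None,
    ridge: float = 0.0,
) -> CpelParams:
    """Maximize theta . S - R log Z_restricted(theta) over the box.

    log Z is convex in theta (log-sum-exp of linear functions), so the
    objective is concave and any interior stationary point is the maximum.
    A non-zero ``ridge`` adds a -ridge * |theta|^2 penalty (a weak
    Gaussian prior) that pins down directions the data leave flat.
    """
    if not np.all(np.isfinite(posterior_stats)):
        raise ValueError("posterior statistics must be finite")
    stats = np.asarray(posterior_stats, dtype=float)

    def neg_obj(theta_arr: np.ndarray) -> tuple[float, np.ndarray]:
        h, J, dh, dJ = chain_potentials(
            region, CpelParams.from_array(theta_arr), group_consistent=True
        )
        log_z, grad = chain_log_partition_grad(h, J, dh, dJ)
        f = theta_arr @ stats - n_reads * float(log_z) - ridge * theta_arr @ theta_arr
        g = stats - n_reads * grad - 2 * ridge * theta_arr
        return -f, -g

    x0 = theta0.as_array() if theta0 is not None else np.zeros(3)
    res = minimize(
        neg_obj,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(-bound, bound)] * 3,
        options={"ftol": 1e-14, "gtol": 1e-9, "maxiter": 500},
    )
    return CpelParams.from_array(res.x)


def em_fit(
    region: EstimationRegion,
    reads: Sequence[ReadEmission],
    *,
    bound: float = DEFAULT_PARAM_BOUND,
    tol: float = EM_REL_TOL,
    max_iter: int = EM_MAX_ITER,
    ridge: float = DEFAULT_RIDGE,
) -> FitResult:
    """EM maximum-likelihood fit of (alpha, beta, gamma) from emissions.

    Starts from the maximum-entropy point theta = (0, 0, 0) and alternates
    exact E- and M-steps until the relative change of the observed-data
    log-likelihood drops below ``tol`` or ``max_iter`` is reached.  With a
    non-zero ``ridge`` the M-step is penalized (MAP estimation), which
    stabilizes directions the data leave flat.
    """
    theta = CpelParams(0.0, 0.0, 0.0)
    trace: list[float] = []
    converged = False
    for it in range(max_iter):
        ll, stats = e_step(region, theta, reads)
        trace.append(ll)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) <= tol * max(abs(prev), 1.0):
                converged = True
                break
        theta = m_step(stats, region, len(reads), bound=bound, theta0=theta, ridge=ridge)
    return FitResult(
        theta_hat=theta,
        loglik_trace=trace,
        n_iter=len(trace),
        converged=converged,
        n_reads=len(reads),
    )


def calls_to_delta_emissions(calls: Sequence[BinaryCalls]) -> list[ReadEmission]:
    """Hard calls as (near-)delta emissions; abstentions become flat."""
    out = []
    for c in calls:
        em = ReadEmission(read_id=c.read_id, region_id=c.region_id)
        for g, call in c.entries:
            if call is Call.METHYLATED:
                em.entries.append((g, 0.0, _DELTA_LL))
            elif call is Call.UNMETHYLATED:
                em.entries.append((g, _DELTA_LL, 0.0))
            else:
                em.entries.append((g, 0.0, 0.0))
        out.append(em)
    return out


def direct_ml_fit(
    region: EstimationRegion,
    calls: Sequence[BinaryCalls],
    *,
    bound: float = DEFAULT_PARAM_BOUND,
    tol: float = EM_REL_TOL,
    max_iter: int = EM_MAX_ITER,
    ridge: float = DEFAULT_RIDGE,
) -> FitResult:
    """Fit the CPEL model directly to hard methylation calls.

    Equivalent to ``em_fit`` with delta emissions at called groups and
    flat emissions at abstained ones; ignores the nanopore noise model.
    """
    if not any(
        call is not Call.ABSTAIN for c in calls for _, call in c.entries
    ):
        raise ValueError("direct_ml_fit requires at least one non-abstained call")
    return em_fit(
        region,
        calls_to_delta_emissions(calls),
        bound=bound,
        tol=tol,
        max_iter=max_iter,
        ridge=ridge,
    )


def empirical_estimates(
    region: EstimationRegion, calls: Sequence[BinaryCalls]
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical site means and adjacent-pair co-methylation frequencies.

    ``means[n]`` is the methylated fraction among non-abstained calls
    covering site n's CG-group; ``pairs[n]`` is the fraction of reads
    calling both site n's and site n+1's groups methylated, among reads
    with non-abstained calls on both.  Uncovered sites/pairs are NaN.
    """
    G = region.n_groups
    meth = np.zeros(G)
    tot = np.zeros(G)
    # per-read called group states for the pair tally
    read_states: list[dict[int, int]] = []
    for c in calls:
        states: dict[int, int] = {}
        for g, call in c.entries:
            if call is Call.ABSTAIN:
                continue
            s = 1 if call is Call.METHYLATED else 0
            states[g] = s
            meth[g] += s
            tot[g] += 1
        read_states.append(states)

    with np.errstate(invalid="ignore", divide="ignore"):
        group_means = np.where(tot > 0, meth / np.maximum(tot, 1), np.nan)
    site_group = np.repeat(np.arange(G), region.group_sizes())
    means = group_means[site_group]

    pairs = np.full(max(region.n_sites - 1, 0), np.nan)
    for n in range(region.n_sites - 1):
        g1, g2 = site_group[n], site_group[n + 1]
        both = 0
        covered = 0
        for states in read_states:
            if g1 in states and g2 in states:
                covered += 1
                if states[g1] == 1 and states[g2] == 1:
                    both += 1
        if covered:
            pairs[n] = both / covered
    return means, pairs
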