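"""The CPEL probability model of the hidden methylation state.

The methylation state of an estimation region with N CpG sites is a binary
vector x with x_n = 1 when site n is methylated.  In spin form
(x~_n = 2 x_n - 1) the model is a nearest-neighbor Ising chain

    p(x; alpha, beta, gamma) = exp(-V(x)) / Z,
    V(x) = -[ alpha * sum_n x~_n
              + beta * sum_n rho_n x~_n
              + gamma * sum_{n<N} x~_n x~_{n+1} ],

where rho_n is the local CpG density at site n.  alpha sets the global
methylation propensity, beta modulates it with density, and gamma is the
nearest-neighbor interaction (cooperativity) parameter.

All quantities are computed exactly by 2x2 transfer-matrix recursions in
log space.  Because V is linear in theta = (alpha, beta, gamma), the
gradient of log Z equals the expected sufficient statistics E[T] and its
Hessian equals Cov[T]; both are obtained by propagating first and second
derivatives alongside the forward recursion, which stays exact at any N.

The *group-consistent* restriction constrains the state to be constant
within each CG-group (nanopore callers score a CG-group with one shared
state, and within-group variability is taken as negligible).  The
restricted model is itself an Ising chain over group spins with fields
a_g = sum_{k in g} (alpha + beta rho_k) and a constant within-group
interaction offset gamma * (m_g - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .config import DEFAULT_PARAM_BOUND
from .regions import EstimationRegion, AnalysisRegion

#: spin value of state index 0 (unmethylated) and 1 (methylated)
SPIN = np.array([-1.0, 1.0])

_N_PARAMS = 3


@dataclass(frozen=True)
class CpelParams:
    """The (alpha, beta, gamma) triple of one estimation region's model."""

    alpha: float
    beta: float
    gamma: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    @staticmethod
    def from_array(theta: np.ndarray) -> "CpelParams":
        return CpelParams(float(theta[0]), float(theta[1]), float(theta[2]))

    def validate(self, bound: float = DEFAULT_PARAM_BOUND) -> None:
        if np.any(np.abs(self.as_array()) > bound):
            raise ValueError(f"parameters must lie in [-{bound}, {bound}]")


def suff_stats(x: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Sufficient statistics (s1, s2, s3) of a binary state vector."""
    x = np.asarray(x)
    if x.shape != rho.shape:
        raise ValueError("state and density vectors must have equal length")
    spins = 2.0 * x - 1.0
    s1 = spins.sum()
    s2 = (rho * spins).sum()
    s3 = (spins[:-1] * spins[1:]).sum() if len(x) > 1 else 0.0
    return np.array([s1, s2, s3])


def potential(x: np.ndarray, region: EstimationRegion, theta: CpelParams) -> float:
    """Potential energy V(x) = -theta . T(x); the model is exp(-V)/Z."""
    if len(x) != region.n_sites:
        raise ValueError("state length does not match region CpG count")
    return float(-theta.as_array() @ suff_stats(np.asarray(x, dtype=float), region.rho))


# ---------------------------------------------------------------------------
# log-potential construction
# ---------------------------------------------------------------------------

def chain_potentials(
    region: EstimationRegion, theta: CpelParams, group_consistent: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Log site/pair potentials (h, J) and their theta-derivatives (dh, dJ).

    Returns ``h`` of shape (G, 2), ``J`` of shape (G-1, 2, 2), ``dh`` of
    shape (G, 2, 3) and ``dJ`` of shape (G-1, 2, 2, 3), where G is the
    number of CpG sites (unrestricted) or CG-groups (group-consistent).
    """
    theta_arr = theta.as_array()
    alpha, beta, gamma = theta_arr
    if group_consistent:
        sizes = region.group_sizes().astype(float)
        rho_sums = np.array(
            [region.rho[g.first_site_idx : g.last_site_idx + 1].sum() for g in region.groups]
        )
        G = len(sizes)
        h = np.empty((G, 2))
        dh = np.zeros((G, 2, _N_PARAMS))
        fields = alpha * sizes + beta * rho_sums
        offsets = gamma * (sizes - 1.0)  # within-group pairs always aligned
        h[:, 0] = -fields + offsets
        h[:, 1] = fields + offsets
        dh[:, 0, 0] = -sizes
        dh[:, 1, 0] = sizes
        dh[:, 0, 1] = -rho_sums
        dh[:, 1, 1] = rho_sums
        dh[:, :, 2] = (sizes - 1.0)[:, None]
    else:
        G = region.n_sites
        fields = alpha + beta * region.rho
        h = fields[:, None] * SPIN[None, :]
        dh = np.zeros((G, 2, _N_PARAMS))
        dh[:, :, 0] = SPIN[None, :]
        dh[:, :, 1] = region.rho[:, None] * SPIN[None, :]
    pair_sign = SPIN[:, None] * SPIN[None, :]
    J = np.broadcast_to(gamma * pair_sign, (max(G - 1, 0), 2, 2)).copy()
    dJ = np.zeros((max(G - 1, 0), 2, 2, _N_PARAMS))
    dJ[..., 2] = pair_sign
    return h, J, dh, dJ


# ---------------------------------------------------------------------------
# transfer-matrix recursions (batched over arbitrary leading axes of h)
# ---------------------------------------------------------------------------

def chain_log_partition(h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """log Z of a two-state chain with log potentials h (..., G, 2), J (G-1, 2, 2)."""
    a = h[..., 0, :]
    for k in range(h.shape[-2] - 1):
        t = a[..., :, None] + J[k]
        a = logsumexp(t, axis=-2) + h[..., k + 1, :]
    return logsumexp(a, axis=-1)


def chain_log_partition_grad(
    h: np.ndarray, J: np.ndarray, dh: np.ndarray, dJ: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """log Z and its gradient wrt theta, by forward derivative propagation.

    ``h`` may carry leading batch axes (e.g. per-read emission offsets);
    ``dh``/``dJ`` are the shared theta-derivatives of the log potentials.
    """
    G = h.shape[-2]
    batch = h.shape[:-2]
    a = h[..., 0, :]
    da = np.broadcast_to(dh[0], batch + (2, _N_PARAMS)).copy()
    for k in range(G - 1):
        t = a[..., :, None] + J[k]  # (..., s, s')
        lse = logsumexp(t, axis=-2)
        w = np.exp(t - lse[..., None, :])  # weights over s, per s'
        dt = da[..., :, None, :] + dJ[k]  # (..., s, s', P)
        da = (w[..., None] * dt).sum(axis=-3) + dh[k + 1]
        a = lse + h[..., k + 1, :]
    logz = logsumexp(a, axis=-1)
    w = np.exp(a - logz[..., None])
    grad = (w[..., None] * da).sum(axis=-2)
    return logz, grad


def chain_log_partition_grad_hess(
    h: np.ndarray, J: np.ndarray, dh: np.ndarray, dJ: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """log Z, gradient and Hessian wrt theta (single chain, no batch axes).

    The gradient is E[T] and the Hessian is Cov[T] of the sufficient
    statistics; the Hessian is symmetric positive semi-definite.
    """
    G = h.shape[-2]
    a = h[0].copy()
    da = dh[0].copy()
    Ha = np.zeros((2, _N_PARAMS, _N_PARAMS))
    for k in range(G - 1):
        t = a[:, None] + J[k]
        lse = logsumexp(t, axis=0)
        w = np.exp(t - lse[None, :])  # (s, s')
        dt = da[:, None, :] + dJ[k]  # (s, s', P)
        mean_dt = (w[..., None] * dt).sum(axis=0)  # (s', P)
        # second-moment propagation: E_w[Ha + dt dt^T] - mean mean^T
        outer = dt[..., :, None] * dt[..., None, :]  # (s, s', P, P)
        second = (w[..., None, None] * (Ha[:, None] + outer)).sum(axis=0)
        Ha = second - mean_dt[..., :, None] * mean_dt[..., None, :]
        da = mean_dt + dh[k + 1]
        a = lse + h[k + 1]
    logz = float(logsumexp(a))
    w = np.exp(a - logz)
    grad = (w[:, None] * da).sum(axis=0)
    outer = da[:, :, None] * da[:, None, :]
    hess = (w[:, None, None] * (Ha + outer)).sum(axis=0) - grad[:, None] * grad[None, :]
    return logz, grad, (hess + hess.T) / 2


# ---------------------------------------------------------------------------
# exact chain-distribution representation
# ---------------------------------------------------------------------------

@dataclass
class ChainDistribution:
    """Inhomogeneous two-state Markov chain over K sites.

    ``init`` is the marginal distribution of the first site (index 0 =
    unmethylated, 1 = methylated); ``trans[k]`` is the row-stochastic
    conditional table P(x_{k+1} | x_k).
    """

    init: np.ndarray
    trans: np.ndarray  # (K-1, 2, 2)

    @property
    def K(self) -> int:
        return len(self.trans) + 1

    def validate(self, tol: float = 1e-12) -> None:
        if abs(self.init.sum() - 1.0) > tol:
            raise ValueError("initial distribution does not sum to 1")
        if len(self.trans) and np.any(np.abs(self.trans.sum(axis=-1) - 1.0) > tol):
            raise ValueError("transition rows do not sum to 1")

    def site_marginals(self) -> np.ndarray:
        """Per-site marginal distributions, shape (K, 2)."""
        out = np.empty((self.K, 2))
        out[0] = self.init
        for k in range(self.K - 1):
            out[k + 1] = out[k] @ self.trans[k]
        return out

    def pair_marginals(self) -> np.ndarray:
        """Joint distributions of adjacent sites, shape (K-1, 2, 2)."""
        p = self.site_marginals()[:-1]
        return p[:, :, None] * self.trans

    def pattern_log_prob(self, x: np.ndarray) -> float:
        """Log probability of one full methylation pattern."""
        x = np.asarray(x, dtype=int)
        with np.errstate(divide="ignore"):
            lp = np.log(self.init[x[0]])
            for k in range(self.K - 1):
                lp += np.log(self.trans[k, x[k], x[k + 1]])
        return float(lp)

    def enumerate_probs(self) -> np.ndarray:
        """Probabilities of all 2^K patterns (small K only), pattern index
        in binary order with site 0 as the most significant bit."""
        if self.K > 20:
            raise ValueError("enumeration limited to K <= 20")
        probs = self.init.copy()
        for k in range(self.K - 1):
            last = np.arange(probs.size) % 2
            probs = (probs[:, None] * self.trans[k][last]).reshape(-1)
        return probs

    def entropy_bits(self) -> float:
        """Shannon entropy of the pattern distribution, in bits (chain rule)."""
        def _ent(p: np.ndarray) -> float:
            p = p[p > 0]
            return float(-(p * np.log2(p)).sum())

        H = _ent(self.init)
        marg = self.site_marginals()
        for k in range(self.K - 1):
            for s in (0, 1):
                H += marg[k, s] * _ent(self.trans[k, s])
        return H

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw n patterns, shape (n, K)."""
        out = np.empty((n, self.K), dtype=int)
        out[:, 0] = rng.random(n) < self.init[1]
        for k in range(self.K - 1):
            p1 = self.trans[k, out[:, k], 1]
            out[:, k + 1] = rng.random(n) < p1
        return out


def chain_from_potentials(h: np.ndarray, J: np.ndarray) -> ChainDistribution:
    """Exact chain representation of p(x) propto exp(sum h + sum J)."""
    G = h.shape[0]
    b = np.zeros((G, 2))
    for k in range(G - 2, -1, -1):
        b[k] = logsumexp(J[k] + (h[k + 1] + b[k + 1])[None, :], axis=1)
    a0 = h[0] + b[0]
    init = np.exp(a0 - logsumexp(a0))
    trans = np.empty((max(G - 1, 0), 2, 2))
    for k in range(G - 1):
        logt = J[k] + (h[k + 1] + b[k + 1])[None, :] - b[k][:, None]
        trans[k] = np.exp(logt)
        trans[k] /= trans[k].sum(axis=1, keepdims=True)
    return ChainDistribution(init=init, trans=trans)


# ---------------------------------------------------------------------------
# public model operations
# ---------------------------------------------------------------------------

def log_partition(
    region: EstimationRegion, theta: CpelParams, group_consistent: bool = False
) -> float:
    """log Z = log sum_x exp(-V(x)), over all states or the group-consistent
    subset."""
    h, J, _, _ = chain_potentials(region, theta, group_consistent)
    return float(chain_log_partition(h, J))


def full_chain(
    region: EstimationRegion, theta: CpelParams, group_consistent: bool = False
) -> ChainDistribution:
    """Exact Markov-chain representation of p(x; theta) over the region."""
    h, J, _, _ = chain_potentials(region, theta, group_consistent)
    return chain_from_potentials(h, J)


def site_means(
    region: EstimationRegion, theta: CpelParams, group_consistent: bool = False
) -> np.ndarray:
    """Exact marginal methylation probabilities E[X_n] per CpG site.

    Under the group-consistent restriction, the per-group marginal is
    broadcast to all member sites.
    """
    chain = full_chain(region, theta, group_consistent)
    marg = chain.site_marginals()[:, 1]
    if group_consistent:
        return np.repeat(marg, region.group_sizes())
    return marg


def pair_correlations(
    region: EstimationRegion, theta: CpelParams, group_consistent: bool = False
) -> np.ndarray:
    """Exact joint probabilities E[X_n X_{n+1}] = Pr[X_n = X_{n+1} = 1]."""
    if region.n_sites < 2:
        return np.empty(0)
    chain = full_chain(region, theta, group_consistent)
    joint11 = chain.pair_marginals()[:, 1, 1]
    if not group_consistent:
        return joint11
    # expand group-level chain to site pairs: within-group pairs share the
    # group's marginal; boundary pairs use the adjacent-group joint
    marg1 = chain.site_marginals()[:, 1]
    sizes = region.group_sizes()
    out = np.empty(region.n_sites - 1)
    i = 0
    for g, m in enumerate(sizes):
        out[i : i + m - 1] = marg1[g]
        i += m - 1
        if g < len(sizes) - 1:
            out[i] = joint11[g]
            i += 1
    return out


def expected_suff_stats(
    region: EstimationRegion, theta: CpelParams, group_consistent: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """E[T] and Cov[T] of the sufficient statistics (s1, s2, s3).

    Computed as the exact gradient and Hessian of log Z via derivative
    propagation through the transfer recursion.
    """
    h, J, dh, dJ = chain_potentials(region, theta, group_consistent)
    _, grad, hess = chain_log_partition_grad_hess(h, J, dh, dJ)
    return grad, hess


def sample_state(
    region: EstimationRegion,
    theta: CpelParams,
    group_consistent: bool = False,
    rng: np.random.Generator | None = None,
    n: int = 1,
) -> np.ndarray:
    """Exact draws from p(x; theta), shape (n, N) over CpG sites.

    Group-consistent draws are constant within each CG-group.
    """
    if rng is None:
        rng = np.random.default_rng()
    chain = full_chain(region, theta, group_consistent)
    draws = chain.sample(rng, n)
    if group_consistent:
        draws = np.repeat(draws, region.group_sizes(), axis=1)
    return draws


def marginal_chain(
    region: EstimationRegion,
    theta: CpelParams,
    analysis_region: AnalysisRegion,
) -> ChainDistribution | None:
    """Exact marginal of p(x; theta) over an analysis region's K CpG sites.

    Because the model is a nearest-neighbor chain, the marginal over a
    contiguous block of sites is again a Markov chain: the flanking sites
    are absorbed into the boundary messages, leaving the block's initial
    marginal and unchanged interior conditionals.  Returns ``None`` for an
    analysis region without CpG sites.
    """
    lo, hi = analysis_region.cpg_idx_range
    if hi <= lo:
        return None
    chain = full_chain(region, theta, group_consistent=False)
    init = chain.site_marginals()[lo]
    trans = chain.trans[lo : hi - 1]
    return ChainDistribution(init=init, trans=trans)
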