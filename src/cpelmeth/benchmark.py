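"""Benchmark metrics for the caller and the estimators on simulated data.

Two layers are covered.  The *caller* layer scores hard methylation calls
against the simulated hidden states: ROC/PR tables over an LLR-threshold
sweep, the single-site call error rate, and the co-occurrence error rate
(the joint both-methylated / both-unmethylated / mixed class of adjacent
CpG pairs).  The *estimator* layer scores fitted CPEL models against the
generating ones: cosine similarity of the parameter vectors and absolute
errors of the model-predicted site means, pair correlations, MML and NME.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .emissions import Call, ReadEmission, binarize_calls
from .estimation import direct_ml_fit, em_fit, empirical_estimates
from .model import CpelParams, pair_correlations, site_means
from .regions import EstimationRegion, qualify_region
from .simulate import sample_truth_params, simulate_region_dataset, synthetic_chromosome
from .summaries import mml, nme
from .model import marginal_chain


def cosine_similarity(theta_hat: CpelParams, theta_star: CpelParams) -> float:
    """Cosine of the angle between two parameter triples, in [-1, 1].

    Undefined (NaN) when either vector is zero.
    """
    a, b = theta_hat.as_array(), theta_star.as_array()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(a @ b / (na * nb))


def caller_benchmark(
    region: EstimationRegion,
    emissions: list[ReadEmission],
    truth: dict[str, np.ndarray],
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score hard calls against true group states over a threshold sweep.

    Returns one row per threshold with per-CpG-site counts (group calls
    weighted by group size): TPR/FPR/precision among non-abstained calls,
    the site error rate, the co-occurrence error rate over adjacent CpG
    pairs with calls on both sites, and the fraction of sites called.
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 10.5, 0.5)
    sizes = region.group_sizes()
    site_group = np.repeat(np.arange(region.n_groups), sizes)
    rows = []
    for thr in thresholds:
        calls = binarize_calls(emissions, float(thr))
        tp = fp = tn = fn = 0
        n_called_sites = 0
        n_covered_sites = 0
        pair_err = 0
        pair_tot = 0
        for c in calls:
            true_states = truth[c.read_id]
            called: dict[int, int] = {}
            for g, call in c.entries:
                n_covered_sites += sizes[g]
                if call is Call.ABSTAIN:
                    continue
                s = 1 if call is Call.METHYLATED else 0
                called[g] = s
                n_called_sites += sizes[g]
                t = true_states[g]
                m = int(sizes[g])
                if s == 1 and t == 1:
                    tp += m
                elif s == 1 and t == 0:
                    fp += m
                elif s == 0 and t == 0:
                    tn += m
                else:
                    fn += m
            # co-occurrence over adjacent CpG site pairs called on both sides
            for n in range(region.n_sites - 1):
                g1, g2 = site_group[n], site_group[n + 1]
                if g1 in called and g2 in called:
                    pair_tot += 1
                    called_class = called[g1] + called[g2]  # 0, 1(mixed), 2
                    true_class = int(true_states[g1]) + int(true_states[g2])
                    if called_class != true_class:
                        pair_err += 1
        n_calls = tp + fp + tn + fn
        rows.append(
            {
                "threshold": float(thr),
                "tpr": tp / (tp + fn) if tp + fn else np.nan,
                "fpr": fp / (fp + tn) if fp + tn else np.nan,
                "precision": tp / (tp + fp) if tp + fp else np.nan,
                "error_rate": (fp + fn) / n_calls if n_calls else np.nan,
                "coocc_error_rate": pair_err / pair_tot if pair_tot else np.nan,
                "frac_called": n_called_sites / n_covered_sites if n_covered_sites else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EstimatorMetrics:
    """Pooled per-site/per-pair/per-region error tables for one estimator."""

    abs_err_means: list[float] = field(default_factory=list)
    abs_err_pairs: list[float] = field(default_factory=list)
    abs_err_mml: list[float] = field(default_factory=list)
    abs_err_nme: list[float] = field(default_factory=list)
    cosine: list[float] = field(default_factory=list)


def _model_predictions(region: EstimationRegion, theta: CpelParams):
    means = site_means(region, theta, group_consistent=True)
    pairs = pair_correlations(region, theta, group_consistent=True)
    mmls, nmes = [], []
    for ar in region.analysis_regions:
        chain = marginal_chain(region, theta, ar)
        if chain is None:
            continue
        mmls.append(mml(chain))
        nmes.append(nme(chain))
    return means, pairs, np.array(mmls), np.array(nmes)


def score_fit(
    metrics: EstimatorMetrics,
    region: EstimationRegion,
    theta_true: CpelParams,
    theta_hat: CpelParams | None = None,
    empirical: tuple[np.ndarray, np.ndarray] | None = None,
) -> None:
    """Accumulate absolute errors of one fitted (or empirical) estimate."""
    true_means, true_pairs, true_mml, true_nme = _model_predictions(region, theta_true)
    if theta_hat is not None:
        est_means, est_pairs, est_mml, est_nme = _model_predictions(region, theta_hat)
        metrics.abs_err_mml.extend(np.abs(est_mml - true_mml))
        metrics.abs_err_nme.extend(np.abs(est_nme - true_nme))
        metrics.cosine.append(cosine_similarity(theta_hat, theta_true))
    else:
        est_means, est_pairs = empirical
    mask = np.isfinite(est_means)
    metrics.abs_err_means.extend(np.abs(est_means - true_means)[mask])
    if len(true_pairs):
        mask = np.isfinite(est_pairs)
        metrics.abs_err_pairs.extend(np.abs(est_pairs - true_pairs)[mask])


def run_estimation_benchmark(
    n_regions: int = 50,
    config: SimConfig | None = None,
    seed: int = 0,
    region_size: int = 3000,
    methods: tuple[str, ...] = ("em", "direct", "empirical"),
) -> dict[str, EstimatorMetrics]:
    """Simulate regions, fit with each estimator, pool the error metrics.

    Regions failing qualification (>= 10 CpGs, target average coverage,
    calls on >= 2/3 of CG-groups) are re-simulated so that exactly
    ``n_regions`` qualified regions are scored.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(seed)
    out = {m: EstimatorMetrics() for m in methods}
    scored = 0
    attempts = 0
    while scored < n_regions and attempts < 4 * n_regions:
        attempts += 1
        _, regions = synthetic_chromosome(1, region_size, rng)
        region = regions[0]
        theta_star = sample_truth_params(1, config, rng)[0]
        reads, _ = simulate_region_dataset(region, theta_star, config, rng)
        if not reads or not qualify_region(
            region, reads, min_group_cov=config.target_coverage / 2
        ):
            continue
        calls = binarize_calls(reads, 0.0)
        if "em" in methods:
            fit = em_fit(region, reads)
            score_fit(out["em"], region, theta_star, theta_hat=fit.theta_hat)
        if "direct" in methods:
            fit = direct_ml_fit(region, calls)
            score_fit(out["direct"], region, theta_star, theta_hat=fit.theta_hat)
        if "empirical" in methods:
            est = empirical_estimates(region, calls)
            score_fit(out["empirical"], region, theta_star, empirical=est)
        scored += 1
    return out


def metrics_summary(metrics: dict[str, EstimatorMetrics]) -> pd.DataFrame:
    """Median absolute errors and median cosine similarity per estimator."""
    rows = []
    for name, m in metrics.items():
        rows.append(
            {
                "method": name,
                "median_abs_err_means": float(np.median(m.abs_err_means)),
                "median_abs_err_pairs": float(np.median(m.abs_err_pairs)),
                "median_abs_err_mml": float(np.median(m.abs_err_mml)) if m.abs_err_mml else np.nan,
                "median_abs_err_nme": float(np.median(m.abs_err_nme)) if m.abs_err_nme else np.nan,
                "median_cosine": float(np.median(m.cosine)) if m.cosine else np.nan,
                "n_sites": len(m.abs_err_means),
                "n_pairs": len(m.abs_err_pairs),
            }
        )
    return pd.DataFrame(rows).set_index("method")
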