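"""EM estimation: read likelihoods, E/M steps, fits, comparator estimators."""

import itertools

import numpy as np
import pytest

from cpelmeth.config import SimConfig
from cpelmeth.emissions import BinaryCalls, Call, ReadEmission, binarize_calls
from cpelmeth.estimation import (
    direct_ml_fit,
    e_step,
    em_fit,
    empirical_estimates,
    m_step,
    read_loglik,
)
from cpelmeth.model import CpelParams, expected_suff_stats, log_partition
from cpelmeth.simulate import simulate_region_dataset
from cpelmeth.benchmark import cosine_similarity

from .conftest import make_region


def brute_force_read_loglik(region, theta, read):
    """Independent oracle: sum q(y|x) p(x) over all group-state vectors."""
    sizes = [g.n_sites for g in region.groups]
    ll_by_group = {g: (m, u) for g, m, u in read.entries}
    total = []
    logz = log_partition(region, theta, group_consistent=True)
    for xg in itertools.product([0, 1], repeat=len(sizes)):
        x = np.repeat(np.array(xg, dtype=float), sizes)
        spins = 2 * x - 1
        s1, s2 = spins.sum(), spins @ region.rho
        s3 = (spins[:-1] * spins[1:]).sum() if len(x) > 1 else 0.0
        lp = theta.alpha * s1 + theta.beta * s2 + theta.gamma * s3 - logz
        emis = sum(ll_by_group[g][1 - xi] if xi == 0 else ll_by_group[g][0]
                   for g, xi in enumerate(xg) if g in ll_by_group)
        total.append(lp + emis)
    m = max(total)
    return m + np.log(np.sum(np.exp(np.array(total) - m)))


@pytest.fixture
def region():
    return make_region([19, 26, 278, 304, 447, 489, 565, 570], chrom_length=700)


def random_read(region, rng, read_id="r", coverage_prob=1.0):
    read = ReadEmission(read_id, region.region_id)
    for g in range(region.n_groups):
        if rng.random() < coverage_prob:
            read.entries.append((g, float(rng.normal(-3, 1)), float(rng.normal(-3, 1))))
    return read


class TestReadLoglik:
    def test_uninformative_emissions_factor_out(self, region, theta):
        c = -1.7
        read = ReadEmission("r", region.region_id, [(g, c, c) for g in range(region.n_groups)])
        assert read_loglik(region, theta, read) == pytest.approx(
            c * region.n_groups, abs=1e-10
        )

    def test_enumeration_oracle(self, region, rng, theta):
        for _ in range(5):
            read = random_read(region, rng, coverage_prob=0.7)
            assert read_loglik(region, theta, read) == pytest.approx(
                brute_force_read_loglik(region, theta, read), abs=1e-10
            )

    def test_uninformative_entry_equals_uncovered(self, region, rng, theta):
        read = random_read(region, rng, coverage_prob=0.6)
        uncovered = [g for g in range(region.n_groups) if g not in dict.fromkeys(
            e[0] for e in read.entries)]
        padded = ReadEmission(read.read_id, read.region_id,
                              read.entries + [(g, 0.0, 0.0) for g in uncovered])
        # a flat emission contributes the same factor to every state, so it
        # is equivalent to leaving the group uncovered (marginalized)
        assert read_loglik(region, theta, padded) == pytest.approx(
            read_loglik(region, theta, read), abs=1e-10
        )

    def test_unknown_group_rejected(self, region, theta):
        read = ReadEmission("r", region.region_id, [(99, -1.0, -1.0)])
        with pytest.raises(ValueError):
            read_loglik(region, theta, read)


class TestEStep:
    def test_uninformative_emissions_give_prior_stats(self, region, theta):
        reads = [
            ReadEmission(f"r{i}", region.region_id, [(g, -2.0, -2.0) for g in range(region.n_groups)])
            for i in range(4)
        ]
        _, stats = e_step(region, theta, reads)
        prior, _ = expected_suff_stats(region, theta, group_consistent=True)
        np.testing.assert_allclose(stats, 4 * prior, atol=1e-10)

    def test_near_delta_emissions_pin_the_pattern(self, region, theta):
        called = np.array([1, 0, 1, 1, 0, 0])  # one state per CG-group
        read = ReadEmission(
            "r",
            region.region_id,
            [(g, 0.0 if s else -50.0, -50.0 if s else 0.0) for g, s in enumerate(called)],
        )
        _, stats = e_step(region, theta, [read])
        x = np.repeat(called.astype(float), [g.n_sites for g in region.groups])
        spins = 2 * x - 1
        expected = np.array(
            [spins.sum(), spins @ region.rho, (spins[:-1] * spins[1:]).sum()]
        )
        np.testing.assert_allclose(stats, expected, atol=1e-8)

    def test_enumeration_oracle(self, region, rng, theta):
        reads = [random_read(region, rng, f"r{i}", 0.8) for i in range(3)]
        total_ll, stats = e_step(region, theta, reads)
        # oracle: weighted stats over enumerated group states per read
        sizes = [g.n_sites for g in region.groups]
        exp_stats = np.zeros(3)
        exp_ll = 0.0
        logz = log_partition(region, theta, group_consistent=True)
        for read in reads:
            ll_by_group = {g: (m, u) for g, m, u in read.entries}
            logps, stats_list = [], []
            for xg in itertools.product([0, 1], repeat=len(sizes)):
                x = np.repeat(np.array(xg, dtype=float), sizes)
                spins = 2 * x - 1
                t = np.array(
                    [spins.sum(), spins @ region.rho, (spins[:-1] * spins[1:]).sum()]
                )
                emis = sum(ll_by_group[g][0] if xi else ll_by_group[g][1]
                           for g, xi in enumerate(xg) if g in ll_by_group)
                logps.append(t @ [theta.alpha, theta.beta, theta.gamma] - logz + emis)
                stats_list.append(t)
            logps = np.array(logps)
            m = logps.max()
            lse = m + np.log(np.exp(logps - m).sum())
            w = np.exp(logps - lse)
            exp_stats += w @ np.array(stats_list)
            exp_ll += lse
        assert total_ll == pytest.approx(exp_ll, abs=1e-9)
        np.testing.assert_allclose(stats, exp_stats, atol=1e-9)


class TestMStep:
    def test_self_consistency_fixed_point(self, region):
        theta_star = CpelParams(0.7, -0.4, 0.5)
        prior, _ = expected_suff_stats(region, theta_star, group_consistent=True)
        n_reads = 20
        theta_hat = m_step(n_reads * prior, region, n_reads)
        np.testing.assert_allclose(
            theta_hat.as_array(), theta_star.as_array(), atol=1e-5
        )

    def test_saturated_stats_hit_bound(self, region):
        x = np.ones(region.n_sites)
        spins = 2 * x - 1
        stats = np.array([spins.sum(), spins @ region.rho, (spins[:-1] * spins[1:]).sum()])
        theta_hat = m_step(10 * stats, region, 10)
        assert theta_hat.alpha == pytest.approx(10.0)

    def test_kkt_stationarity(self, region, rng):
        theta0 = CpelParams(*rng.uniform(-1, 1, 3))
        prior, _ = expected_suff_stats(region, theta0, group_consistent=True)
        stats = 15 * prior + rng.normal(0, 0.5, 3)
        theta_hat = m_step(stats, region, 15)
        et, _ = expected_suff_stats(region, theta_hat, group_consistent=True)
        grad = stats - 15 * et
        on_bound = np.abs(np.abs(theta_hat.as_array()) - 10.0) < 1e-9
        assert np.all((np.abs(grad) < 1e-4) | on_bound)

    def test_non_finite_stats_rejected(self, region):
        with pytest.raises(ValueError):
            m_step(np.array([np.nan, 0, 0]), region, 1)


class TestEmFit:
    def test_loglik_trace_monotone_pure_ml(self, region, rng, theta):
        reads, _ = simulate_region_dataset(
            region, theta, SimConfig(noise_sd=3.0, target_coverage=8.0), rng
        )
        fit = em_fit(region, reads, ridge=0.0)
        assert np.all(np.diff(fit.loglik_trace) > -1e-8)

    def test_loglik_trace_monotone_default_ridge(self, region, rng, theta):
        reads, _ = simulate_region_dataset(
            region, theta, SimConfig(noise_sd=3.0, target_coverage=8.0), rng
        )
        fit = em_fit(region, reads)
        assert np.all(np.diff(fit.loglik_trace) > -1e-8)

    def test_uninformative_single_read_converges_immediately(self, region):
        read = ReadEmission("r", region.region_id, [(g, -1.0, -1.0) for g in range(region.n_groups)])
        fit = em_fit(region, [read])
        assert fit.converged and fit.n_iter <= 3
        assert np.allclose(np.diff(fit.loglik_trace), 0.0, atol=1e-9)

    def test_near_delta_emissions_match_direct_fit(self, region, rng):
        theta = CpelParams(0.8, 0.0, 0.5)
        cfg = SimConfig(noise_sd=1e-6, target_coverage=15.0)
        reads, _ = simulate_region_dataset(region, theta, cfg, rng)
        em = em_fit(region, reads)
        direct = direct_ml_fit(region, binarize_calls(reads, 0.0))
        np.testing.assert_allclose(
            em.theta_hat.as_array(), direct.theta_hat.as_array(), atol=1e-4
        )

    def test_parameter_recovery_cosine(self):
        """Replicated recovery at 25x coverage, sd = 3 nanopore noise."""
        from cpelmeth.simulate import synthetic_chromosome

        theta_star = CpelParams(0.5, -0.3, 0.4)
        cfg = SimConfig(noise_sd=3.0, target_coverage=25.0)
        cos = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            _, regions = synthetic_chromosome(1, 3000, rng)
            reads, _ = simulate_region_dataset(regions[0], theta_star, cfg, rng)
            fit = em_fit(regions[0], reads)
            cos.append(cosine_similarity(fit.theta_hat, theta_star))
        assert np.mean(np.array(cos) > 0.9) >= 0.5


class TestDirectMlFit:
    def test_all_methylated_hits_bound(self, region):
        calls = [
            BinaryCalls(f"r{i}", region.region_id,
                        [(g, Call.METHYLATED) for g in range(region.n_groups)])
            for i in range(10)
        ]
        fit = direct_ml_fit(region, calls, ridge=0.0)
        assert fit.theta_hat.alpha == pytest.approx(10.0, abs=1e-6)

    def test_all_abstained_rejected(self, region):
        calls = [BinaryCalls("r", region.region_id, [(0, Call.ABSTAIN)])]
        with pytest.raises(ValueError):
            direct_ml_fit(region, calls)

    def test_noiseless_recovery(self):
        from cpelmeth.simulate import synthetic_chromosome

        theta_star = CpelParams(1.0, -0.3, 0.5)
        cfg = SimConfig(noise_sd=1e-6, target_coverage=50.0)
        cos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            _, regions = synthetic_chromosome(1, 3000, rng)
            reads, _ = simulate_region_dataset(regions[0], theta_star, cfg, rng)
            fit = direct_ml_fit(regions[0], binarize_calls(reads, 0.0))
            cos.append(cosine_similarity(fit.theta_hat, theta_star))
        assert np.median(cos) > 0.95


class TestEmpiricalEstimates:
    def test_all_methylated_mean_one(self, region):
        calls = [
            BinaryCalls("r", region.region_id,
                        [(g, Call.METHYLATED) for g in range(region.n_groups)])
        ]
        means, _ = empirical_estimates(region, calls)
        np.testing.assert_allclose(means, 1.0)

    def test_uncovered_site_missing(self, region):
        calls = [BinaryCalls("r", region.region_id, [(0, Call.METHYLATED)])]
        means, pairs = empirical_estimates(region, calls)
        assert np.isfinite(means[0]) and np.isnan(means[-1])

    def test_hand_tallied_fractions(self):
        region = make_region([10, 40, 70], chrom_length=200)  # 3 singleton groups
        M, U, A = Call.METHYLATED, Call.UNMETHYLATED, Call.ABSTAIN
        patterns = [
            [(0, M), (1, M), (2, U)],
            [(0, M), (1, U), (2, U)],
            [(0, U), (1, M), (2, M)],
            [(0, M), (1, A), (2, M)],
            [(1, M), (2, M)],
            [(0, U), (1, U)],
        ]
        calls = [BinaryCalls(f"r{i}", region.region_id, p) for i, p in enumerate(patterns)]
        means, pairs = empirical_estimates(region, calls)
        np.testing.assert_allclose(means, [3 / 5, 3 / 5, 3 / 5])
        # pair (0,1): reads 0,1,2,5 cover both; both methylated only in read 0
        # pair (1,2): reads 0,1,2,4 cover both; both methylated in reads 2,4
        np.testing.assert_allclose(pairs, [1 / 4, 2 / 4])
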