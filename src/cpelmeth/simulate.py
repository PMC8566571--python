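"""Synthetic nanopore methylation data under known CPEL ground truth.

The generator emulates the benchmarking scheme end to end: CPEL parameters
drawn from fixed priors per estimation region, per-read hidden states drawn
from the group-consistent model (one molecule per read), per-CG-group
Gaussian current summaries at noise sd in {2, 2.5, 3, 3.5}, read spans at
target coverages on the 5x-25x grid, and the iterative random-transfer
subsampling procedure used to reach a desired average per-CpG coverage.

Sequences are synthesized with explicitly placed CG dinucleotides (20-60
per 3-kb region by default, arranged as one dense CpG-island-like cluster
plus scattered background sites) so that CpG counts, spacings and local
densities are controlled rather than inherited from base composition;
accidental CG formation in the background is removed.
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig
from .emissions import ReadEmission, gaussian_group_loglik
from .model import CpelParams, sample_state
from .regions import EstimationRegion, partition_chromosome


def _spread_positions(
    lo: int, hi: int, n: int, min_sep: int, rng: np.random.Generator
) -> np.ndarray:
    """n positions in [lo, hi) with pairwise separation >= min_sep (uniform)."""
    if n <= 0:
        return np.empty(0, dtype=int)
    slack = (hi - lo) - (n - 1) * min_sep - 1
    if slack < 0:
        raise ValueError("interval too short for requested position count")
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    return lo + cuts + min_sep * np.arange(n)


def synthetic_region_sequence(
    length: int,
    n_cpgs: int,
    rng: np.random.Generator,
    min_sep: int = 4,
    island_frac: tuple[float, float] = (0.5, 0.8),
    island_spacing: tuple[int, int] = (7, 16),
) -> tuple[str, list[int]]:
    """Random DNA of given length with exactly ``n_cpgs`` CG dinucleotides.

    CpG placement emulates the island structure of real methylomes: a
    fraction of the sites (``island_frac``) forms one dense cluster with
    per-gap spacings drawn from ``island_spacing`` (sub-10-bp gaps occur,
    so the cluster yields multi-CpG CG-groups, as in real caller output),
    while the remaining sites are scattered uniformly over the flanks with
    a minimum separation.  The background is random A/C/G/T with any
    accidental CG removed (its G mutated to A), so the returned positions
    are the complete CpG set.  Small regions (fewer than 6 CpGs) are
    placed uniformly without an island.
    """
    if n_cpgs * min_sep + 2 > length:
        raise ValueError("region too short for requested CpG count")
    if n_cpgs >= 6:
        n_island = int(round(n_cpgs * rng.uniform(*island_frac)))
        gaps = rng.integers(island_spacing[0], island_spacing[1], size=n_island - 1)
        island_len = int(gaps.sum()) + 2
        n_bg = n_cpgs - n_island
        # leave room for the background sites in the flanks
        margin = (n_bg + 2) * min_sep
        start = int(rng.integers(margin, max(margin + 1, length - island_len - margin)))
        island = start + np.concatenate([[0], np.cumsum(gaps)])
        left_len = start - min_sep
        right_lo = int(island[-1]) + min_sep + 2
        right_len = max(0, length - 2 - right_lo)
        n_left = int(rng.binomial(n_bg, left_len / max(left_len + right_len, 1)))
        n_left = min(n_left, max(0, left_len // min_sep))
        n_right = n_bg - n_left
        left = _spread_positions(0, left_len, n_left, min_sep, rng)
        right = _spread_positions(right_lo, length - 2, n_right, min_sep, rng)
        positions = np.sort(np.concatenate([left, island, right]))
    else:
        positions = _spread_positions(0, length - 2, n_cpgs, min_sep, rng)
    seq = rng.choice(list("ACGT"), size=length)
    for p in positions:
        seq[p], seq[p + 1] = "C", "G"
    s = "".join(seq)
    chosen = set(int(p) for p in positions)
    out = list(s)
    i = s.find("CG")
    while i != -1:
        if i not in chosen:
            out[i + 1] = "A"
        i = s.find("CG", i + 1)
    return "".join(out), [int(p) for p in positions]


def synthetic_chromosome(
    n_regions: int,
    region_size: int,
    rng: np.random.Generator,
    n_cpgs_range: tuple[int, int] = (20, 60),
    **partition_kwargs,
) -> tuple[str, list[EstimationRegion]]:
    """Concatenate synthetic estimation-region sequences into a chromosome."""
    parts = []
    for _ in range(n_regions):
        n_cpgs = int(rng.integers(n_cpgs_range[0], n_cpgs_range[1] + 1))
        part, _ = synthetic_region_sequence(region_size, n_cpgs, rng)
        parts.append(part)
    # avoid CG formation across a junction: "...C" + "G..." cannot occur
    # because synthetic_region_sequence never ends a region mid-CG; still,
    # guard by mutating any junction G
    seq = list("".join(parts))
    for j in range(1, n_regions):
        p = j * region_size
        if seq[p - 1] == "C" and seq[p] == "G":
            seq[p] = "A"
    sequence = "".join(seq)
    regions = partition_chromosome(sequence, "chrSim", region_size=region_size, **partition_kwargs)
    return sequence, regions


def sample_truth_params(
    n_regions: int, config: SimConfig, rng: np.random.Generator
) -> list[CpelParams]:
    """Draw one theta per region uniformly from the prior boxes."""
    out = []
    for _ in range(n_regions):
        out.append(
            CpelParams(
                alpha=float(rng.uniform(*config.alpha_range)),
                beta=float(rng.uniform(*config.beta_range)),
                gamma=float(rng.uniform(*config.gamma_range)),
            )
        )
    return out


def simulate_reads(
    chrom_length: int, config: SimConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Read spans (0-based half-open) reaching the target mean coverage.

    Read lengths are lognormal (median ``read_length_mean``, log-scale sd
    ``read_length_log_sd``, clipped below at ``read_length_min``); starts
    are uniform including partial overlaps at the chromosome ends, so the
    expected coverage is uniform along the chromosome.  Reads accumulate
    until the expected per-position coverage meets the target.
    """
    spans: list[tuple[int, int]] = []
    expected = 0.0
    while expected < config.target_coverage:
        length = int(
            np.clip(
                rng.lognormal(np.log(config.read_length_mean), config.read_length_log_sd),
                config.read_length_min,
                None,
            )
        )
        start = int(rng.integers(-(length - 1), chrom_length))
        spans.append((max(0, start), min(chrom_length, start + length)))
        expected += length / (chrom_length + length - 1)
    return spans


def simulate_read_signals(
    region: EstimationRegion,
    span: tuple[int, int],
    theta: CpelParams,
    config: SimConfig,
    rng: np.random.Generator,
    read_id: str,
) -> tuple[ReadEmission, np.ndarray]:
    """One read: hidden group-consistent state plus Gaussian emissions.

    The hidden state covers the whole region (one molecule); emissions are
    produced only for CG-groups fully contained in the read span.  Returns
    the emission record and the true per-group state vector.
    """
    states = sample_state(region, theta, group_consistent=True, rng=rng, n=1)[0]
    group_states = np.array(
        [states[g.first_site_idx] for g in region.groups], dtype=int
    )
    em = ReadEmission(read_id=read_id, region_id=region.region_id)
    start, end = span
    for g, grp in enumerate(region.groups):
        if grp.start >= start and grp.end <= end:
            mean = (2 * group_states[g] - 1) * config.delta / 2
            signal = float(mean + rng.normal(0.0, config.noise_sd))
            ll_m, ll_u = gaussian_group_loglik(signal, config.noise_sd, config.delta)
            em.entries.append((g, ll_m, ll_u))
    return em, group_states


def mean_cpg_coverage(region: EstimationRegion, reads: list[ReadEmission]) -> float:
    """Average over CpG sites of the number of reads calling the site's group."""
    if region.n_sites == 0:
        return 0.0
    counts = np.zeros(region.n_groups)
    for read in reads:
        for g, _, _ in read.entries:
            counts[g] += 1
    return float(np.repeat(counts, region.group_sizes()).mean())


def subsample_to_coverage(
    pool: list[ReadEmission],
    target_coverage: float,
    region: EstimationRegion,
    rng: np.random.Generator,
) -> tuple[list[ReadEmission], bool]:
    """Iterative random-transfer subsampling to a desired mean CpG coverage.

    One read at a time is moved at random from the remaining pool into the
    selected set until the average per-CpG coverage of the selected set is
    no less than the target.  Returns (selected reads, reached_target);
    if the pool is exhausted first, all reads are returned with a False
    flag.
    """
    if not pool:
        raise ValueError("read pool is empty")
    remaining = list(pool)
    selected: list[ReadEmission] = []
    counts = np.zeros(region.n_groups)
    sizes = region.group_sizes()
    n_sites = max(region.n_sites, 1)
    mean_cov = 0.0
    while mean_cov < target_coverage:
        if not remaining:
            return selected, False
        idx = int(rng.integers(len(remaining)))
        read = remaining.pop(idx)
        selected.append(read)
        for g, _, _ in read.entries:
            counts[g] += 1
        mean_cov = float((counts * sizes).sum() / n_sites)
    return selected, True


def simulate_region_dataset(
    region: EstimationRegion,
    theta: CpelParams,
    config: SimConfig,
    rng: np.random.Generator,
    pool_factor: float = 1.6,
) -> tuple[list[ReadEmission], dict[str, np.ndarray]]:
    """Simulate a read pool over one region and subsample to target coverage.

    The initial pool is generated at ``pool_factor`` times the target
    coverage, then thinned with :func:`subsample_to_coverage`.  Returns
    the selected reads and a map read_id -> true per-group state vector.
    """
    pool_cfg = SimConfig(
        noise_sd=config.noise_sd,
        delta=config.delta,
        target_coverage=config.target_coverage * pool_factor,
        read_length_mean=config.read_length_mean,
        read_length_log_sd=config.read_length_log_sd,
        read_length_min=config.read_length_min,
        alpha_range=config.alpha_range,
        beta_range=config.beta_range,
        gamma_range=config.gamma_range,
    )
    length = region.end - region.start
    spans = simulate_reads(length, pool_cfg, rng)
    pool = []
    truth: dict[str, np.ndarray] = {}
    for i, (s, e) in enumerate(spans):
        span = (region.start + s, region.start + e)
        read_id = f"{region.region_id}_read{i}"
        em, states = simulate_read_signals(region, span, theta, config, rng, read_id)
        if em.entries:
            pool.append(em)
            truth[read_id] = states
    if not pool:
        return [], truth
    selected, _ = subsample_to_coverage(pool, config.target_coverage, region, rng)
    return selected, truth
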