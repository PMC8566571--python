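"""Shared fixtures: hand-built regions and a brute-force model oracle.

The enumeration oracle recomputes every model quantity by summing over all
2^N states with the potential written out directly, independently of the
transfer-matrix code paths it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cpelmeth.model import CpelParams
from cpelmeth.regions import EstimationRegion, build_cg_groups, make_analysis_regions


def make_region(
    positions: list[int],
    chrom_length: int | None = None,
    rho: np.ndarray | None = None,
    cg_gap: int = 10,
    s_max: int = 350,
    chrom: str = "chrT",
) -> EstimationRegion:
    """Build a fully populated region directly from CpG positions."""
    if chrom_length is None:
        chrom_length = (positions[-1] + 100) if positions else 100
    region = EstimationRegion(chrom=chrom, start=0, end=chrom_length)
    region.cpg_positions = list(positions)
    if rho is None:
        rho = np.linspace(0.02, 0.2, len(positions))
    region.rho = np.asarray(rho, dtype=float)
    region.dist = np.diff(positions).astype(float)
    region.groups = build_cg_groups(positions, cg_gap)
    region.analysis_regions = make_analysis_regions(region, s_max)
    return region


def enumerate_model(region: EstimationRegion, theta: CpelParams, group_consistent=False):
    """Brute-force pattern table: (patterns, probabilities, log Z, stats).

    States are enumerated exhaustively; the potential is evaluated from its
    definition (fields alpha + beta*rho_n, nearest-neighbor coupling gamma).
    """
    N = region.n_sites
    rho = region.rho
    if group_consistent:
        sizes = [g.n_sites for g in region.groups]
        pats = [
            np.repeat(np.array(xg, dtype=float), sizes)
            for xg in itertools.product([0, 1], repeat=len(sizes))
        ]
    else:
        pats = [np.array(x, dtype=float) for x in itertools.product([0, 1], repeat=N)]
    pats = np.array(pats)
    spins = 2 * pats - 1
    s1 = spins.sum(axis=1)
    s2 = spins @ rho
    s3 = (spins[:, :-1] * spins[:, 1:]).sum(axis=1) if N > 1 else np.zeros(len(pats))
    stats = np.column_stack([s1, s2, s3])
    logw = stats @ np.array([theta.alpha, theta.beta, theta.gamma])
    m = logw.max()
    z = np.exp(logw - m).sum()
    logz = m + np.log(z)
    probs = np.exp(logw - logz)
    return pats, probs, logz, stats


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_region():
    """8 CpG sites, mixed spacing: two 2-site CG-groups and 4 singletons."""
    return make_region([19, 26, 278, 304, 447, 489, 565, 570], chrom_length=700)


@pytest.fixture
def theta():
    return CpelParams(0.4, -0.7, 0.6)
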