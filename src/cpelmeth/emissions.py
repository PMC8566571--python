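"""Per-read emission evidence q(y | x): parsing, binarization, signal model.

Nanopore methylation callers emit, per read and per CG-group, a pair of
log-likelihoods for the grouped current evidence under the methylated and
unmethylated hypotheses.  This module consumes tables in the Nanopolish
``call-methylation`` TSV dialect, turns them into :class:`ReadEmission`
records indexed by CG-group, thresholds log-likelihood ratios into hard
calls, and provides the two-mean Gaussian signal model used by the
simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regions import EstimationRegion

logger = logging.getLogger(__name__)

NANOPOLISH_COLUMNS = [
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "log_lik_methylated",
    "log_lik_unmethylated",
    "num_calling_strands",
    "num_motifs",
    "sequence",
]


@dataclass
class ReadEmission:
    """One read's per-CG-group emission log-likelihood pairs.

    ``entries`` holds ``(group_index, ll_meth, ll_unmeth)`` tuples for the
    CG-groups the read covers; uncovered groups are simply absent and are
    marginalized downstream (emission factor 1), never imputed.
    """

    read_id: str
    region_id: str
    entries: list[tuple[int, float, float]] = field(default_factory=list)

    def covered_groups(self) -> list[int]:
        return [g for g, _, _ in self.entries]


class Call(Enum):
    UNMETHYLATED = 0
    METHYLATED = 1
    ABSTAIN = 2


@dataclass
class BinaryCalls:
    """Hard per-CG-group calls for one read."""

    read_id: str
    region_id: str
    entries: list[tuple[int, Call]] = field(default_factory=list)


def llr(entry: tuple[int, float, float]) -> float:
    """Log-likelihood ratio (methylated vs unmethylated) of one entry."""
    return entry[1] - entry[2]


def parse_nanopolish_calls(
    source, regions: Sequence[EstimationRegion]
) -> list[ReadEmission]:
    """Parse a Nanopolish ``call-methylation`` TSV into ReadEmissions.

    Rows are grouped by ``read_name`` and matched to CG-groups by overlap
    of their ``[start, end]`` motif span with the group span; rows on the
    reverse strand are first mapped to the forward-strand C (pos - 1).
    Rows falling outside every region are skipped (counted in the log);
    duplicate (read, group) rows keep the entry with the larger |LLR|.
    """
    df = pd.read_csv(source, sep="\t", comment=None)
    missing = set(NANOPOLISH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")

    # fast lookup: per chromosome, sorted regions with group spans
    by_chrom: dict[str, list[EstimationRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: r.start)

    emissions: dict[tuple[str, str], ReadEmission] = {}
    n_skipped = 0
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if row.strand == "-":
            start, end = start - 1, end - 1
        matched = False
        for region in by_chrom.get(str(row.chromosome), []):
            if start >= region.end or end < region.start:
                continue
            for g, grp in enumerate(region.groups):
                # inclusive motif span vs half-open group span
                if start < grp.end and end >= grp.start:
                    if int(row.num_motifs) != grp.n_sites:
                        logger.debug(
                            "row num_motifs=%s disagrees with group size %d at %s:%d",
                            row.num_motifs, grp.n_sites, region.chrom, start,
                        )
                    key = (str(row.read_name), region.region_id)
                    em = emissions.setdefault(
                        key, ReadEmission(read_id=key[0], region_id=key[1])
                    )
                    entry = (g, float(row.log_lik_methylated), float(row.log_lik_unmethylated))
                    if not np.isfinite(entry[1]) or not np.isfinite(entry[2]):
                        raise ValueError(f"non-finite log-likelihood in row {row}")
                    existing = next((i for i, e in enumerate(em.entries) if e[0] == g), None)
                    if existing is None:
                        em.entries.append(entry)
                    elif abs(llr(entry)) > abs(llr(em.entries[existing])):
                        em.entries[existing] = entry
                    matched = True
                    break
            if matched:
                break
        if not matched:
            n_skipped += 1
    if n_skipped:
        logger.info("skipped %d rows outside all regions", n_skipped)
    for em in emissions.values():
        em.entries.sort(key=lambda e: e[0])
    return list(emissions.values())


def write_nanopolish_calls(
    emissions: Iterable[ReadEmission],
    regions: Sequence[EstimationRegion],
    path,
    sequence: str | None = None,
) -> None:
    """Write ReadEmissions back out in the Nanopolish TSV dialect."""
    by_id = {r.region_id: r for r in regions}
    rows = []
    for em in emissions:
        region = by_id[em.region_id]
        for g, ll_m, ll_u in em.entries:
            grp = region.groups[g]
            first = region.cpg_positions[grp.first_site_idx]
            last = region.cpg_positions[grp.last_site_idx]
            if sequence is not None:
                ctx = sequence[max(0, first - 5) : last + 7]
            else:
                ctx = "."
            rows.append(
                {
                    "chromosome": region.chrom,
                    "strand": "+",
                    "start": first,
                    "end": last,
                    "read_name": em.read_id,
                    "log_lik_ratio": ll_m - ll_u,
                    "log_lik_methylated": ll_m,
                    "log_lik_unmethylated": ll_u,
                    "num_calling_strands": 1,
                    "num_motifs": grp.n_sites,
                    "sequence": ctx,
                }
            )
    pd.DataFrame(rows, columns=NANOPOLISH_COLUMNS).to_csv(path, sep="\t", index=False)


def binarize_calls(
    emissions: Iterable[ReadEmission], threshold: float = 0.0
) -> list[BinaryCalls]:
    """Threshold LLRs into hard calls; |LLR| <= threshold abstains.

    At threshold 0 an exact tie (LLR = 0) abstains.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    out = []
    for em in emissions:
        calls = BinaryCalls(read_id=em.read_id, region_id=em.region_id)
        for entry in em.entries:
            ratio = llr(entry)
            if ratio > threshold:
                call = Call.METHYLATED
            elif ratio < -threshold:
                call = Call.UNMETHYLATED
            else:
                call = Call.ABSTAIN
            calls.entries.append((entry[0], call))
        out.append(calls)
    return out


def gaussian_group_loglik(signal: float, sd: float, delta: float) -> tuple[float, float]:
    """Two-mean Gaussian emission model for one CG-group current summary.

    The grouped current summary is modeled as N(+delta/2, sd^2) when the
    group is methylated and N(-delta/2, sd^2) when unmethylated, a
    deliberate simplification of the k-mer pore model in which ``delta``
    controls separability.  The resulting LLR is delta * signal / sd^2.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    const = -0.5 * np.log(2 * np.pi * sd**2)
    ll_meth = const - 0.5 * ((signal - delta / 2) / sd) ** 2
    ll_unmeth = const - 0.5 * ((signal + delta / 2) / sd) ** 2
    return float(ll_meth), float(ll_unmeth)
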