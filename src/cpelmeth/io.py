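"""Tab-separated readers/writers for fits, summary tracks and test results.

All files are plain TSV with a header row; coordinates are 0-based
half-open (BED convention).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .differential import RegionTestResult
from .estimation import FitResult
from .model import CpelParams
from .regions import EstimationRegion

FIT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "alpha",
    "beta",
    "gamma",
    "n_cpgs",
    "log_likelihood",
    "n_reads",
    "converged",
]


def write_fits(
    fits: Sequence[tuple[EstimationRegion, FitResult]], path
) -> None:
    rows = []
    for region, fit in fits:
        rows.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "alpha": fit.theta_hat.alpha,
                "beta": fit.theta_hat.beta,
                "gamma": fit.theta_hat.gamma,
                "n_cpgs": region.n_sites,
                "log_likelihood": fit.loglik_trace[-1] if fit.loglik_trace else float("nan"),
                "n_reads": fit.n_reads,
                "converged": fit.converged,
            }
        )
    pd.DataFrame(rows, columns=FIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fits(path) -> dict[tuple[str, int, int], CpelParams]:
    """Map (chrom, start, end) -> fitted parameters."""
    df = pd.read_csv(path, sep="\t")
    missing = set(FIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fit table missing columns: {sorted(missing)}")
    return {
        (str(r.chrom), int(r.start), int(r.end)): CpelParams(
            float(r.alpha), float(r.beta), float(r.gamma)
        )
        for r in df.itertuples(index=False)
    }


def write_track(rows: Sequence[tuple[str, int, int, float]], path, value_name: str) -> None:
    """BED-like TSV track: chrom, start, end, value."""
    pd.DataFrame(rows, columns=["chrom", "start", "end", value_name]).to_csv(
        path, sep="\t", index=False
    )


def write_diff_results(
    results: Sequence[tuple[str, int, int, RegionTestResult]], path
) -> None:
    rows = []
    for chrom, start, end, r in results:
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "Tmml": r.t_mml,
                "Pmml": r.p_mml,
                "Qmml": r.q_mml,
                "Tnme": r.t_nme,
                "Pnme": r.p_nme,
                "Qnme": r.q_nme,
                "Tcmd": r.t_cmd,
                "Pcmd": r.p_cmd,
                "Qcmd": r.q_cmd,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
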