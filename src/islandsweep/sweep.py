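"""Joint empirical-percentile selective-sweep scan.

Candidate sweep windows are those strictly above both the Fst and the
diversity log-ratio empirical cutoffs (nearest-rank q-quantile, default
0.95); flagged windows on the same scaffold that overlap or are book-ended
(end + 1 = start) merge into candidate regions.  Ties at the threshold are
excluded — deterministic and conservative.  +inf log-ratio flags (fully
swept windows with zero diversity in the selected group) sort above every
finite value and are always included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SweepRegion:
    scaffold: str
    start: int
    end: int
    n_windows: int
    mean_fst: float
    mean_pi_log_ratio: float
    contained_snps: list[tuple[str, int]] = field(default_factory=list)


def empirical_cutoff(values, q: float = 0.95, min_values: int = 20) -> float:
    """Nearest-rank q-quantile of the finite values.

    +inf flags are not part of the finite distribution but always exceed the
    returned threshold.  NaN values are ignored.
    """
    v = np.asarray(values, float)
    finite = np.sort(v[np.isfinite(v)])
    if len(finite) < min_values:
        raise ValueError(f"need at least {min_values} finite values, got {len(finite)}")
    rank = int(np.ceil(q * len(finite)))
    return float(finite[max(rank - 1, 0)])


def call_sweeps(
    windows: pd.DataFrame,
    q: float = 0.95,
    fst_col: str = "fst",
    ratio_col: str = "pi_log_ratio",
    per_scaffold: bool = False,
) -> list[SweepRegion]:
    """Call candidate sweep regions from a window-statistic table.

    Windows strictly above both nearest-rank cutoffs are flagged; flagged
    windows merge by overlap or book-ending within a scaffold.  Cutoffs are
    computed genome-wide by default (``per_scaffold`` switches to
    per-scaffold empirical distributions).
    """
    w = windows.sort_values(["scaffold", "start"]).reset_index(drop=True)
    fst = w[fst_col].to_numpy(float)
    ratio = w[ratio_col].to_numpy(float)
    if per_scaffold:
        flag = np.zeros(len(w), dtype=bool)
        for sc in w["scaffold"].unique():
            i = (w["scaffold"] == sc).to_numpy()
            cf = empirical_cutoff(fst[i], q)
            cr = empirical_cutoff(ratio[i], q)
            flag[i] = (fst[i] > cf) & (ratio[i] > cr)
    else:
        cf = empirical_cutoff(fst, q)
        cr = empirical_cutoff(ratio, q)
        flag = (fst > cf) & (ratio > cr)
    regions: list[SweepRegion] = []
    cur = None  # (scaffold, start, end, [row indices])
    for i in np.flatnonzero(flag):
        sc, s, e = w.loc[i, "scaffold"], int(w.loc[i, "start"]), int(w.loc[i, "end"])
        if cur is not None and cur[0] == sc and s <= cur[2] + 1:
            cur = (sc, cur[1], max(cur[2], e), cur[3] + [i])
        else:
            if cur is not None:
                regions.append(_finish(cur, w, fst_col, ratio_col))
            cur = (sc, s, e, [i])
    if cur is not None:
        regions.append(_finish(cur, w, fst_col, ratio_col))
    return regions


def _finish(cur, w, fst_col, ratio_col) -> SweepRegion:
    sc, s, e, idx = cur
    fst_vals = w.loc[idx, fst_col].to_numpy(float)
    ratio_vals = w.loc[idx, ratio_col].to_numpy(float)
    finite_ratio = ratio_vals[np.isfinite(ratio_vals)]
    return SweepRegion(
        scaffold=sc, start=s, end=e, n_windows=len(idx),
        mean_fst=float(np.nanmean(fst_vals)),
        mean_pi_log_ratio=float(np.mean(finite_ratio)) if len(finite_ratio) else float("inf"),
    )


def annotate_regions(
    regions: list[SweepRegion], snps: list[tuple[str, int]]
) -> list[SweepRegion]:
    """Attach SNPs (1-based positions) contained in each region, inclusive bounds."""
    for r in regions:
        r.contained_snps = [
            (sc, pos) for sc, pos in snps if sc == r.scaffold and r.start <= pos <= r.end
        ]
    return regions


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold": r.scaffold, "start": r.start, "end": r.end,
                "n_windows": r.n_windows, "mean_fst": r.mean_fst,
                "mean_pi_log_ratio": r.mean_pi_log_ratio,
                "n_contained_snps": len(r.contained_snps),
            }
            for r in regions
        ],
        columns=["scaffold", "start", "end", "n_windows", "mean_fst",
                 "mean_pi_log_ratio", "n_contained_snps"],
    )


def regions_to_bed(regions: list[SweepRegion]) -> pd.DataFrame:
    """0-based half-open BED representation of the (1-based inclusive) regions."""
    return pd.DataFrame(
        [{"chrom": r.scaffold, "start": r.start - 1, "end": r.end} for r in regions],
        columns=["chrom", "start", "end"],
    )
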