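"""Copy-number-variable regions (CNVRs) and VST morph differentiation.

Per-individual CNV calls (scaffold, 1-based inclusive start/end, copy number
normalised so the single-X male baseline is 1) are merged into CNVRs by
transitive overlap per scaffold, boundaries being the minimum start and
maximum end of the member calls.  CNVRs supported by fewer than three
distinct individuals are filtered.  Individuals without a call in a region
sit at the baseline copy number of 1.

Differentiation between groups uses VST = (VT - VS) / VT, where VT is the
total copy-number variance across both groups pooled and VS the
sample-size-weighted average of the within-group variances (sample, n-1,
variances throughout).  A CNVR in the top 5% of VST that also has a
two-sample t-test p < 0.05 is flagged as morph-differentiated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sweep import empirical_cutoff

MIN_SUPPORT = 3
BASELINE_COPY_NUMBER = 1.0


@dataclass
class CNVR:
    scaffold: str
    start: int
    end: int
    support: int  # distinct individuals with a call in the region
    copy_numbers: dict[str, float] = field(default_factory=dict)
    vst: float | None = None
    t_p: float | None = None
    differentiated: bool = False


def merge_cnvrs(
    calls: pd.DataFrame,
    all_individuals: list[str] | None = None,
    min_support: int = MIN_SUPPORT,
) -> list[CNVR]:
    """Merge per-individual CNV calls into supported CNVRs.

    ``calls`` columns: individual, scaffold, start, end, copy_number.
    ``all_individuals`` fixes the cohort whose members default to copy
    number 1 where they have no call (defaults to the individuals present
    in ``calls``).
    """
    if len(calls) and ((calls["end"] < calls["start"]).any() or (calls["start"] < 1).any()):
        raise ValueError("malformed intervals: need 1 <= start <= end")
    if all_individuals is None:
        all_individuals = sorted(calls["individual"].unique()) if len(calls) else []
    out: list[CNVR] = []
    for scaffold, sub in calls.groupby("scaffold") if len(calls) else []:
        sub = sub.sort_values(["start", "end"]).reset_index(drop=True)
        cluster: list[int] = []
        cur_end = None
        for i in range(len(sub)):
            s, e = int(sub.loc[i, "start"]), int(sub.loc[i, "end"])
            if cur_end is not None and s <= cur_end:
                cluster.append(i)
                cur_end = max(cur_end, e)
            else:
                if cluster:
                    out.extend(_close(scaffold, sub.loc[cluster], all_individuals, min_support))
                cluster = [i]
                cur_end = e
        if cluster:
            out.extend(_close(scaffold, sub.loc[cluster], all_individuals, min_support))
    return out


def _close(scaffold, member_calls: pd.DataFrame, cohort, min_support) -> list[CNVR]:
    supporters = member_calls["individual"].unique()
    if len(supporters) < min_support:
        return []
    cn = {ind: BASELINE_COPY_NUMBER for ind in cohort}
    # an individual with several member calls contributes its mean copy number
    for ind, grp in member_calls.groupby("individual"):
        cn[ind] = float(grp["copy_number"].mean())
    return [
        CNVR(
            scaffold=scaffold,
            start=int(member_calls["start"].min()),
            end=int(member_calls["end"].max()),
            support=len(supporters),
            copy_numbers=cn,
        )
    ]


def vst(group_a, group_b) -> float:
    """VST = (VT - VS) / VT on copy numbers; 0 when there is no variance.

    VS is the within-group variance averaged with sample-size weights;
    sample (n-1) variances are used throughout.  Symmetric in group order
    and invariant to adding a constant to all copy numbers.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 individuals")
    vt = float(np.var(np.concatenate([a, b]), ddof=1))
    if vt == 0:
        return 0.0
    vs = (len(a) * np.var(a, ddof=1) + len(b) * np.var(b, ddof=1)) / (len(a) + len(b))
    return float((vt - vs) / vt)


def differentiated_cnvrs(
    cnvrs: list[CNVR],
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    q: float = 0.95,
    t_alpha: float = 0.05,
) -> list[CNVR]:
    """Flag CNVRs in the top VST percentile that also pass the t-test.

    ``groups`` maps individual -> group label.  VST and the two-sample
    t-test are computed on each region's per-individual copy numbers; flag =
    (VST strictly above the nearest-rank q cutoff) AND (t-test p < t_alpha).
    """
    for r in cnvrs:
        a = [v for ind, v in r.copy_numbers.items() if groups.get(ind) == group_a]
        b = [v for ind, v in r.copy_numbers.items() if groups.get(ind) == group_b]
        r.vst = vst(a, b)
        if np.var(a) == 0 and np.var(b) == 0:
            r.t_p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        else:
            r.t_p = float(stats.ttest_ind(a, b, equal_var=False)[1])
    vsts = [r.vst for r in cnvrs]
    if len(cnvrs) < 20:
        warnings.warn(
            f"only {len(cnvrs)} CNVRs; the top-{100 * (1 - q):g}% percentile is noisy",
            stacklevel=2,
        )
    cutoff = empirical_cutoff(vsts, q, min_values=min(len(cnvrs), 20))
    for r in cnvrs:
        r.differentiated = bool(r.vst > cutoff and r.t_p < t_alpha)
    return cnvrs


def cnvrs_to_frame(cnvrs: list[CNVR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold": r.scaffold, "start": r.start, "end": r.end,
                "support": r.support, "vst": r.vst, "t_p": r.t_p,
                "differentiated": r.differentiated,
            }
            for r in cnvrs
        ],
        columns=["scaffold", "start", "end", "support", "vst", "t_p", "differentiated"],
    )
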