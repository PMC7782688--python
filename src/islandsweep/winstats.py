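"""Sliding-window population statistics.

Windows default to 10 kb with a 2.5 kb step; windows overstepping a scaffold
boundary are dropped.  Per-site denominators follow the whole-window-bp
convention (monomorphic and uncallable sites contribute zero to numerators),
which reproduces the behaviour of the standard VCF toolchain on all-sites
data.  Missing calls are handled by pairwise deletion: each site contributes
only its observed alleles.

Statistics: nucleotide diversity pi, Watterson's theta, Tajima's D, the
Weir-Cockerham and Hudson Fst estimators, absolute divergence dxy, net
divergence d = dxy - (dx + dy)/2, the diversity log-ratio
log10(pi_unselected / pi_selected) used for sweep scanning, and haplotype
r^2 with greedy LD pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

DEFAULT_WINDOW = 10_000
DEFAULT_STEP = 2_500


@dataclass
class WindowSpec:
    size: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.step > self.size:
            raise ValueError("step must not exceed window size")


def window_iter(spec: WindowSpec):
    """Yield (scaffold, start, end) 1-based inclusive windows fully inside scaffolds."""
    for scaffold, length in spec.lengths.items():
        start = 1
        while start + spec.size - 1 <= length:
            yield scaffold, start, start + spec.size - 1
            start += spec.step


# ---------------------------------------------------------------------------
# per-site building blocks (vectorised over sites)
# ---------------------------------------------------------------------------

def _pair_diffs(n_alt: np.ndarray, n_called: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference 2*n_ref*n_alt / (n*(n-1)); 0 where n < 2."""
    n = n_called.astype(float)
    n_ref = n - n_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 2.0 * n_ref * n_alt / (n * (n - 1.0))
    d[n < 2] = 0.0
    return d


def pi(n_alt: np.ndarray, n_called: np.ndarray, window_bp: int) -> float:
    """Nucleotide diversity: summed per-site pairwise differences / window bp.

    Returns NaN (undefined) when no site in the window has two observed
    alleles.
    """
    if window_bp <= 0:
        raise ValueError("window length must be positive")
    if len(n_called) == 0 or not np.any(n_called >= 2):
        return float("nan")
    return float(_pair_diffs(np.asarray(n_alt, float), np.asarray(n_called, float)).sum() / window_bp)


def watterson_theta(n_alt: np.ndarray, n_called: np.ndarray) -> float:
    """Watterson's estimator S / a1 per window (absolute, not per site)."""
    seg = (n_alt > 0) & (n_alt < n_called)
    s = int(seg.sum())
    if s == 0:
        return 0.0
    n = int(np.round(np.mean(n_called[seg])))
    if n < 2:
        return float("nan")
    a1 = np.sum(1.0 / np.arange(1, n))
    return s / a1


def tajimas_d(n_alt: np.ndarray, n_called: np.ndarray) -> float:
    """Tajima's (1989) D over a window; NaN when there are no segregating sites.

    k is the mean pairwise difference count over the window (absolute).  The
    sample size entering the constants is the (rounded) mean call count over
    segregating sites; on clean simulated data this is simply n.
    """
    n_alt = np.asarray(n_alt, float)
    n_called = np.asarray(n_called, float)
    seg = (n_alt > 0) & (n_alt < n_called) & (n_called >= 2)
    s = int(seg.sum())
    if s == 0:
        return float("nan")
    n = int(np.round(np.mean(n_called[seg])))
    if n < 2:
        return float("nan")
    k = float(_pair_diffs(n_alt, n_called)[seg].sum())
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return float("nan")
    return float((k - s / a1) / np.sqrt(var))


def fst_weir_cockerham(
    n_alt_a, n_called_a, n_alt_b, n_called_b
) -> float:
    """Weir-Cockerham (1984) weighted two-population Fst over a window.

    Allele-level analysis of variance: per-site among-population (MSP) and
    within-population (MSG) mean squares are combined as a ratio of sums
    across sites.  Negative estimates are reported as-is.  Haploid male-X
    calls enter as single alleles.
    """
    n1 = np.asarray(n_called_a, float)
    n2 = np.asarray(n_called_b, float)
    p1 = np.divide(n_alt_a, n1, out=np.zeros_like(n1), where=n1 > 0)
    p2 = np.divide(n_alt_b, n2, out=np.zeros_like(n2), where=n2 > 0)
    use = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)
    poly = use & ((np.asarray(n_alt_a) + np.asarray(n_alt_b)) > 0) & (
        (np.asarray(n_alt_a) + np.asarray(n_alt_b)) < (n1 + n2)
    )
    if not np.any(poly):
        return float("nan")
    n1, n2, p1, p2 = n1[poly], n2[poly], p1[poly], p2[poly]
    ntot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    r = 2.0
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - r)
    nc = (ntot - (n1**2 + n2**2) / ntot) / (r - 1)
    num = msp - msg
    den = msp + (nc - 1) * msg
    den_sum = float(den.sum())
    if den_sum == 0:
        return float("nan")
    return float(num.sum() / den_sum)


def fst_hudson(n_alt_a, n_called_a, n_alt_b, n_called_b) -> float:
    """Hudson's Fst (1 - Hw/Hb), ratio-of-sums across sites."""
    n1 = np.asarray(n_called_a, float)
    n2 = np.asarray(n_called_b, float)
    a1 = np.asarray(n_alt_a, float)
    a2 = np.asarray(n_alt_b, float)
    use = (n1 >= 2) & (n2 >= 2)
    if not np.any(use):
        return float("nan")
    n1, n2, a1, a2 = n1[use], n2[use], a1[use], a2[use]
    p1, p2 = a1 / n1, a2 / n2
    # unbiased within-heterozygosity, averaged over the two populations
    hw = (2 * p1 * (1 - p1) * n1 / (n1 - 1) + 2 * p2 * (1 - p2) * n2 / (n2 - 1)) / 2.0
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    hb_sum = float(hb.sum())
    if hb_sum == 0:
        return float("nan")
    return float(1.0 - hw.sum() / hb_sum)


def dxy(n_alt_a, n_called_a, n_alt_b, n_called_b, window_bp: int) -> float:
    """Absolute divergence: mean inter-population per-site difference / window bp."""
    n1 = np.asarray(n_called_a, float)
    n2 = np.asarray(n_called_b, float)
    a1 = np.asarray(n_alt_a, float)
    a2 = np.asarray(n_alt_b, float)
    use = (n1 >= 1) & (n2 >= 1)
    if not np.any(use):
        return float("nan")
    p1 = a1[use] / n1[use]
    p2 = a2[use] / n2[use]
    d = p1 * (1 - p2) + p2 * (1 - p1)
    return float(d.sum() / window_bp)


def net_divergence(dxy_val: float, dx: float, dy: float) -> float:
    """Net divergence d = dxy - (dx + dy)/2."""
    return dxy_val - (dx + dy) / 2.0


def pi_log_ratio(pi_unselected: float, pi_selected: float) -> float:
    """log10(pi_unselected / pi_selected); positive means diversity loss in
    the selected group.

    A fully swept window has pi_selected = 0 and must not be discarded, so it
    maps to +inf (flagged for top-percentile inclusion).  pi_unselected = 0
    leaves the ratio uninformative: NaN (window dropped).
    """
    if np.isnan(pi_unselected) or np.isnan(pi_selected) or pi_unselected == 0:
        return float("nan")
    if pi_selected == 0:
        return float("inf")
    return float(np.log10(pi_unselected / pi_selected))


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(hap_i: np.ndarray, hap_j: np.ndarray) -> float:
    """Squared haplotype-frequency correlation between two loci.

    Expects phased or haploid allele vectors (male X data are inherently
    haploid); missing values (<0) are dropped pairwise.  NaN when either
    locus is monomorphic among co-called haplotypes.
    """
    hap_i = np.asarray(hap_i)
    hap_j = np.asarray(hap_j)
    ok = (hap_i >= 0) & (hap_j >= 0)
    if ok.sum() < 2:
        return float("nan")
    a, b = hap_i[ok].astype(float), hap_j[ok].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = np.mean(a * b)
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def ld_prune(haplotypes: np.ndarray, threshold: float = 0.1, window: int = 50) -> np.ndarray:
    """Greedy left-to-right LD pruning.

    For each pair within a ``window``-site sliding window with r^2 strictly
    above ``threshold``, the later site is removed.  Monomorphic sites are
    excluded from pruning decisions (but retained).  Returns indices of
    retained sites.
    """
    n_sites = haplotypes.shape[0]
    keep = np.ones(n_sites, dtype=bool)
    for i in range(n_sites):
        if not keep[i]:
            continue
        for j in range(i + 1, min(i + window, n_sites)):
            if not keep[j]:
                continue
            r2 = ld_r2(haplotypes[i], haplotypes[j])
            if not np.isnan(r2) and r2 > threshold:
                keep[j] = False
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# window table assembly
# ---------------------------------------------------------------------------

def window_stats(
    matrices: list[GenotypeMatrix],
    pops: dict[str, list[str]],
    spec: WindowSpec | None = None,
    pairs: list[tuple[str, str]] | None = None,
    ratio_pair: tuple[str, str] | None = None,
    fst_estimator: str = "weir_cockerham",
) -> pd.DataFrame:
    """Compute the per-window statistic table.

    ``pops`` maps population labels to sample ids.  ``pairs`` selects the
    population pairs for Fst/dxy/d (default: all ordered combinations of the
    listed populations).  ``ratio_pair`` is (unselected, selected) for the
    diversity log-ratio.  Returns one row per window with columns
    ``pi_<pop>``, ``thetaW_<pop>``, ``tajd_<pop>``, ``fst_<a>_<b>``,
    ``dxy_<a>_<b>``, ``d_<a>_<b>``, and ``pi_log_ratio``.
    """
    if spec is None:
        spec = WindowSpec(lengths={m.scaffold: int(m.length) for m in matrices})
    if pairs is None:
        labels = list(pops)
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    fst_fn = {"weir_cockerham": fst_weir_cockerham, "hudson": fst_hudson}[fst_estimator]
    by_scaffold = {m.scaffold: m for m in matrices}
    rows = []
    for scaffold, start, end in window_iter(spec):
        m = by_scaffold.get(scaffold)
        if m is None:
            continue
        lo = np.searchsorted(m.positions, start, side="left")
        hi = np.searchsorted(m.positions, end, side="right")
        counts = {}
        for label, ids in pops.items():
            idx = m.sample_index(ids)
            n_alt, n_called = m.take_sites(np.arange(lo, hi)).allele_counts(idx) if hi > lo else (
                np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
            )
            counts[label] = (n_alt, n_called)
        row: dict = {"scaffold": scaffold, "start": start, "end": end, "n_sites": hi - lo}
        wbp = spec.size
        for label, (n_alt, n_called) in counts.items():
            row[f"pi_{label}"] = pi(n_alt, n_called, wbp)
            row[f"thetaW_{label}"] = watterson_theta(n_alt, n_called)
            row[f"tajd_{label}"] = tajimas_d(n_alt, n_called)
        for a, b in pairs:
            na, ca = counts[a]
            nb, cb = counts[b]
            row[f"fst_{a}_{b}"] = fst_fn(na, ca, nb, cb)
            dxy_v = dxy(na, ca, nb, cb, wbp)
            row[f"dxy_{a}_{b}"] = dxy_v
            row[f"d_{a}_{b}"] = net_divergence(dxy_v, row[f"pi_{a}"], row[f"pi_{b}"])
        if ratio_pair is not None:
            u, s = ratio_pair
            row["pi_log_ratio"] = pi_log_ratio(row[f"pi_{u}"], row[f"pi_{s}"])
        rows.append(row)
    return pd.DataFrame(rows)
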