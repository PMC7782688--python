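"""ABBA-BABA (Patterson's D) with weighted block jackknife.

The frequency-weighted (multi-individual) estimator is used throughout:
per site, with derived-allele frequencies p1, p2, p3 in the three focal
populations and p4 in the outgroup,

    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    D = (sum abba - sum baba) / (sum abba + sum baba)

Single haploid genomes reduce this to literal ABBA/BABA pattern counting.
The derived allele at each site is the allele that is not the outgroup
major allele; outgroup-polymorphic sites are retained with (1 - p4)
down-weighting rather than excluded.  Positive D indicates an excess of
shared derived alleles between P2 and P3, the signature of gene flow.

The standard error comes from a weighted delete-one block jackknife over
contiguous genomic blocks (weights = per-block denominators), with
Z = D / SE tested against the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

DEFAULT_BLOCK_SIZE = 1_000_000


@dataclass
class DResult:
    d: float
    se: float
    z: float
    p_value: float
    n_blocks: int
    block_size: int
    blocks: pd.DataFrame  # block, abba, baba, d_block
    taxa: tuple[str, str, str, str] | None = None


def site_weights(p1, p2, p3, p4) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (abba, baba) weights from derived-allele frequencies."""
    arrs = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    for a in arrs:
        if np.any((a < 0) | (a > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
    p1, p2, p3, p4 = arrs
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def d_statistic(abba: np.ndarray, baba: np.ndarray) -> float:
    """Genome-wide D; NaN when no informative sites (zero denominator)."""
    num = float(np.sum(abba) - np.sum(baba))
    den = float(np.sum(abba) + np.sum(baba))
    if den == 0:
        return float("nan")
    return num / den


def block_jackknife(
    abba: np.ndarray,
    baba: np.ndarray,
    block_ids: np.ndarray,
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_blocks: int = 10,
) -> DResult:
    """Weighted delete-one block jackknife for D.

    ``block_ids`` assigns each site to a contiguous genomic block.  Blocks
    with zero denominator are dropped.  With fewer than ``min_blocks``
    non-empty blocks the SE is not estimable at a useful resolution and an
    error advises a smaller block size.  When every block has an identical
    D the SE is 0 and Z is flagged infinite.
    """
    abba = np.asarray(abba, float)
    baba = np.asarray(baba, float)
    block_ids = np.asarray(block_ids)
    uniq = np.unique(block_ids)
    b_abba = np.array([abba[block_ids == b].sum() for b in uniq])
    b_baba = np.array([baba[block_ids == b].sum() for b in uniq])
    den = b_abba + b_baba
    keep = den > 0
    b_abba, b_baba, den, uniq = b_abba[keep], b_baba[keep], den[keep], uniq[keep]
    g = len(uniq)
    if g < min_blocks:
        raise ValueError(
            f"only {g} non-empty blocks (< {min_blocks}); use a smaller block size"
        )
    tot_num = float((b_abba - b_baba).sum())
    tot_den = float(den.sum())
    d_hat = tot_num / tot_den
    d_minus = (tot_num - (b_abba - b_baba)) / (tot_den - den)
    d_block = (b_abba - b_baba) / den
    if np.allclose(d_minus, d_hat):
        se, z, p = 0.0, float("inf") if d_hat != 0 else float("nan"), float("nan")
    else:
        # Busing et al. (1999) delete-m_j jackknife with unequal block weights
        h = tot_den / den
        theta_j = g * d_hat - np.sum((1 - den / tot_den) * d_minus)
        pseudo = h * d_hat - (h - 1) * d_minus
        var = np.sum((pseudo - theta_j) ** 2 / (h - 1)) / g
        se = float(np.sqrt(var))
        z = d_hat / se if se > 0 else float("inf")
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    blocks = pd.DataFrame(
        {"block": uniq, "abba": b_abba, "baba": b_baba, "d_block": d_block}
    )
    return DResult(
        d=float(d_hat), se=se, z=float(z), p_value=p,
        n_blocks=g, block_size=block_size, blocks=blocks,
    )


def derived_frequencies(
    gm: GenotypeMatrix, pops: dict[str, list[str]], taxa: tuple[str, str, str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site derived-allele frequencies for (P1, P2, P3, O), plus positions.

    The derived allele is defined relative to the outgroup major allele.
    Sites where any taxon has no observed allele are dropped.
    """
    freqs = []
    calleds = []
    for t in taxa:
        idx = gm.sample_index(pops[t])
        n_alt, n_called = gm.allele_counts(idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs.append(np.where(n_called > 0, n_alt / np.maximum(n_called, 1), np.nan))
        calleds.append(n_called)
    p1, p2, p3, p4 = freqs
    ok = np.all([c > 0 for c in calleds], axis=0)
    # polarise: derived = allele that is minor in the outgroup
    flip = p4 > 0.5
    out = []
    for p in (p1, p2, p3, p4):
        out.append(np.where(flip, 1.0 - p, p)[ok])
    return (*out, gm.positions[ok])


def d_test(
    matrices: list[GenotypeMatrix] | GenotypeMatrix,
    pops: dict[str, list[str]],
    taxa: tuple[str, str, str, str],
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_blocks: int = 10,
) -> DResult:
    """Full D test for taxa = (P1, P2, P3, Outgroup) over one or more scaffolds."""
    if isinstance(matrices, GenotypeMatrix):
        matrices = [matrices]
    abba_all, baba_all, blocks_all = [], [], []
    for si, gm in enumerate(matrices):
        p1, p2, p3, p4, pos = derived_frequencies(gm, pops, taxa)
        abba, baba = site_weights(p1, p2, p3, p4)
        abba_all.append(abba)
        baba_all.append(baba)
        blocks_all.append(si * 10**9 + pos // block_size)
    res = block_jackknife(
        np.concatenate(abba_all), np.concatenate(baba_all), np.concatenate(blocks_all),
        block_size=block_size, min_blocks=min_blocks,
    )
    res.taxa = taxa
    return res


def compare_scenarios(d_blocks_a: np.ndarray, d_blocks_b: np.ndarray):
    """Welch two-sided t-test on per-block |D| values between two scenarios.

    Returns (t, p).  When the pooled values are all identical the test is
    degenerate and p = 1 by the exact-equality shortcut.
    """
    a = np.abs(np.asarray(d_blocks_a, float))
    b = np.abs(np.asarray(d_blocks_b, float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 block values per group")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
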