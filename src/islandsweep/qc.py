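"""Site and genotype quality control for multi-sample VCF data.

Implements the filtering chain applied before any population-genetic
inference: a Phred site-quality floor, per-individual abnormal-depth masking
(with halved bounds on the hemizygous X), collapsing of impossible
heterozygous calls on the male X using allele depths, and a site-level
missingness cap.  All rules use strict inequalities, so boundary values are
retained, and every function returns a new matrix (inputs are not mutated).
"""

from __future__ import annotations

import numpy as np

from .genotypes import MISSING, NO_ALLELE, GenotypeMatrix

DEFAULT_MIN_QUAL = 30.0
DEFAULT_MAX_MISSING = 0.25
AD_SUPERMAJORITY = 3.0  # one allele's depth must exceed 3x the other


def filter_site_quality(m: GenotypeMatrix, min_qual: float = DEFAULT_MIN_QUAL) -> GenotypeMatrix:
    """Drop sites with Phred-scaled quality strictly below ``min_qual``."""
    if m.qual is None:
        raise ValueError(f"{m.scaffold}: no site quality scores available")
    return m.take_sites(~(m.qual < min_qual))


def mask_abnormal_depth(m: GenotypeMatrix) -> GenotypeMatrix:
    """Set calls with abnormal depth to unknown.

    A call is abnormal when its depth is strictly below 1/3 or strictly above
    3x that individual's mean sequencing depth.  On X-linked scaffolds, where
    males carry a single copy, both criteria are halved: bounds become
    [mean/6, 1.5 * mean].
    """
    if m.depth is None:
        return m.copy()
    if m.sample_mean_depth is None:
        raise ValueError(f"{m.scaffold}: per-individual mean depths unknown")
    bad_mean = np.isnan(np.asarray(m.sample_mean_depth, dtype=float))
    if bad_mean.any():
        missing = [s for s, b in zip(m.samples, bad_mean) if b]
        raise ValueError(f"missing mean depth for individual(s): {', '.join(missing)}")
    out = m.copy()
    mean = np.asarray(m.sample_mean_depth, dtype=float)[None, :]
    lo, hi = (mean / 6.0, 1.5 * mean) if m.is_x else (mean / 3.0, 3.0 * mean)
    abnormal = (m.depth < lo) | (m.depth > hi)
    mask3 = abnormal[:, :, None] & (out.alleles != NO_ALLELE)
    out.alleles[mask3] = MISSING
    return out


def fix_x_hemizygote_call(allele_depth: tuple[float, float], call: tuple[int, int]) -> int:
    """Collapse one diploid-coded male X call to a haploid allele.

    Heterozygous calls are resolved by allele depth: the allele whose depth is
    strictly greater than 3x the other wins; otherwise the call becomes
    unknown.  Homozygous calls collapse to their single allele.
    """
    a, b = call
    if a < 0 or b < 0:
        return MISSING
    if a == b:
        return a
    ref_d, alt_d = allele_depth
    if ref_d < 0 or alt_d < 0:
        raise ValueError("negative allele depths")
    if ref_d > AD_SUPERMAJORITY * alt_d:
        return 0
    if alt_d > AD_SUPERMAJORITY * ref_d:
        return 1
    return MISSING


def fix_x_hemizygotes(m: GenotypeMatrix, male_samples: list[str] | None = None) -> GenotypeMatrix:
    """Apply the hemizygote fix to male columns of an X scaffold.

    ``male_samples`` defaults to all diploid-coded columns; columns already
    haploid are untouched (the operation is idempotent).  Heterozygous calls
    without allele depths cannot be adjudicated and become unknown.
    """
    if not m.is_x:
        return m.copy()
    out = m.copy()
    idx = range(m.n_samples) if male_samples is None else m.sample_index(male_samples)
    for j in idx:
        if out.ploidy[j] == 1:
            continue
        for i in range(m.n_sites):
            a, b = int(out.alleles[i, j, 0]), int(out.alleles[i, j, 1])
            if a < 0 or b < 0:
                out.alleles[i, j, 0] = MISSING
            elif a == b:
                out.alleles[i, j, 0] = a
            elif out.allele_depth is None:
                out.alleles[i, j, 0] = MISSING
            else:
                ad = out.allele_depth[i, j]
                out.alleles[i, j, 0] = fix_x_hemizygote_call((float(ad[0]), float(ad[1])), (a, b))
        out.ploidy[j] = 1
        out.alleles[:, j, 1] = NO_ALLELE
    return out


def filter_missingness(m: GenotypeMatrix, max_fraction: float = DEFAULT_MAX_MISSING) -> GenotypeMatrix:
    """Drop sites with unknown genotypes in strictly more than ``max_fraction`` of individuals."""
    unknown = np.any(m.alleles == MISSING, axis=2)  # (n_sites, n_samples)
    frac = unknown.mean(axis=1)
    return m.take_sites(~(frac > max_fraction))


def qc_chain(
    m: GenotypeMatrix,
    male_samples: list[str] | None = None,
    min_qual: float = DEFAULT_MIN_QUAL,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Run the full QC chain; returns the filtered matrix and a removal report."""
    report: dict[str, int] = {}
    n0 = m.n_sites
    m = filter_site_quality(m, min_qual) if m.qual is not None else m.copy()
    report["site_quality"] = n0 - m.n_sites
    m = mask_abnormal_depth(m)
    if m.is_x:
        m = fix_x_hemizygotes(m, male_samples)
    n1 = m.n_sites
    m = filter_missingness(m, max_missing)
    report["missingness"] = n1 - m.n_sites
    return m, report
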