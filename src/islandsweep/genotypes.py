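"""In-memory genotype container and VCF text I/O.

The central substrate for every statistic in this package is a per-scaffold
matrix of allele calls.  Samples may be diploid (autosomes, female X) or
haploid (male X in the XX/XO system, where males carry a single X).  Calls
are stored in a ``(n_sites, n_samples, 2)`` int8 array:

* ``0`` / ``1``  -- reference / alternate allele
* ``MISSING`` (-1) -- unknown call
* ``NO_ALLELE`` (-2) -- the permanently absent second slot of a haploid call

Positions are 1-based, strictly increasing within a scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

MISSING = -1
NO_ALLELE = -2


@dataclass
class GenotypeMatrix:
    """Allele calls for one scaffold.

    Parameters
    ----------
    scaffold : str
        Scaffold name.
    positions : ndarray of int
        1-based site positions, strictly increasing.
    alleles : ndarray of int8, shape (n_sites, n_samples, 2)
        Allele calls (see module docstring for the encoding).
    samples : list of str
        Sample identifiers, one per column.
    ploidy : ndarray of int, shape (n_samples,)
        2 for diploid columns, 1 for haploid (male X) columns.
    is_x : bool
        Whether the scaffold is X-linked.
    qual : ndarray of float, optional
        Per-site Phred-scaled quality score.
    depth : ndarray, shape (n_sites, n_samples), optional
        Per-call sequencing depth.
    allele_depth : ndarray, shape (n_sites, n_samples, 2), optional
        Per-call (ref, alt) allele depths.
    sample_mean_depth : ndarray, shape (n_samples,), optional
        Per-individual mean sequencing depth across the genome.
    length : int, optional
        Scaffold length in bp (defaults to the last position).
    """

    scaffold: str
    positions: np.ndarray
    alleles: np.ndarray
    samples: list[str]
    ploidy: np.ndarray
    is_x: bool = False
    qual: np.ndarray | None = None
    depth: np.ndarray | None = None
    allele_depth: np.ndarray | None = None
    sample_mean_depth: np.ndarray | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_sites, n_samples, 2)")
        if self.alleles.shape[0] != self.positions.shape[0]:
            raise ValueError("positions / alleles length mismatch")
        if self.alleles.shape[1] != len(self.samples):
            raise ValueError("samples / alleles width mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"{self.scaffold}: positions must be strictly increasing")
        if self.length is None:
            self.length = int(self.positions[-1]) if self.n_sites else 0
        # haploid columns never carry a second allele
        hap = self.ploidy == 1
        if hap.any():
            self.alleles[:, hap, 1] = NO_ALLELE

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[1]

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r} on {self.scaffold}") from None

    def allele_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(n_alt, n_called)`` per site over the given sample columns."""
        a = self.alleles if sample_idx is None else self.alleles[:, sample_idx, :]
        called = a >= 0
        n_alt = np.sum(a == 1, axis=(1, 2))
        n_called = np.sum(called, axis=(1, 2))
        return n_alt.astype(np.int64), n_called.astype(np.int64)

    def haplotypes(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Allele-slot matrix (n_sites, n_slots) dropping haploid NO_ALLELE slots."""
        a = self.alleles if sample_idx is None else self.alleles[:, sample_idx, :]
        pl = self.ploidy if sample_idx is None else self.ploidy[sample_idx]
        cols = []
        for j in range(a.shape[1]):
            cols.append(a[:, j, 0])
            if pl[j] == 2:
                cols.append(a[:, j, 1])
        if not cols:
            return np.empty((self.n_sites, 0), dtype=np.int8)
        return np.stack(cols, axis=1)

    def take_sites(self, mask_or_idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            positions=self.positions[idx],
            alleles=self.alleles[idx],
            qual=None if self.qual is None else self.qual[idx],
            depth=None if self.depth is None else self.depth[idx],
            allele_depth=None if self.allele_depth is None else self.allele_depth[idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            positions=self.positions.copy(),
            alleles=self.alleles.copy(),
            qual=None if self.qual is None else self.qual.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            allele_depth=None if self.allele_depth is None else self.allele_depth.copy(),
        )


def _format_call(call: np.ndarray, pl: int, ad: np.ndarray | None, dp) -> str:
    if pl == 1:
        gt = "." if call[0] < 0 else str(int(call[0]))
    else:
        gt = "/".join("." if a < 0 else str(int(a)) for a in call)
    parts = [gt]
    if dp is not None:
        parts.append(str(int(dp)))
    if ad is not None:
        parts.append(f"{int(ad[0])},{int(ad[1])}")
    return ":".join(parts)


def write_vcf(matrices: Iterable[GenotypeMatrix], path, metadata=None) -> None:
    """Write scaffolds to a VCF v4.2 text file.

    All matrices must share the same sample list.  X scaffolds are flagged in
    the contig header lines (``linkage=X``).  REF/ALT are written as A/T
    placeholders: every statistic downstream is symbol-agnostic.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no scaffolds to write")
    samples = matrices[0].samples
    for m in matrices:
        if m.samples != samples:
            raise ValueError("all scaffolds must share one sample list")
    has_dp = all(m.depth is not None for m in matrices)
    has_ad = all(m.allele_depth is not None for m in matrices)
    fmt = "GT" + (":DP" if has_dp else "") + (":AD" if has_ad else "")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=islandsweep\n")
        for m in matrices:
            linkage = "X" if m.is_x else "autosome"
            fh.write(f"##contig=<ID={m.scaffold},length={m.length},linkage={linkage}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_ad:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for m in matrices:
            for i in range(m.n_sites):
                qual = "." if m.qual is None else f"{m.qual[i]:g}"
                calls = [
                    _format_call(
                        m.alleles[i, j],
                        int(m.ploidy[j]),
                        m.allele_depth[i, j] if has_ad else None,
                        m.depth[i, j] if has_dp else None,
                    )
                    for j in range(m.n_samples)
                ]
                fh.write(
                    f"{m.scaffold}\t{int(m.positions[i])}\t.\tA\tT\t{qual}\t.\t.\t{fmt}\t"
                    + "\t".join(calls)
                    + "\n"
                )


def read_vcf(path, sample_mean_depth: dict[str, float] | None = None) -> list[GenotypeMatrix]:
    """Read a VCF into per-scaffold :class:`GenotypeMatrix` objects.

    Haploidy is inferred per sample per scaffold from the GT shape; scaffolds
    whose contig header carries ``linkage=X`` are flagged X-linked.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    x_flags: dict[str, bool] = {}
    lengths: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            body = line.split("<", 1)[1].rstrip(">")
            kv = dict(item.split("=", 1) for item in body.split(","))
            x_flags[kv["ID"]] = kv.get("linkage") == "X"
            if "length" in kv:
                lengths[kv["ID"]] = int(kv["length"])

    per_scaffold: dict[str, dict[str, list]] = {}
    for var in vcf:
        rec = per_scaffold.setdefault(
            var.CHROM, {"pos": [], "gt": [], "qual": [], "dp": [], "ad": []}
        )
        rec["pos"].append(var.POS)
        arr = np.asarray(var.genotype.array())  # last column is the phased flag
        gts = arr[:, : arr.shape[1] - 1]  # (n_samples, 1 or 2); -1 missing, -2 absent
        if gts.shape[1] == 1:  # all-haploid record
            gts = np.concatenate(
                [gts, np.full_like(gts, NO_ALLELE)], axis=1
            )
        rec["gt"].append(gts)
        rec["qual"].append(var.QUAL if var.QUAL is not None else np.nan)
        try:
            rec["dp"].append(var.format("DP")[:, 0])
        except (KeyError, TypeError):
            rec["dp"].append(None)
        try:
            rec["ad"].append(var.format("AD"))
        except (KeyError, TypeError):
            rec["ad"].append(None)

    out = []
    for scaffold, rec in per_scaffold.items():
        gt = np.stack(rec["gt"]).astype(np.int8)  # (n_sites, n_samples, 2)
        ploidy = np.where(np.all(gt[:, :, 1] == NO_ALLELE, axis=0), 1, 2).astype(np.int8)
        dp = None
        if all(d is not None for d in rec["dp"]):
            dp = np.stack(rec["dp"]).astype(np.float64)
        ad = None
        if all(a is not None for a in rec["ad"]):
            ad = np.stack(rec["ad"]).astype(np.int64)
        smd = None
        if sample_mean_depth is not None:
            smd = np.array([sample_mean_depth[s] for s in samples], dtype=float)
        elif dp is not None:
            smd = np.nanmean(dp, axis=0)
        out.append(
            GenotypeMatrix(
                scaffold=scaffold,
                positions=np.array(rec["pos"], dtype=np.int64),
                alleles=gt,
                samples=samples,
                ploidy=ploidy,
                is_x=x_flags.get(scaffold, False),
                qual=np.array(rec["qual"], dtype=float),
                depth=dp,
                allele_depth=ad,
                sample_mean_depth=smd,
                length=lengths.get(scaffold),
            )
        )
    return out
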