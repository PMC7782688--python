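"""Apply the variant QC chain to each simulated dataset.

Filters: Phred quality < 30, abnormal per-individual depth (1/3x-3x of the
individual mean, halved bounds on the hemizygous male X), impossible male-X
heterozygotes resolved by allele depth, and >25% missingness.  Writes
results/qc/<scenario>/qc.vcf plus a per-rule removal report.
"""

from pathlib import Path

import pandas as pd

from islandsweep import qc
from islandsweep.genotypes import read_vcf, write_vcf

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for scenario in ("parallel", "introgression", "no_geneflow"):
        indir = ROOT / "datasets" / scenario
        meta = pd.read_csv(indir / "samples.tsv", sep="\t")
        males = list(meta[meta["sex"] == "male"]["id"])
        matrices = read_vcf(indir / "genotypes.vcf")
        out, rows = [], []
        for m in matrices:
            mm, rep = qc.qc_chain(m, males)
            out.append(mm)
            for rule, removed in rep.items():
                rows.append({"scaffold": m.scaffold, "rule": rule, "removed": removed})
        outdir = ROOT / "qc" / scenario
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(out, outdir / "qc.vcf")
        report = pd.DataFrame(rows)
        report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        total_in = sum(m.n_sites for m in matrices)
        removed = int(report["removed"].sum())
        print(f"{scenario}: removed {removed}/{total_in} sites "
              f"({100 * removed / total_in:.2f}%) -> {outdir / 'qc.vcf'}")


if __name__ == "__main__":
    main()
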