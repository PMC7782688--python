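"""Per-island case/control association and cross-island harmonisation.

Each island's flatwing males are tested against normal-wing controls
(within-island for the polymorphic islands; the fixed island uses the
pooled-control design).  The strictest criterion — the reference island's
Bonferroni-corrected raw-p cutoff — harmonises the three runs, and the Venn
overlap of the harmonised sets distinguishes shared-mutation from
parallel-mutation architectures.
"""

import json
from pathlib import Path

import pandas as pd

from islandsweep import assoc
from islandsweep.genotypes import read_vcf

ROOT = Path(__file__).resolve().parents[1] / "results"
ISLANDS = ("kauai", "oahu", "hilo")


def main() -> None:
    for scenario in ("parallel", "introgression"):
        matrices = [m for m in read_vcf(ROOT / "qc" / scenario / "qc.vcf") if m.is_x]
        meta = pd.read_csv(ROOT / "datasets" / scenario / "samples.tsv", sep="\t")

        def members(deme, morph=None):
            sel = meta["deme"] == deme
            if morph:
                sel &= meta["morph"] == morph
            return list(meta[sel]["id"])

        all_normals = [s for d in ISLANDS for s in members(d, "normal")]
        tables = {}
        for d in ISLANDS:
            controls = members(d, "normal") if d != "kauai" else all_normals
            tables[d] = assoc.gwas(matrices, members(d, "flatwing"), controls,
                                   population=d)
        harmonised = assoc.strictest_criterion(tables, "oahu")
        sets = {p: assoc.significant_sites(t) for p, t in harmonised.items()}
        venn = assoc.overlap(sets)
        outdir = ROOT / "association" / scenario
        outdir.mkdir(parents=True, exist_ok=True)
        pd.concat(tables.values()).to_csv(outdir / "assoc.tsv", sep="\t", index=False)
        with open(outdir / "venn.json", "w") as fh:
            json.dump(venn, fh, indent=2)
        print(f"{scenario}: per-island significant "
              f"{ {p: len(s) for p, s in sets.items()} }; "
              f"shared SNPs={venn['snp']['all']}, "
              f"shared scaffolds={venn['scaffold']['all']}")


if __name__ == "__main__":
    main()
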