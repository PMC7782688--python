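"""Tree-based introgression test and the net-divergence contrast.

Builds the bootstrap NJ tree over the harmonised candidate-SNP sites shared
by all three islands, asks whether flatwing individuals form one clade, and
contrasts net divergence d (and dxy) between the two wild-flatwing islands
inside versus outside the trait-associated regions with a 1000-draw
randomisation null.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from islandsweep import parallelism, winstats
from islandsweep.genotypes import read_vcf

ROOT = Path(__file__).resolve().parents[1] / "results"
ISLANDS = ("kauai", "oahu", "hilo")
FLANK = 1_000


def main() -> None:
    for scenario in ("parallel", "introgression"):
        matrices = [m for m in read_vcf(ROOT / "qc" / scenario / "qc.vcf") if m.is_x]
        meta = pd.read_csv(ROOT / "datasets" / scenario / "samples.tsv", sep="\t")
        a = pd.read_csv(ROOT / "association" / scenario / "assoc.tsv", sep="\t")
        with open(ROOT / "association" / scenario / "venn.json") as fh:
            json.load(fh)  # provenance check only
        sig = a[a["significant"]]
        shared = set.intersection(
            *[set(sig[sig.population == p]["scaffold"]) for p in ISLANDS]
        )
        snps = sorted(
            {(r.scaffold, int(r.position)) for r in sig.itertuples()
             if r.scaffold in shared}
        )
        island_males = list(meta[meta["deme"].isin(ISLANDS)]["id"])
        masks = {
            m.scaffold: np.isin(
                m.positions, [p for sc, p in snps if sc == m.scaffold]
            )
            for m in matrices
        }
        tree, support = parallelism.bootstrap_consensus(
            matrices, island_males, n_bootstrap=100, seed=1, site_masks=masks
        )
        verdict = parallelism.flatwing_clustering_test(
            tree, dict(zip(meta["id"], meta["morph"])), support
        )
        outdir = ROOT / "parallelism" / scenario
        outdir.mkdir(parents=True, exist_ok=True)
        tree.write(str(outdir / "flatwing_tree.nwk"))
        print(f"{scenario}: flatwing monophyletic={verdict.monophyletic} "
              f"(support {verdict.support}), mixing score={verdict.mixing_score}")

        pops = {
            "kauai_fw": list(meta[(meta.deme == "kauai") & (meta.morph == "flatwing")]["id"]),
            "oahu_fw": list(meta[(meta.deme == "oahu") & (meta.morph == "flatwing")]["id"]),
        }
        w = winstats.window_stats(
            matrices, pops, pairs=[("kauai_fw", "oahu_fw")],
        )
        ko_snps = [
            (r.scaffold, int(r.position)) for r in sig.itertuples()
            if r.population in ("kauai", "oahu")
        ]
        mask = np.zeros(len(w), bool)
        for sc, pos in ko_snps:
            mask |= ((w.scaffold == sc) & (w.start <= pos + FLANK)
                     & (w.end >= pos - FLANK)).to_numpy()
        res = parallelism.region_divergence_contrast(
            w, mask, columns=("d_kauai_fw_oahu_fw", "dxy_kauai_fw_oahu_fw"), seed=1
        )
        for col, r in res.items():
            stat = "d" if col.startswith("d_") else "dxy"
            print(f"  {stat}: inside-outside={r.observed_diff:+.2e}, "
                  f"randomisation p={r.p_empirical:.3g}, t-test p={r.p_ttest:.3g}")
        pd.DataFrame(
            [{"statistic": c, "observed_diff": r.observed_diff,
              "p_empirical": r.p_empirical, "p_ttest": r.p_ttest,
              "n_inside": r.n_inside, "n_outside": r.n_outside}
             for c, r in res.items()]
        ).to_csv(outdir / "divergence_contrast.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
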