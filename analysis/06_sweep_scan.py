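"""Joint-percentile selective-sweep scan on the parallel scenario.

Windowed pi, Fst and the diversity log-ratio between the swept island's
flatwing males (selected) and the non-parasitised mainland males
(unselected); windows in the top 5% of both Fst and the log-ratio merge
into candidate sweep regions, annotated with the trait-associated SNPs
they contain.
"""

from pathlib import Path

import pandas as pd

from islandsweep import sweep, winstats
from islandsweep.genotypes import read_vcf

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scenario = "parallel"
    matrices = [m for m in read_vcf(ROOT / "qc" / scenario / "qc.vcf") if m.is_x]
    meta = pd.read_csv(ROOT / "datasets" / scenario / "samples.tsv", sep="\t")
    pops = {
        "kauai_fw": list(meta[(meta.deme == "kauai") & (meta.morph == "flatwing")]["id"]),
        "australia": list(meta[meta.deme == "australia"]["id"]),
    }
    w = winstats.window_stats(
        matrices, pops, pairs=[("kauai_fw", "australia")],
        ratio_pair=("australia", "kauai_fw"),
    )
    regions = sweep.call_sweeps(
        w, q=0.95, fst_col="fst_kauai_fw_australia", ratio_col="pi_log_ratio"
    )
    a = pd.read_csv(ROOT / "association" / scenario / "assoc.tsv", sep="\t")
    sig = a[a["significant"]]
    snps = sorted({(r.scaffold, int(r.position)) for r in sig.itertuples()})
    sweep.annotate_regions(regions, snps)
    outdir = ROOT / "sweep_scan"
    outdir.mkdir(parents=True, exist_ok=True)
    w.to_csv(outdir / "windows.tsv", sep="\t", index=False)
    sweep.regions_to_frame(regions).to_csv(outdir / "regions.tsv", sep="\t", index=False)
    sweep.regions_to_bed(regions).to_csv(
        outdir / "regions.bed", sep="\t", index=False, header=False
    )
    print(f"{len(w)} windows -> {len(regions)} sweep regions")
    for r in regions:
        print(f"  {r.scaffold}:{r.start}-{r.end}  mean Fst={r.mean_fst:.2f}, "
              f"mean log-ratio={r.mean_pi_log_ratio:.2f}, "
              f"{len(r.contained_snps)} associated SNPs inside")


if __name__ == "__main__":
    main()
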