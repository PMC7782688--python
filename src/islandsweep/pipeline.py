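"""End-to-end orchestration: simulate (or load) -> QC -> gene flow ->
association -> parallelism -> sweep scan -> CNV, with one summary verdict.

The summary's headline fields answer the questions the island system poses:

* ``gene_flow_detected`` — does the ABBA-BABA test reject D = 0 among the
  three islands?
* ``shared_snps`` / ``shared_scaffolds`` — after harmonising the three
  per-island association runs with the strictest criterion, how many
  trait-associated SNPs (and scaffolds) are shared by all three islands?
* ``flatwing_monophyletic`` — do trait-carrier individuals from different
  islands form one clade at trait-associated loci?
* ``d_contrast_p`` — is net divergence between islands elevated at
  trait-associated regions relative to the X background?
* ``sweep_regions_n`` — how many joint-percentile sweep regions are called?

Under parallel evolution with gene flow the expected verdict vector is
(True, 0, >=1, False, <0.05, >=1); adaptive introgression flips the SNP
sharing and monophyly answers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import cnv as cnv_mod
from . import dstat as dstat_mod
from . import parallelism as par_mod
from . import simdata
from . import sweep as sweep_mod
from . import winstats
from .genotypes import read_vcf, write_vcf
from .qc import qc_chain

ALL_STAGES = ("simulate", "qc", "dstat", "assoc", "winstats", "trees", "contrast", "sweep", "cnv")


@dataclass
class RunConfig:
    scenario: str | None = "parallel"
    vcf_path: str | None = None
    meta_path: str | None = None
    outdir: str = "islandsweep_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    window_size: int = 10_000
    window_step: int = 2_500
    block_size: int = 25_000
    sweep_q: float = 0.95
    n_bootstrap: int = 100
    n_randomizations: int = 1_000
    assoc_flank: int = 1_000
    min_qual: float = 30.0
    max_missing: float = 0.25
    sim_overrides: dict = field(default_factory=dict)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of unmet preconditions (empty = valid); runs nothing."""
    problems = []
    if config.window_step > config.window_size:
        problems.append("window step exceeds window size")
    if config.scenario is None and "simulate" in config.stages:
        problems.append("simulate stage enabled but no scenario named")
    if config.scenario is not None and config.scenario not in simdata.SCENARIOS:
        problems.append(f"unknown scenario {config.scenario!r}")
    if config.scenario is None and (config.vcf_path is None or config.meta_path is None):
        problems.append("no simulation scenario and no VCF/metadata paths supplied")
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        problems.append(f"unknown stages: {sorted(unknown)}")
    if not 0 < config.sweep_q < 1:
        problems.append("sweep percentile q must lie in (0, 1)")
    return problems


def _snp_flank_mask(gm, snps, flank):
    mask = np.zeros(gm.n_sites, dtype=bool)
    for sc, pos in snps:
        if sc == gm.scaffold:
            mask |= (gm.positions >= pos - flank) & (gm.positions <= pos + flank)
    return mask


def run(config: RunConfig, dataset: simdata.SimulatedDataset | None = None) -> dict:
    """Execute the configured stages; returns (and writes) the summary dict.

    ``dataset`` short-circuits the simulate stage with a pre-built dataset
    (used by callers that want to reuse one simulation across analyses).
    Identical config and seed give an identical summary.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {s: int(np.random.default_rng(child).integers(1, 2**31 - 1))
                  for s, child in zip(ALL_STAGES, ss.spawn(len(ALL_STAGES)))}
    summary: dict = {"scenario": config.scenario, "seed": config.seed, "stages": {}}

    def stage_enabled(name):
        return name in config.stages

    current_stage = "inputs"
    try:
        # ----- inputs -------------------------------------------------
        if dataset is None and stage_enabled("simulate") and config.scenario is not None:
            cfg = simdata.make_scenario(config.scenario)
            for k, v in config.sim_overrides.items():
                setattr(cfg, k, v)
            dataset = simdata.simulate_demography(cfg, seed=stage_seed["simulate"])
            simdata.write_dataset(dataset, outdir / "simulated")
        elif dataset is None:
            matrices = read_vcf(config.vcf_path)
            metadata = pd.read_csv(config.meta_path, sep="\t")
            truth = simdata.Truth(
                pd.DataFrame(columns=["deme", "scaffold", "position", "origin_deme"]),
                pd.DataFrame(), pd.DataFrame(), pd.DataFrame(),
            )
            dataset = simdata.SimulatedDataset(None, matrices, metadata, truth)
        md = dataset.metadata
        islands = [d for d in simdata.ISLANDS if (md["deme"] == d).any()]

        # ----- QC -----------------------------------------------------
        current_stage = "qc"
        if stage_enabled("qc"):
            males = list(md[md["sex"] == "male"]["id"])
            matrices = []
            report_rows = []
            for m in dataset.matrices:
                mm, rep = qc_chain(m, males, config.min_qual, config.max_missing)
                matrices.append(mm)
                for rule, removed in rep.items():
                    report_rows.append({"scaffold": m.scaffold, "rule": rule, "removed": removed})
            pd.DataFrame(report_rows).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
            write_vcf(matrices, outdir / "qc.vcf")
            summary["stages"]["qc"] = {
                "sites_removed": int(sum(r["removed"] for r in report_rows))
            }
        else:
            matrices = dataset.matrices
        x_mats = [m for m in matrices if m.is_x]
        pops_all = {d: dataset.samples_where(deme=d) for d in md["deme"].unique()}

        # ----- gene flow ---------------------------------------------
        current_stage = "dstat"
        if (
            stage_enabled("dstat") and len(islands) == 3
            and (md["deme"] == "outgroup").any() and (md["deme"] == "australia").any()
        ):
            # The only ((P1,P2),P3) arrangement the population tree allows
            # uses the island sister pair as (P1,P2).  With P3 the third
            # island, unequal pair migration rates leave an ABBA/BABA excess;
            # with P3 the distant conspecific (no recent island contact) the
            # same test is a negative control, and the per-block |D| contrast
            # between the two is the island-vs-distant scenario t-test.
            island_taxa = ("kauai", "hilo", "oahu", "outgroup")
            control_taxa = ("kauai", "hilo", "australia", "outgroup")
            d_rows = []
            results = {}
            for taxa in (island_taxa, control_taxa):
                res = dstat_mod.d_test(
                    matrices, pops_all, taxa, block_size=config.block_size
                )
                results[taxa] = res
                d_rows.append(
                    {"p1": taxa[0], "p2": taxa[1], "p3": taxa[2], "outgroup": taxa[3],
                     "d": res.d, "se": res.se, "z": res.z, "p": res.p_value,
                     "n_blocks": res.n_blocks}
                )
            pd.DataFrame(d_rows).to_csv(outdir / "dstat.tsv", sep="\t", index=False)
            z_island = results[island_taxa].z
            t_stat, t_p = dstat_mod.compare_scenarios(
                results[island_taxa].blocks["d_block"],
                results[control_taxa].blocks["d_block"],
            )
            summary["gene_flow_detected"] = bool(
                np.isfinite(z_island) and abs(z_island) > 3
            )
            summary["stages"]["dstat"] = {
                "tests": d_rows, "scenario_t": t_stat, "scenario_t_p": t_p,
            }

        # ----- association -------------------------------------------
        current_stage = "assoc"
        harmonised = None
        if stage_enabled("assoc"):
            tables = {}
            all_normals = [
                s for d in islands for s in dataset.samples_where(deme=d, morph="normal")
            ]
            for d in islands:
                cases = dataset.samples_where(deme=d, morph="flatwing")
                own_controls = dataset.samples_where(deme=d, morph="normal")
                # fixed-morph demes fall back to the pooled-control design
                controls = own_controls if d != "kauai" else all_normals
                if len(cases) < 2 or len(controls) < 2:
                    continue
                tables[d] = assoc_mod.gwas(x_mats or matrices, cases, controls, population=d)
            if len(tables) == 3:
                ref = "oahu" if "oahu" in tables else sorted(tables)[0]
                harmonised = assoc_mod.strictest_criterion(tables, ref)
                sets = {p: assoc_mod.significant_sites(t) for p, t in harmonised.items()}
                venn = assoc_mod.overlap(sets)
                summary["shared_snps"] = venn["snp"]["all"]
                summary["shared_scaffolds"] = venn["scaffold"]["all"]
                summary["stages"]["assoc"] = {
                    "n_significant": {p: int(len(s)) for p, s in sets.items()},
                    "reference": ref,
                    "venn": venn,
                }
                pd.concat(tables.values()).to_csv(
                    outdir / "assoc.tsv", sep="\t", index=False
                )

        # ----- window statistics -------------------------------------
        current_stage = "winstats"
        win_table = None
        if stage_enabled("winstats") and x_mats:
            popmap = {}
            for d in islands:
                fw = dataset.samples_where(deme=d, morph="flatwing")
                if fw:
                    popmap[f"{d}_fw"] = fw
            if (md["deme"] == "australia").any():
                popmap["australia"] = dataset.samples_where(deme="australia")
            spec = winstats.WindowSpec(
                size=config.window_size, step=config.window_step,
                lengths={m.scaffold: int(m.length) for m in x_mats},
            )
            pairs = []
            if "kauai_fw" in popmap and "australia" in popmap:
                pairs.append(("kauai_fw", "australia"))
            if "kauai_fw" in popmap and "oahu_fw" in popmap:
                pairs.append(("kauai_fw", "oahu_fw"))
            ratio_pair = (
                ("australia", "kauai_fw")
                if {"australia", "kauai_fw"} <= set(popmap) else None
            )
            win_table = winstats.window_stats(
                x_mats, popmap, spec, pairs=pairs, ratio_pair=ratio_pair
            )
            win_table.to_csv(outdir / "windows.tsv", sep="\t", index=False)
            summary["stages"]["winstats"] = {"n_windows": int(len(win_table))}

        # sites associated with the trait, for trees and the contrast mask
        assoc_snps = (
            sorted(set().union(*[assoc_mod.significant_sites(t) for t in harmonised.values()]))
            if harmonised else []
        )
        # the clustering verdict uses SNPs on scaffolds associated in every
        # population: population-private scaffolds reflect within-island
        # founder structure, not the shared trait architecture
        if harmonised:
            per_pop_scaffolds = [
                {s for s, _ in assoc_mod.significant_sites(t)} for t in harmonised.values()
            ]
            shared_scaffolds = set.intersection(*per_pop_scaffolds)
            tree_snps = [sp for sp in assoc_snps if sp[0] in shared_scaffolds] or assoc_snps
            # the divergence contrast compares the two populations with wild
            # trait carriers, at the regions associated in those populations
            contrast_pops = [p for p in ("kauai", "oahu") if p in harmonised]
            contrast_snps = sorted(
                set().union(
                    *[assoc_mod.significant_sites(harmonised[p]) for p in contrast_pops]
                )
            ) if contrast_pops else assoc_snps
        else:
            tree_snps = contrast_snps = assoc_snps

        # ----- trees --------------------------------------------------
        current_stage = "trees"
        if stage_enabled("trees") and tree_snps and x_mats:
            island_males = [s for d in islands for s in pops_all[d]]
            # verdict tree over the combined candidate-SNP positions
            # themselves: flanking sites carry island background ancestry,
            # which swamps the trait signal at desk scale
            tree_pos = {sc: {p for s2, p in tree_snps if s2 == sc} for sc in
                        {s2 for s2, _ in tree_snps}}
            masks = {
                m.scaffold: np.isin(
                    m.positions, sorted(tree_pos.get(m.scaffold, ()))
                )
                for m in x_mats
            }
            if sum(int(v.sum()) for v in masks.values()) >= 3:
                tree, support = par_mod.bootstrap_consensus(
                    x_mats, island_males, n_bootstrap=config.n_bootstrap,
                    seed=stage_seed["trees"], site_masks=masks,
                )
                morph_of = dict(zip(md["id"], md["morph"]))
                verdict = par_mod.flatwing_clustering_test(tree, morph_of, support)
                tree.write(str(outdir / "flatwing_regions.nwk"))
                summary["flatwing_monophyletic"] = verdict.monophyletic
                summary["stages"]["trees"] = {
                    "monophyletic": verdict.monophyletic,
                    "support": verdict.support,
                    "mixing_score": verdict.mixing_score,
                    "introgression_consistent": verdict.introgression_consistent,
                }

        # ----- divergence contrast -----------------------------------
        current_stage = "contrast"
        if (
            stage_enabled("contrast") and win_table is not None and contrast_snps
            and "d_kauai_fw_oahu_fw" in win_table
        ):
            mask = np.zeros(len(win_table), dtype=bool)
            for sc, pos in contrast_snps:
                mask |= (
                    (win_table["scaffold"] == sc)
                    & (win_table["start"] <= pos + config.assoc_flank)
                    & (win_table["end"] >= pos - config.assoc_flank)
                ).to_numpy()
            if 10 <= mask.sum() <= len(win_table) - 10:
                contrasts = par_mod.region_divergence_contrast(
                    win_table, mask,
                    columns=("d_kauai_fw_oahu_fw", "dxy_kauai_fw_oahu_fw"),
                    n_randomizations=config.n_randomizations,
                    seed=stage_seed["contrast"],
                )
                d_res = contrasts["d_kauai_fw_oahu_fw"]
                summary["d_contrast_p"] = d_res.p_empirical
                summary["stages"]["contrast"] = {
                    c: dataclasses.asdict(r) for c, r in contrasts.items()
                }

        # ----- sweep scan --------------------------------------------
        current_stage = "sweep"
        if (
            stage_enabled("sweep") and win_table is not None
            and "fst_kauai_fw_australia" in win_table and "pi_log_ratio" in win_table
        ):
            regions = sweep_mod.call_sweeps(
                win_table, q=config.sweep_q,
                fst_col="fst_kauai_fw_australia", ratio_col="pi_log_ratio",
            )
            sweep_mod.annotate_regions(regions, assoc_snps)
            sweep_mod.regions_to_frame(regions).to_csv(
                outdir / "sweep_regions.tsv", sep="\t", index=False
            )
            summary["sweep_regions_n"] = len(regions)
            causal = set(dataset.truth.causal_loci["scaffold"]) if len(
                dataset.truth.causal_loci
            ) else set()
            summary["stages"]["sweep"] = {
                "n_regions": len(regions),
                "causal_scaffold_called": bool(
                    causal & {r.scaffold for r in regions}
                ),
                "snps_in_regions": int(sum(len(r.contained_snps) for r in regions)),
            }

        # ----- CNV ----------------------------------------------------
        current_stage = "cnv"
        if stage_enabled("cnv") and dataset.cnv_calls is not None and len(dataset.cnv_calls):
            cohort = [
                s for s in md[md["deme"] != "outgroup"]["id"]
            ]
            cnvrs = cnv_mod.merge_cnvrs(dataset.cnv_calls, all_individuals=cohort)
            kauai = md[md["deme"] == "kauai"]
            groups = dict(zip(kauai["id"], kauai["morph"]))
            k_fw = (kauai["morph"] == "flatwing").sum()
            k_nw = (kauai["morph"] == "normal").sum()
            if cnvrs and k_fw >= 2 and k_nw >= 2:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    cnv_mod.differentiated_cnvrs(cnvrs, groups, "flatwing", "normal")
                cnv_mod.cnvrs_to_frame(cnvrs).to_csv(
                    outdir / "cnvrs.tsv", sep="\t", index=False
                )
                summary["stages"]["cnv"] = {
                    "n_cnvrs": len(cnvrs),
                    "n_differentiated": int(sum(r.differentiated for r in cnvrs)),
                }
    except Exception as exc:  # pragma: no cover - error surface
        raise RuntimeError(
            f"pipeline stage {current_stage!r} failed: {exc}"
        ) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
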