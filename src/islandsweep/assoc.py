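"""Case/control association for an X-linked, male-limited trait.

Per site, carrier (case) and non-carrier (control) allele counts form a 2x2
table tested with Fisher's exact test (two-sided); p-values are
Bonferroni-adjusted within each run.  X-linked sites in hemizygous males
contribute one allele each (females, if present, two).  Cross-population
harmonisation applies the reference run's Bonferroni-corrected raw-p cutoff
(0.05 / n_tests_reference) to every population — the "strictest criterion" —
so significance is comparable across runs with different test counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

ALPHA = 0.05


def fisher_site(case_ref: int, case_alt: int, control_ref: int, control_alt: int) -> float:
    """Two-sided Fisher exact p for one site's 2x2 allele-count table.

    An empty margin (no observed alleles in a group, or a monomorphic table)
    carries no association information: p = 1.
    """
    table = np.array([[case_ref, case_alt], [control_ref, control_alt]])
    if table.min() < 0:
        raise ValueError("negative counts")
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def gwas(
    matrices: list[GenotypeMatrix] | GenotypeMatrix,
    case_samples: list[str],
    control_samples: list[str],
    population: str = "",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-site Fisher association between case and control allele counts.

    Sites monomorphic across the combined case+control alleles are skipped
    and do not count toward the Bonferroni test number.  Returns one row per
    tested site with raw p, Bonferroni-adjusted p, and a significance flag
    (adjusted p < alpha).
    """
    if isinstance(matrices, GenotypeMatrix):
        matrices = [matrices]
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    rows = []
    for gm in matrices:
        ci = gm.sample_index(case_samples)
        ki = gm.sample_index(control_samples)
        case_alt, case_n = gm.allele_counts(ci)
        ctrl_alt, ctrl_n = gm.allele_counts(ki)
        tot_alt = case_alt + ctrl_alt
        tot_n = case_n + ctrl_n
        poly = (tot_alt > 0) & (tot_alt < tot_n) & (case_n > 0) & (ctrl_n > 0)
        for i in np.flatnonzero(poly):
            p = fisher_site(
                int(case_n[i] - case_alt[i]), int(case_alt[i]),
                int(ctrl_n[i] - ctrl_alt[i]), int(ctrl_alt[i]),
            )
            rows.append(
                {
                    "scaffold": gm.scaffold,
                    "position": int(gm.positions[i]),
                    "case_ref": int(case_n[i] - case_alt[i]),
                    "case_alt": int(case_alt[i]),
                    "control_ref": int(ctrl_n[i] - ctrl_alt[i]),
                    "control_alt": int(ctrl_alt[i]),
                    "p": p,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["scaffold", "position", "case_ref", "case_alt",
                 "control_ref", "control_alt", "p"],
    )
    n_tests = len(table)
    table["p_bonferroni"] = np.minimum(1.0, table["p"] * n_tests)
    table["significant"] = table["p_bonferroni"] < alpha
    table["population"] = population
    table.attrs["n_tests"] = n_tests
    return table


def strictest_criterion(
    tables: dict[str, pd.DataFrame], reference_pop: str, alpha: float = ALPHA
) -> dict[str, pd.DataFrame]:
    """Harmonise significant sets using the reference run's corrected cutoff.

    The reference population's Bonferroni-corrected raw-p cutoff
    (alpha / n_tests_reference) is applied to the raw p-values of every
    population; only sites at or below it are retained.  With each
    population as its own reference this reduces to per-population
    Bonferroni.
    """
    ref = tables[reference_pop]
    n_ref = ref.attrs.get("n_tests", len(ref))
    if n_ref == 0:
        raise ValueError(f"reference table {reference_pop!r} is empty")
    cutoff = alpha / n_ref
    out = {}
    for pop, t in tables.items():
        kept = t[t["p"] <= cutoff].copy()
        kept.attrs["cutoff"] = cutoff
        out[pop] = kept
    return out


def _venn3(sets: dict[str, set]) -> dict[str, int]:
    (la, a), (lb, b), (lc, c) = sets.items()
    return {
        f"{la}_only": len(a - b - c),
        f"{lb}_only": len(b - a - c),
        f"{lc}_only": len(c - a - b),
        f"{la}_{lb}": len((a & b) - c),
        f"{la}_{lc}": len((a & c) - b),
        f"{lb}_{lc}": len((b & c) - a),
        "all": len(a & b & c),
    }


def overlap(
    site_sets: dict[str, set[tuple[str, int]]]
) -> dict[str, dict[str, int]]:
    """Venn counts (all 7 regions) at SNP and scaffold granularity.

    ``site_sets`` maps population -> set of (scaffold, position) keys.
    """
    if len(site_sets) != 3:
        raise ValueError("overlap expects exactly three populations")
    scaffold_sets = {p: {s for s, _ in sites} for p, sites in site_sets.items()}
    return {"snp": _venn3(site_sets), "scaffold": _venn3(scaffold_sets)}


def significant_sites(table: pd.DataFrame) -> set[tuple[str, int]]:
    sig = table[table["significant"]] if "significant" in table else table
    return set(zip(sig["scaffold"], sig["position"]))
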