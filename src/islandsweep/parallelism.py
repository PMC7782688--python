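"""Introgression-vs-parallel-origin tests.

Two instruments distinguish a single introgressed adaptive allele from
independent mutational origins:

* Trees: identity-by-state distances over trait-associated sites, a
  neighbour-joining tree with bootstrap supports, and a clustering verdict —
  under recent introgression all trait-carrying individuals should form one
  well-supported clade irrespective of island; under parallel origin they
  cluster by island instead.  A Fitch parsimony score on the morph character
  quantifies morph mixing on the tree.
* Divergence contrast: under very recent introgression the trait-associated
  regions should be *less* diverged between islands than the chromosomal
  background; under parallel sweeps net divergence d = dxy - (dx+dy)/2 is
  instead elevated in those regions (each island fixes its own haplotype,
  depressing within-island diversity while absolute divergence is
  unchanged).  Significance comes from randomising the region labels over
  windows, by default with a rotation (block) scheme that preserves the
  autocorrelation of overlapping windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import majority_rule, nj

from .genotypes import GenotypeMatrix


# ---------------------------------------------------------------------------
# identity-by-state distances
# ---------------------------------------------------------------------------

def ibs_distance(
    matrices: list[GenotypeMatrix] | GenotypeMatrix,
    samples: list[str] | None = None,
    site_masks: dict[str, np.ndarray] | None = None,
) -> DistanceMatrix:
    """1 - identity-by-state over a site set, with pairwise deletion.

    The distance between two individuals is the fraction of co-called
    alleles (allele-slot-wise) that mismatch.  A pair with zero co-called
    sites is an error.
    """
    if isinstance(matrices, GenotypeMatrix):
        matrices = [matrices]
    if samples is None:
        samples = matrices[0].samples
    if len(samples) < 2:
        raise ValueError("need at least 2 individuals")
    dosages = []
    for gm in matrices:
        d = _dosage_matrix(gm, samples)
        if site_masks is not None and gm.scaffold in site_masks:
            d = d[site_masks[gm.scaffold]]
        dosages.append(d)
    D = np.concatenate(dosages, axis=0)  # (n_sites, n_ind); NaN = missing
    n = len(samples)
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ok = ~np.isnan(D[:, a]) & ~np.isnan(D[:, b])
            tot = int(ok.sum())
            if tot == 0:
                raise ValueError(
                    f"no co-called sites for pair ({samples[a]}, {samples[b]})"
                )
            dist[a, b] = dist[b, a] = float(np.abs(D[ok, a] - D[ok, b]).mean())
    return DistanceMatrix(dist, ids=samples)


def _dosage_matrix(gm: GenotypeMatrix, samples: list[str]) -> np.ndarray:
    """Per-individual alternate-allele dosage scaled to [0, 1]; NaN if any
    slot of the call is unknown.  Haploid calls give {0, 1}; diploid calls
    {0, 0.5, 1}, so the pairwise |difference| is the standard allele-sharing
    mismatch fraction."""
    idx = gm.sample_index(samples)
    a = gm.alleles[:, idx, :].astype(float)
    pl = gm.ploidy[idx].astype(float)
    a[a == -2] = np.nan  # NO_ALLELE slots do not participate
    with np.errstate(invalid="ignore"):
        dos = np.nansum(np.where(a >= 0, a, np.nan), axis=2) / pl[None, :]
    missing = np.any(a == -1, axis=2)
    dos[missing] = np.nan
    return dos


# ---------------------------------------------------------------------------
# neighbour joining and bootstrap
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining; negative branch lengths clamped to 0."""
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    return nj(dm, neg_as_zero=True)


def _bipartitions(tree: TreeNode, tip_set: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised to its smaller side."""
    out = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        other = tip_set - clade
        if len(clade) < 2 or len(other) < 2:
            continue
        out.add(min(clade, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_consensus(
    matrices: list[GenotypeMatrix] | GenotypeMatrix,
    samples: list[str],
    n_bootstrap: int = 100,
    seed=0,
    site_masks: dict[str, np.ndarray] | None = None,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Site-resampled NJ bootstrap.

    Resamples site columns with replacement, rebuilds the NJ tree, and
    returns the full-data NJ tree with per-bipartition bootstrap support
    percentages (also usable to build a majority-rule consensus via
    :func:`consensus_tree`).
    """
    if isinstance(matrices, GenotypeMatrix):
        matrices = [matrices]
    if n_bootstrap < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    # concatenate haplotype slots across scaffolds (all-male X usage: one
    # slot per individual per scaffold)
    blocks = []
    for gm in matrices:
        idx = gm.sample_index(samples)
        h = gm.haplotypes(idx)
        if site_masks is not None and gm.scaffold in site_masks:
            h = h[site_masks[gm.scaffold]]
        pl = gm.ploidy[idx]
        if not np.all(pl == pl[0]):
            raise ValueError("mixed ploidy among chosen samples is not supported here")
        if pl[0] == 2:
            # use allele dosage per individual
            h = h.reshape(h.shape[0], -1, 2).mean(axis=2)
        blocks.append(h)
    H = np.concatenate(blocks, axis=0)
    n_sites = H.shape[0]
    if n_sites < 10:
        import warnings

        warnings.warn(f"bootstrap over only {n_sites} sites", stacklevel=2)

    def tree_from(h: np.ndarray) -> TreeNode:
        called = h >= 0
        n = len(samples)
        d = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                ok = called[:, a] & called[:, b]
                tot = int(ok.sum())
                d[a, b] = d[b, a] = (
                    np.mean(np.abs(h[ok, a] - h[ok, b])) if tot else 0.0
                )
        return nj_tree(DistanceMatrix(d, ids=samples))

    tip_set = frozenset(samples)
    main_tree = tree_from(H)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_bootstrap):
        res = rng.integers(0, n_sites, size=n_sites)
        for bp in _bipartitions(tree_from(H[res]), tip_set):
            counts[bp] = counts.get(bp, 0) + 1
    support = {bp: 100.0 * c / n_bootstrap for bp, c in counts.items()}
    # annotate the full-data tree
    for node in main_tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        key = min(clade, tip_set - clade, key=lambda s: (len(s), sorted(s)))
        node.name = f"{support.get(key, 0.0):.0f}"
    return main_tree, support


def consensus_tree(trees: list[TreeNode], cutoff: float = 0.5) -> TreeNode:
    """Majority-rule consensus of bootstrap trees."""
    return majority_rule(trees, cutoff=cutoff)[0]


# ---------------------------------------------------------------------------
# clustering verdict
# ---------------------------------------------------------------------------

def fitch_score(tree: TreeNode, labels: dict[str, str]) -> int:
    """Minimum number of label changes on the tree (small-parsimony score).

    Exact for arbitrary (multifurcating) trees via unit-cost Sankoff dynamic
    programming, and invariant to rooting because the cost is symmetric.
    ``labels`` maps tip name -> character state.
    """
    states = sorted(set(labels.values()))
    s_idx = {s: i for i, s in enumerate(states)}
    inf = float("inf")

    def post(node) -> np.ndarray:
        if node.is_tip():
            cost = np.full(len(states), inf)
            cost[s_idx[labels[node.name]]] = 0.0
            return cost
        total = np.zeros(len(states))
        for child in node.children:
            c = post(child)
            # transition cost: stay free, switch costs 1
            total += np.minimum(c, c.min() + 1.0)
        return total

    return int(post(tree).min())


@dataclass
class ClusteringVerdict:
    monophyletic: bool
    support: float | None
    mixing_score: int
    introgression_consistent: bool


def flatwing_clustering_test(
    tree: TreeNode,
    morph_of: dict[str, str],
    support: dict[frozenset[str], float] | None = None,
    focal_morph: str = "flatwing",
    min_support: float = 70.0,
) -> ClusteringVerdict:
    """Do all focal-morph tips form a single (unrooted) clade?

    The verdict is "introgression-consistent" iff the focal tips are
    monophyletic with bootstrap support >= ``min_support`` (a tree without
    support values passes on topology alone).  The mixing score is the Fitch
    parsimony count of morph changes: 1 for perfect segregation, higher the
    more morphs interleave across islands.
    """
    tips = [t.name for t in tree.tips()]
    focal = frozenset(t for t in tips if morph_of[t] == focal_morph)
    if len(focal) < 2:
        raise ValueError("need at least 2 focal-morph tips")
    tip_set = frozenset(tips)
    other = tip_set - focal
    mono = len(other) >= 1 and focal in {
        frozenset(t.name for t in node.tips())
        for node in tree.traverse(include_self=False)
        if not node.is_tip()
    } | {
        # unrooted: the complement clade also implies the bipartition
        tip_set - frozenset(t.name for t in node.tips())
        for node in tree.traverse(include_self=False)
        if not node.is_tip()
    }
    key = min(focal, other, key=lambda s: (len(s), sorted(s)))
    sup = support.get(key) if support is not None else None
    score = fitch_score(tree, morph_of)
    consistent = mono and (sup is None or sup >= min_support)
    return ClusteringVerdict(
        monophyletic=bool(mono),
        support=sup,
        mixing_score=score,
        introgression_consistent=bool(consistent),
    )


# ---------------------------------------------------------------------------
# region divergence contrast
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    statistic: str
    observed_diff: float  # mean(inside) - mean(outside)
    p_empirical: float
    p_ttest: float
    n_inside: int
    n_outside: int
    n_randomizations: int


def _randomized_diffs(
    values: np.ndarray, mask: np.ndarray, n_rand: int, rng, mode: str
) -> np.ndarray:
    n = len(values)
    k = int(mask.sum())
    diffs = np.empty(n_rand)
    for r in range(n_rand):
        if mode == "block":
            shift = int(rng.integers(1, n))
            m = np.roll(mask, shift)
        else:
            m = np.zeros(n, dtype=bool)
            m[rng.choice(n, size=k, replace=False)] = True
        diffs[r] = values[m].mean() - values[~m].mean()
    return diffs


def region_divergence_contrast(
    windows: pd.DataFrame,
    region_mask: np.ndarray,
    columns: tuple[str, ...] = ("d", "dxy"),
    n_randomizations: int = 1000,
    mode: str = "label",
    seed=0,
) -> dict[str, ContrastResult]:
    """Inside-vs-outside contrast of window statistics with a randomisation null.

    ``region_mask`` marks in-region windows.  For each named column the
    observed difference of means (inside - outside) is compared with
    ``n_randomizations`` random reassignments of the in-region label that
    preserve the in-region window count (``mode='label'``, the default).
    ``mode='block'`` instead rotates the mask along the window sequence,
    preserving contiguity and hence the autocorrelation of overlapping
    windows; it is the conservative choice but at a few hundred windows its
    null has too few distinct configurations to resolve small p-values.
    The one-sided empirical p is (1 + #null >= observed) / (n + 1); a Welch
    t-test p is reported alongside.
    """
    mask = np.asarray(region_mask, bool)
    if mask.all():
        raise ValueError("region covers all windows; no background to contrast")
    if mask.sum() < 10 or (~mask).sum() < 10:
        raise ValueError("need at least 10 windows in each class")
    rng = np.random.default_rng(seed)
    out = {}
    for col in columns:
        vals = windows[col].to_numpy(float)
        ok = np.isfinite(vals)
        v, m = vals[ok], mask[ok]
        obs = v[m].mean() - v[~m].mean()
        null = _randomized_diffs(v, m, n_randomizations, rng, mode)
        p_emp = (1.0 + np.sum(null >= obs)) / (n_randomizations + 1.0)
        p_t = float(stats.ttest_ind(v[m], v[~m], equal_var=False)[1])
        out[col] = ContrastResult(
            statistic=col, observed_diff=float(obs), p_empirical=float(p_emp),
            p_ttest=p_t, n_inside=int(m.sum()), n_outside=int((~m).sum()),
            n_randomizations=n_randomizations,
        )
    return out
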