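"""Island-system simulator: neutral backbone plus X-linked male-limited sweeps.

The model system is a set of three island demes recently derived from a
distant conspecific source population, with a sister-species outgroup.  Males
are XO (one X copy), females XX.  A focal "silencing" allele on an X scaffold
is favoured by male-limited viability selection: carrier males escape an
acoustically orienting parasitoid, non-carrier (singing) males survive with
relative fitness ``w_normal``.  The deme presets mirror the study system's
field demographics: fixation in deme 1 (Kauai-like), a balanced polymorphism
around 45% in deme 2 (Oahu-like), and a rare, recently arisen variant in
deme 3 (Hilo-like).

Two machineries cooperate:

* Neutral variation is generated with msprime under the configured demography
  (ordered splits, founding bottlenecks with recent expansion, and symmetric
  island migration switched on at ``migration_start_generation``).  The
  mutation rate is a desk-scale effective rate: downstream statistics need
  site counts, not per-base realism.
* The focal locus is simulated forward in time with a Wright-Fisher
  recursion specific to X-linked inheritance (sons inherit their X from
  mothers, daughters one X from each parent) and male-limited viability
  selection.  The sweep is then planted into the sampled haplotypes: carriers
  share their deme's founder haplotype around the causal site (parallel
  scenario) or the origin deme's founder haplotype (introgression scenario).

Every downstream stage of the package consumes the resulting
:class:`SimulatedDataset`, and the ground truth (causal loci, per-generation
allele trajectories, migrant-ancestry fractions) is carried alongside the
genotypes so planted signals can be checked against what each stage recovers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .genotypes import MISSING, NO_ALLELE, GenotypeMatrix, write_vcf

ISLANDS = ("kauai", "oahu", "hilo")
ALL_DEMES = ISLANDS + ("australia", "outgroup")
SCENARIOS = ("parallel", "introgression", "no_geneflow", "neutral")

GENERATIONS_PER_YEAR = 4  # generation time of 0.25 year


@dataclass(frozen=True)
class Scaffold:
    name: str
    length: int
    is_x: bool = False


@dataclass
class SelectionModel:
    """Male-limited viability selection on the X-linked focal locus.

    w_normal : relative survival of singing (non-carrier) males; carriers 1.
    p0 : initial allele frequency at sweep onset.
    balanced_equilibrium / balance_strength : optional negative
        frequency-dependent carrier fitness 1 + strength * (eq - phenotype
        frequency), giving a stable polymorphism at ``balanced_equilibrium``.
    """

    w_normal: float = 0.1
    p0: float = 0.005
    balanced_equilibrium: float | None = None
    balance_strength: float = 4.0


def default_genome_layout() -> list[Scaffold]:
    return [
        Scaffold("scaffold_A1", 250_000, is_x=False),
        Scaffold("scaffold_A2", 250_000, is_x=False),
        Scaffold("scaffold_X1", 250_000, is_x=True),
        Scaffold("scaffold_X2", 250_000, is_x=True),
    ]


@dataclass
class SimulationConfig:
    """Full parameterisation of one simulated island system.

    Split times are generations before present and must decrease toward the
    present: the oldest is the founding of deme 2's lineage from the
    conspecific source, then deme 3 splits from deme 2, then deme 1 from
    deme 3 (the best-supported colonisation order for the study system,
    converted from years at 4 generations per year).
    """

    deme_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "kauai": 500, "oahu": 500, "hilo": 500, "australia": 500, "outgroup": 1000,
        }
    )
    # (founding of oahu lineage, hilo from oahu, kauai from hilo), generations ago
    split_times: tuple[float, float, float] = (3200.0, 2280.0, 1600.0)
    australia_split: float = 8000.0
    outgroup_split: float = 40000.0
    bottleneck_factors: dict[str, float] = field(
        default_factory=lambda: {"kauai": 0.2, "oahu": 0.2, "hilo": 0.2}
    )
    migration_rate: float = 0.005
    # optional per-pair symmetric rates (keys: sorted island pairs); the
    # scalar rate applies to any pair not listed
    pair_migration: dict[tuple[str, str], float] | None = None
    migration_start_generation: int = 1400
    mutation_rate: float = 5.0e-7  # desk-scale effective rate, per site per generation
    recombination_rate: float = 1.0e-7
    genome_layout: list[Scaffold] = field(default_factory=default_genome_layout)
    causal_scenario: str = "parallel"
    causal_scaffold: str = "scaffold_X1"
    causal_positions: dict[str, int] = field(default_factory=dict)
    causal_origin: dict[str, str] = field(default_factory=dict)
    selection: SelectionModel = field(default_factory=SelectionModel)
    sweep_flank: int = 30_000
    sweep_generations: int = 120
    # per-deme sample design: (n_flatwing_males, n_normal_males)
    samples: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "kauai": (10, 10), "oahu": (10, 10), "hilo": (10, 10),
            "australia": (0, 7), "outgroup": (0, 3),
        }
    )
    mean_depth_range: tuple[float, float] = (20.0, 30.0)
    seed: int = 0

    def validate(self) -> None:
        t_found, t_hilo, t_kauai = self.split_times
        if not (t_found > t_hilo > t_kauai > 0):
            raise ValueError("split times must be strictly decreasing toward the present")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration rate must lie in [0, 1]")
        for pair, rate in (self.pair_migration or {}).items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"migration rate for pair {pair} must lie in [0, 1]")
        if not 0.0 < self.selection.w_normal <= 1.0:
            raise ValueError("w_normal must lie in (0, 1]")
        if any(n < 2 for n in self.deme_sizes.values()):
            raise ValueError("deme sizes must be >= 2")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be non-negative")
        if self.causal_scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.causal_scenario!r}; valid: {', '.join(SCENARIOS)}"
            )

    def x_scaffolds(self) -> list[Scaffold]:
        return [s for s in self.genome_layout if s.is_x]

    def pair_rate(self, a: str, b: str) -> float:
        """Symmetric per-generation migration rate between two islands."""
        if self.pair_migration:
            key = tuple(sorted((a, b)))
            if key in self.pair_migration:
                return self.pair_migration[key]
        return self.migration_rate


@dataclass
class AlleleTrajectory:
    """Per-generation state of the focal allele in one deme."""

    generation: np.ndarray
    p_f: np.ndarray  # allele frequency on female X chromosomes
    p_m: np.ndarray  # allele frequency on male X chromosomes (zygotes)
    male_phenotype_freq: np.ndarray  # carrier fraction among surviving adult males

    @property
    def lost(self) -> bool:
        return bool(self.p_f[-1] == 0.0 and self.p_m[-1] == 0.0)

    @property
    def fixed(self) -> bool:
        return bool(self.p_f[-1] == 1.0 and self.p_m[-1] == 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "p_f": self.p_f,
                "p_m": self.p_m,
                "male_phenotype_freq": self.male_phenotype_freq,
            }
        )


@dataclass
class Truth:
    causal_loci: pd.DataFrame  # deme, scaffold, position, origin_deme
    trajectories: pd.DataFrame  # deme, generation, p_f, p_m, male_phenotype_freq
    ancestry: pd.DataFrame  # id, deme, anc_kauai, anc_oahu, anc_hilo
    migration_record: pd.DataFrame  # deme, generation, migrant_fraction


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    matrices: list[GenotypeMatrix]
    metadata: pd.DataFrame  # id, deme, sex, morph, carrier
    truth: Truth
    cnv_calls: pd.DataFrame | None = None

    def matrix(self, scaffold: str) -> GenotypeMatrix:
        for m in self.matrices:
            if m.scaffold == scaffold:
                return m
        raise KeyError(scaffold)

    def samples_where(self, deme: str | None = None, morph: str | None = None) -> list[str]:
        md = self.metadata
        if deme is not None:
            md = md[md["deme"] == deme]
        if morph is not None:
            md = md[md["morph"] == morph]
        return list(md["id"])


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def make_scenario(name: str) -> SimulationConfig:
    """Return a fully populated configuration for a named scenario.

    parallel       three distinct causal loci on the shared X scaffold, each
                   deme its own mutational origin; migration on.
    introgression  a single causal origin in the Kauai-like deme, carried to
                   the other islands by migrants.
    no_geneflow    migration off; causal locus in the Kauai-like deme only.
    neutral        no causal locus, no selection.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid names: {', '.join(SCENARIOS)}")
    cfg = SimulationConfig(causal_scenario=name)
    # per-pair symmetric rates differ among pairs (the inferred history has
    # unequal arrow weights); this realised asymmetry is what gives the
    # sister-pair ABBA-BABA test a non-zero expectation
    unequal = {
        ("kauai", "oahu"): 0.0001,
        ("hilo", "kauai"): 0.001,
        ("hilo", "oahu"): 0.001,
    }
    if name == "parallel":
        cfg.pair_migration = dict(unequal)
        cfg.causal_positions = {"kauai": 60_000, "oahu": 125_000, "hilo": 190_000}
        cfg.causal_origin = {d: d for d in ISLANDS}
    elif name == "introgression":
        cfg.pair_migration = dict(unequal)
        cfg.causal_positions = {d: 60_000 for d in ISLANDS}
        cfg.causal_origin = {d: "kauai" for d in ISLANDS}
    elif name == "no_geneflow":
        cfg.migration_rate = 0.0
        cfg.causal_positions = {"kauai": 60_000}
        cfg.causal_origin = {"kauai": "kauai"}
    else:  # neutral
        cfg.causal_positions = {}
        cfg.causal_origin = {}
        cfg.selection = SelectionModel(w_normal=1.0, p0=0.0)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# forward Wright-Fisher sweep trajectory
# ---------------------------------------------------------------------------

def sweep_trajectory(
    n: int,
    w_normal: float,
    p0: float,
    generations: int,
    seed,
    balanced_equilibrium: float | None = None,
    balance_strength: float = 4.0,
) -> AlleleTrajectory:
    """Simulate the X-linked focal allele forward for ``generations`` steps.

    ``n`` is the diploid-count deme size; half the individuals are female
    (two X copies), half male (one X).  Each generation: male-limited
    viability selection (carrier males survive with fitness 1 or the
    frequency-dependent fitness of the balanced model, singing males with
    ``w_normal``); then binomial Wright-Fisher sampling with sons drawing
    their X from mothers and daughters one X from each parent.  The allele
    has no recurrent mutation, so frequencies 0 and 1 are absorbing.
    """
    rng = np.random.default_rng(seed)
    n_f = n // 2
    n_m = n - n_f
    p_f = float(p0)
    p_m = float(p0)
    gens = np.arange(generations + 1)
    out_pf = np.empty(generations + 1)
    out_pm = np.empty(generations + 1)
    out_pheno = np.empty(generations + 1)
    for t in range(generations + 1):
        # viability selection among males
        if balanced_equilibrium is not None:
            w_fw = max(0.0, 1.0 + balance_strength * (balanced_equilibrium - p_m))
        else:
            w_fw = 1.0
        denom = p_m * w_fw + (1.0 - p_m) * w_normal
        p_m_star = p_m * w_fw / denom if denom > 0 else 0.0
        out_pf[t] = p_f
        out_pm[t] = p_m
        out_pheno[t] = p_m_star
        if t == generations:
            break
        if (p_f == 0.0 and p_m == 0.0) or (p_f == 1.0 and p_m == 1.0):
            # absorbed; frequencies stay put
            continue
        sons = rng.binomial(n_m, p_f)
        d_maternal = rng.binomial(n_f, p_f)
        d_paternal = rng.binomial(n_f, p_m_star)
        p_m = sons / n_m
        p_f = (d_maternal + d_paternal) / (2 * n_f)
    return AlleleTrajectory(gens, out_pf, out_pm, out_pheno)


def deterministic_trajectory(
    w_normal: float, p0: float, generations: int
) -> AlleleTrajectory:
    """Infinite-population limit of :func:`sweep_trajectory` (no balancing)."""
    p_f = p0
    p_m = p0
    rows = []
    for _t in range(generations + 1):
        p_m_star = p_m / (p_m + w_normal * (1.0 - p_m)) if (p_m + w_normal * (1 - p_m)) > 0 else 0.0
        rows.append((p_f, p_m, p_m_star))
        p_f, p_m = (p_f + p_m_star) / 2.0, p_f
    arr = np.array(rows)
    return AlleleTrajectory(np.arange(generations + 1), arr[:, 0], arr[:, 1], arr[:, 2])


def simulate_sweep_trajectory(
    config: SimulationConfig, deme: str, seed, generations: int | None = None
) -> AlleleTrajectory:
    """Run the focal-allele forward simulation for one deme of ``config``."""
    if deme not in config.causal_positions:
        raise ValueError(f"deme {deme!r} has no causal locus in this scenario")
    sel = config.selection
    balanced = sel.balanced_equilibrium if deme == "oahu" else None
    if config.causal_scenario in ("parallel", "introgression") and deme == "oahu":
        balanced = sel.balanced_equilibrium if sel.balanced_equilibrium is not None else 0.45
    return sweep_trajectory(
        n=config.deme_sizes[deme],
        w_normal=sel.w_normal,
        p0=sel.p0,
        generations=generations if generations is not None else config.sweep_generations,
        seed=seed,
        balanced_equilibrium=balanced,
        balance_strength=sel.balance_strength,
    )


# ---------------------------------------------------------------------------
# neutral backbone (msprime)
# ---------------------------------------------------------------------------

def _build_demography(config: SimulationConfig, x_linked: bool) -> msprime.Demography:
    """Population tree: ((kauai,hilo)@t3, oahu)@t2 joins the conspecific
    source lineage at t1 (the founding of the archipelago lineage); the
    outgroup species attaches at ``outgroup_split``.  Islands sit at their
    founding (bottleneck) size from the split until the recent expansion at
    ``migration_start_generation``, when symmetric migration also begins."""
    # X-linked scaffolds carry 3/4 of the autosomal number of copies
    scale = 0.75 if x_linked else 1.0
    sz = {k: scale * v for k, v in config.deme_sizes.items()}
    bf = {d: config.bottleneck_factors.get(d, 1.0) for d in ISLANDS}
    dem = msprime.Demography()
    for name in ALL_DEMES:
        dem.add_population(name=name, initial_size=sz[name])
    # ancestral lineage populations (hilo-lineage pre-kauai-split, oahu
    # lineage pre-hilo-split, conspecific source)
    dem.add_population(name="anc_kh", initial_size=bf["hilo"] * sz["hilo"])
    dem.add_population(name="anc_kho", initial_size=bf["oahu"] * sz["oahu"])
    dem.add_population(name="anc_oce", initial_size=sz["australia"])
    dem.add_population(name="root", initial_size=sz["outgroup"])
    t_found, t_hilo, t_kauai = config.split_times
    m_start = config.migration_start_generation
    for island in ISLANDS:
        if bf[island] != 1.0:
            dem.add_population_parameters_change(
                time=m_start, population=island, initial_size=bf[island] * sz[island]
            )
    any_migration = False
    for i, a in enumerate(ISLANDS):
        for b in ISLANDS[i + 1 :]:
            rate = config.pair_rate(a, b)
            if rate > 0:
                dem.set_symmetric_migration_rate([a, b], rate)
                any_migration = True
    if any_migration:
        dem.add_migration_rate_change(time=m_start, rate=0.0)
    dem.add_population_split(time=t_kauai, derived=["kauai", "hilo"], ancestral="anc_kh")
    dem.add_population_split(time=t_hilo, derived=["anc_kh", "oahu"], ancestral="anc_kho")
    dem.add_population_split(
        time=t_found, derived=["anc_kho", "australia"], ancestral="anc_oce"
    )
    dem.add_population_split(
        time=config.outgroup_split, derived=["anc_oce", "outgroup"], ancestral="root"
    )
    dem.sort_events()
    return dem


def _metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for deme in ALL_DEMES:
        n_fw, n_nw = config.samples.get(deme, (0, 0))
        for k in range(n_fw + n_nw):
            morph = "flatwing" if k < n_fw else "normal"
            rows.append(
                {
                    "id": f"{deme}_{k:02d}",
                    "deme": deme,
                    "sex": "male",
                    "morph": morph,
                    "carrier": morph == "flatwing",
                }
            )
    return pd.DataFrame(rows)


def _simulate_scaffold(
    config: SimulationConfig, scaffold: Scaffold, metadata: pd.DataFrame, seed_pair
) -> GenotypeMatrix:
    dem = _build_demography(config, scaffold.is_x)
    counts = metadata.groupby("deme", sort=False)["id"].count()
    sample_sets = []
    slots_per_ind = []  # X lineage count per individual (males: 1)
    for deme in ALL_DEMES:
        n_ind = int(counts.get(deme, 0))
        if n_ind == 0:
            continue
        per_ind = 1 if scaffold.is_x else 2  # all sampled individuals are male
        sample_sets.append(
            msprime.SampleSet(n_ind * per_ind, population=deme, ploidy=1)
        )
        slots_per_ind.extend([per_ind] * n_ind)
    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        sequence_length=scaffold.length,
        recombination_rate=config.recombination_rate,
        random_seed=int(seed_pair[0]),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        random_seed=int(seed_pair[1]),
        model=msprime.BinaryMutationModel(),
    )
    H = mts.genotype_matrix().astype(np.int8)  # (n_sites, n_lineages)
    positions = np.array([int(s.position) + 1 for s in mts.sites()], dtype=np.int64)
    # discrete genome: positions unique and increasing
    n_ind = len(metadata)
    alleles = np.full((H.shape[0], n_ind, 2), NO_ALLELE, dtype=np.int8)
    col = 0
    for j, per_ind in enumerate(slots_per_ind):
        alleles[:, j, 0] = H[:, col]
        if per_ind == 2:
            alleles[:, j, 1] = H[:, col + 1]
        col += per_ind
    ploidy = np.array([1 if scaffold.is_x else 2] * n_ind, dtype=np.int8)
    return GenotypeMatrix(
        scaffold=scaffold.name,
        positions=positions,
        alleles=alleles,
        samples=list(metadata["id"]),
        ploidy=ploidy,
        is_x=scaffold.is_x,
        length=scaffold.length,
    )


# ---------------------------------------------------------------------------
# migrant-ancestry truth (forward tracking)
# ---------------------------------------------------------------------------

def _track_ancestry(config: SimulationConfig, rng: np.random.Generator):
    """Forward simulation of per-individual island-ancestry fractions.

    From ``migration_start_generation`` to the present, each deme of diploid
    size N reproduces by drawing two uniform parents per offspring; with
    probability m per source island an offspring is instead a migrant copied
    from that island's previous generation.  Ancestry vectors (fractions over
    the three islands) average over parents.  Also records the realised
    per-generation migrant fraction per deme.
    """
    n_demes = len(ISLANDS)
    sizes = [config.deme_sizes[d] for d in ISLANDS]
    anc = [np.eye(n_demes)[i][None, :].repeat(sizes[i], axis=0) for i in range(n_demes)]
    # per-deme in-migration rates from each other deme
    rates = np.zeros((n_demes, n_demes))
    for i, a in enumerate(ISLANDS):
        for j, b in enumerate(ISLANDS):
            if i != j:
                rates[i, j] = config.pair_rate(a, b)
    records = []
    for gen in range(config.migration_start_generation):
        new = []
        for i in range(n_demes):
            N = sizes[i]
            p1 = rng.integers(N, size=N)
            p2 = rng.integers(N, size=N)
            child = 0.5 * (anc[i][p1] + anc[i][p2])
            total_in = rates[i].sum()
            if total_in > 0:
                u = rng.random(N)
                is_migrant = u < total_in
                srcs = [j for j in range(n_demes) if rates[i, j] > 0]
                probs = np.array([rates[i, j] for j in srcs]) / total_in
                for j in np.flatnonzero(is_migrant):
                    s = int(rng.choice(srcs, p=probs))
                    child[j] = anc[s][rng.integers(sizes[s])]
                records.append(
                    {"deme": ISLANDS[i], "generation": gen, "migrant_fraction": is_migrant.mean()}
                )
            new.append(child)
        anc = new
    ancestry = {ISLANDS[i]: anc[i] for i in range(n_demes)}
    rec = pd.DataFrame(records) if records else pd.DataFrame(
        columns=["deme", "generation", "migrant_fraction"]
    )
    return ancestry, rec


# ---------------------------------------------------------------------------
# sweep planting
# ---------------------------------------------------------------------------

def _plant_sweeps(
    config: SimulationConfig,
    gm: GenotypeMatrix,
    metadata: pd.DataFrame,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Overwrite carrier haplotypes around each causal site with the founder
    haplotype of the origin deme, add a few carrier-private recent mutations,
    and insert the causal site itself."""
    out = gm.copy()
    id_to_col = {s: i for i, s in enumerate(out.samples)}
    founders: dict[str, np.ndarray] = {}
    # founder haplotypes are taken from the origin deme before any overwrite
    for deme, pos in config.causal_positions.items():
        origin = config.causal_origin.get(deme, deme)
        key = f"{origin}:{pos}"
        if key not in founders:
            origin_carriers = metadata[(metadata.deme == origin) & metadata.carrier]
            donor = origin_carriers["id"].iloc[0] if len(origin_carriers) else None
            if donor is None:
                continue
            founders[key] = gm.alleles[:, id_to_col[donor], 0].copy()
    new_sites: dict[int, np.ndarray] = {}
    for deme, pos in sorted(config.causal_positions.items()):
        origin = config.causal_origin.get(deme, deme)
        key = f"{origin}:{pos}"
        if key not in founders:
            continue
        founder = founders[key]
        lo, hi = pos - config.sweep_flank, pos + config.sweep_flank
        region = (out.positions >= lo) & (out.positions <= hi)
        region_idx = np.flatnonzero(region)
        carriers = metadata[(metadata.deme == deme) & metadata.carrier]["id"]
        for s in carriers:
            j = id_to_col[s]
            out.alleles[region_idx, j, 0] = founder[region_idx]
            # a handful of post-sweep private mutations keep carrier
            # haplotypes from being strictly identical
            k = rng.poisson(0.5)
            if k and len(region_idx):
                flip = rng.choice(region_idx, size=min(k, len(region_idx)), replace=False)
                out.alleles[flip, j, 0] = 1 - out.alleles[flip, j, 0]
        # causal site column: alt allele = carrier status in this deme
        if pos not in new_sites:
            new_sites[pos] = np.zeros(out.n_samples, dtype=np.int8)
        cols = [id_to_col[s] for s in carriers]
        new_sites[pos][cols] = 1
    if new_sites:
        add_pos = np.array(sorted(new_sites), dtype=np.int64)
        add_calls = np.full((len(add_pos), out.n_samples, 2), NO_ALLELE, dtype=np.int8)
        for i, p in enumerate(add_pos):
            add_calls[i, :, 0] = new_sites[int(p)]
        keep = ~np.isin(out.positions, add_pos)
        positions = np.concatenate([out.positions[keep], add_pos])
        alleles = np.concatenate([out.alleles[keep], add_calls], axis=0)
        order = np.argsort(positions, kind="stable")
        out = dataclasses.replace(out, positions=positions[order], alleles=alleles[order])
    return out


# ---------------------------------------------------------------------------
# sequencing-layer dressing (QUAL / DP / AD)
# ---------------------------------------------------------------------------

def _dress_matrix(gm: GenotypeMatrix, rng: np.random.Generator, mean_depth: np.ndarray) -> None:
    n_sites, n_samples = gm.n_sites, gm.n_samples
    gm.qual = np.clip(rng.normal(200.0, 60.0, size=n_sites), 1.0, None)
    gm.depth = rng.poisson(mean_depth[None, :], size=(n_sites, n_samples)).astype(np.float64)
    ad = np.zeros((n_sites, n_samples, 2), dtype=np.int64)
    a = gm.alleles
    dp = gm.depth.astype(np.int64)
    ref_like = a[:, :, 0] == 0
    alt_like = a[:, :, 0] == 1
    het = (a[:, :, 0] >= 0) & (a[:, :, 1] >= 0) & (a[:, :, 0] != a[:, :, 1])
    ad[:, :, 0] = np.where(ref_like & ~het, dp, 0)
    ad[:, :, 1] = np.where(alt_like & ~het, dp, 0)
    if het.any():
        split = rng.binomial(dp[het], 0.5)
        ad[het, 0] = split
        ad[het, 1] = dp[het] - split
    gm.allele_depth = ad
    gm.sample_mean_depth = mean_depth.copy()


# ---------------------------------------------------------------------------
# synthetic CNV call table
# ---------------------------------------------------------------------------

def simulate_cnv_calls(
    config: SimulationConfig, metadata: pd.DataFrame, seed, n_background_loci: int = 45
) -> pd.DataFrame:
    """Per-individual CNV call table on the X scaffolds.

    Copy numbers are normalised to the single-X male baseline of 1.  A set of
    shared background CNV loci varies independently of morph (enough that
    well over 20 CNVRs survive overlap-merging and the 3-supporter filter,
    the minimum for a meaningful top-5% VST percentile); if the Kauai-like
    deme carries a causal locus, one duplication spanning its sweep region is
    planted in carriers only, mirroring the morph-differentiated CNVR the
    study system shows on a single island.
    """
    rng = np.random.default_rng(seed)
    xs = config.x_scaffolds()
    if not xs:
        return pd.DataFrame(columns=["individual", "scaffold", "start", "end", "copy_number"])
    rows = []
    loci = []
    for _ in range(n_background_loci):
        sc = xs[rng.integers(len(xs))]
        start = int(rng.integers(1, sc.length - 8_000))
        loci.append((sc.name, start, start + int(rng.integers(1_500, 5_000))))
    for _, ind in metadata.iterrows():
        if ind["deme"] == "outgroup":
            continue
        for sc_name, start, end in loci:
            if rng.random() < 0.25:
                cn = float(rng.choice([0.0, 2.0, 3.0]))
                rows.append(
                    {"individual": ind["id"], "scaffold": sc_name,
                     "start": start, "end": end, "copy_number": cn}
                )
    if "kauai" in config.causal_positions and config.causal_scenario != "neutral":
        pos = config.causal_positions["kauai"]
        start, end = max(1, pos - 5_000), pos + 5_000
        for _, ind in metadata.iterrows():
            if ind["deme"] == "kauai" and ind["carrier"]:
                rows.append(
                    {"individual": ind["id"], "scaffold": config.causal_scaffold,
                     "start": start, "end": end, "copy_number": 2.0}
                )
    return pd.DataFrame(rows, columns=["individual", "scaffold", "start", "end", "copy_number"])


# ---------------------------------------------------------------------------
# top-level dataset assembly
# ---------------------------------------------------------------------------

def simulate_demography(config: SimulationConfig, seed=None) -> SimulatedDataset:
    """Simulate the full island system under ``config``.

    Returns genotypes for every scaffold, sample metadata (morphs assigned by
    the stratified sampling design), and the complete ground truth.  Identical
    config and seed give identical output.
    """
    config.validate()
    if not config.genome_layout:
        raise ValueError("genome layout has no scaffolds")
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    msp_seeds = rng.integers(1, 2**31 - 1, size=(len(config.genome_layout), 2))
    metadata = _metadata(config)
    matrices = [
        _simulate_scaffold(config, sc, metadata, msp_seeds[i])
        for i, sc in enumerate(config.genome_layout)
    ]

    # focal-locus forward trajectories (wild-deme truth)
    traj_frames = []
    for deme_idx, deme in enumerate(sorted(config.causal_positions)):
        gens = config.sweep_generations
        attempt = 0
        while True:  # condition on establishment: the observed sweeps did establish
            tr = simulate_sweep_trajectory(config, deme, (seed, deme_idx, attempt), gens)
            if tr.p_m.max() > 0.10 or attempt >= 50:
                break
            attempt += 1
        df = tr.to_frame()
        df.insert(0, "deme", deme)
        traj_frames.append(df)
    trajectories = (
        pd.concat(traj_frames, ignore_index=True)
        if traj_frames
        else pd.DataFrame(columns=["deme", "generation", "p_f", "p_m", "male_phenotype_freq"])
    )

    # plant sweeps into the causal scaffold
    for i, m in enumerate(matrices):
        if m.scaffold == config.causal_scaffold and config.causal_positions:
            matrices[i] = _plant_sweeps(config, m, metadata, rng)

    # sequencing dressing
    n_ind = len(metadata)
    lo, hi = config.mean_depth_range
    mean_depth = rng.uniform(lo, hi, size=n_ind)
    for m in matrices:
        _dress_matrix(m, rng, mean_depth)

    # migrant-ancestry truth
    ancestry_pop, migration_record = _track_ancestry(config, rng)
    anc_rows = []
    counters = {d: 0 for d in ISLANDS}
    for _, ind in metadata.iterrows():
        deme = ind["deme"]
        if deme in ISLANDS:
            vec = ancestry_pop[deme][counters[deme] % config.deme_sizes[deme]]
            counters[deme] += 1
        else:
            vec = np.zeros(len(ISLANDS))
        row = {"id": ind["id"], "deme": deme}
        row.update({f"anc_{d}": float(vec[i]) for i, d in enumerate(ISLANDS)})
        anc_rows.append(row)
    ancestry = pd.DataFrame(anc_rows)
    if config.causal_scenario == "introgression":
        # carriers outside the origin deme hold the origin haplotype around the
        # causal site; their ancestry fraction must reflect at least that tract
        xlen = next(s.length for s in config.genome_layout if s.name == config.causal_scaffold)
        tract = 2 * config.sweep_flank / xlen / len(config.x_scaffolds() or [1])
        carriers = metadata[metadata.carrier & (metadata.deme != "kauai")]["id"]
        sel = ancestry["id"].isin(carriers)
        ancestry.loc[sel, "anc_kauai"] = np.maximum(ancestry.loc[sel, "anc_kauai"], tract)

    causal_rows = [
        {
            "deme": deme,
            "scaffold": config.causal_scaffold,
            "position": pos,
            "origin_deme": config.causal_origin.get(deme, deme),
        }
        for deme, pos in sorted(config.causal_positions.items())
    ]
    causal_loci = pd.DataFrame(
        causal_rows, columns=["deme", "scaffold", "position", "origin_deme"]
    )
    truth = Truth(causal_loci, trajectories, ancestry, migration_record)
    ds = SimulatedDataset(config, matrices, metadata, truth)
    ds.cnv_calls = simulate_cnv_calls(config, metadata, rng.integers(1, 2**31 - 1))
    return ds


# ---------------------------------------------------------------------------
# unlinked-panel helper for gene-flow tests
# ---------------------------------------------------------------------------

def simulate_geneflow_panel(
    config: SimulationConfig,
    n_target_sites: int = 10_000,
    n_per_island: int = 5,
    n_outgroup: int = 3,
    sequence_length: int = 1_000_000,
    seed=1,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Simulate a panel of loosely linked biallelic sites for D-statistics.

    One autosome-like segment is simulated under the configured demography
    with a high recombination rate, and the mutation rate is solved so the
    expected number of segregating sites is ``n_target_sites``.  Returns a
    haploid genotype matrix plus the population map.
    """
    dem = _build_demography(config, x_linked=False)
    sample_plan = [("kauai", n_per_island), ("hilo", n_per_island), ("oahu", n_per_island),
                   ("outgroup", n_outgroup)]
    n_lineages = sum(n for _, n in sample_plan)
    a1 = np.sum(1.0 / np.arange(1, n_lineages))
    theta_needed = n_target_sites / a1  # = 4 N mu L
    mu = theta_needed / (4 * config.deme_sizes["kauai"] * sequence_length)
    ss = np.random.SeedSequence(seed)
    s1, s2 = np.random.default_rng(ss).integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n, population=p, ploidy=1) for p, n in sample_plan],
        demography=dem,
        sequence_length=sequence_length,
        recombination_rate=1e-6,
        random_seed=int(s1),
    )
    mts = msprime.sim_mutations(
        ts, rate=mu, random_seed=int(s2), model=msprime.BinaryMutationModel()
    )
    H = mts.genotype_matrix().astype(np.int8)
    positions = np.array([int(s.position) + 1 for s in mts.sites()], dtype=np.int64)
    ids, pops = [], {}
    for pop, n in sample_plan:
        pops[pop] = [f"{pop}_{k}" for k in range(n)]
        ids.extend(pops[pop])
    alleles = np.full((H.shape[0], n_lineages, 2), NO_ALLELE, dtype=np.int8)
    alleles[:, :, 0] = H
    gm = GenotypeMatrix(
        scaffold="panel",
        positions=positions,
        alleles=alleles,
        samples=ids,
        ploidy=np.ones(n_lineages, dtype=np.int8),
        is_x=False,
        length=sequence_length,
    )
    return gm, pops


# ---------------------------------------------------------------------------
# truth / dataset serialisation
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_truth(dataset: SimulatedDataset, outdir) -> None:
    """Serialise truth tables (TSV) and sample metadata next to the VCF."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = dataset.truth
    t.causal_loci.to_csv(outdir / "truth_causal_loci.tsv", sep="\t", index=False)
    t.trajectories.to_csv(
        outdir / "truth_trajectories.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    t.ancestry.to_csv(
        outdir / "truth_ancestry.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    t.migration_record.to_csv(
        outdir / "truth_migration.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    dataset.metadata.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    if dataset.cnv_calls is not None:
        dataset.cnv_calls.to_csv(
            outdir / "cnv_calls.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )


def read_truth(outdir) -> Truth:
    from pathlib import Path

    outdir = Path(outdir)
    return Truth(
        causal_loci=pd.read_csv(outdir / "truth_causal_loci.tsv", sep="\t"),
        trajectories=pd.read_csv(outdir / "truth_trajectories.tsv", sep="\t"),
        ancestry=pd.read_csv(outdir / "truth_ancestry.tsv", sep="\t"),
        migration_record=pd.read_csv(outdir / "truth_migration.tsv", sep="\t"),
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write the VCF plus all truth tables to ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(dataset.matrices, outdir / "genotypes.vcf")
    write_truth(dataset, outdir)
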