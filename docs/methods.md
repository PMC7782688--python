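# Methods

## The island system and what the simulator emulates

The simulated system is three island demes of a field cricket with an
XX/XO sex system (males hemizygous for the X), recently derived from a
distant conspecific mainland population, with a sister-species outgroup.
An X-linked, male-limited variant silences males and is favoured because
silent males escape an acoustically hunting parasitoid.  The deme
presets mirror the field demographics of the study system: fixation in
deme 1 (Kauai-like), a balanced polymorphism near 45% flatwing males in
deme 2 (Oahu-like), and a rare, recently arisen variant in deme 3
(Hilo-like).

**Demography.**  Time is measured in generations at 4 generations per
year.  The preset population tree converts the inferred colonisation
history: the archipelago lineage separates from the mainland source
3200 generations ago (800 years), deme 3 splits from deme 2 at 2280
(570 years), deme 1 from deme 3 at 1600 (400 years); the outgroup
species attaches at 40,000 generations and the mainland split at 8,000
— desk-scale choices deep enough to provide abundant fixed differences
for ABBA–BABA polarisation.  Each island sits at its founding
(bottleneck) size — factor 0.2 of the present size N = 500 diploids —
from its split until 1400 generations ago (350 years), when it expands
to N and symmetric migration among islands begins, continuing to the
present ("ancient bottlenecks, recent expansions accompanied by gene
flow").

**Migration.**  Migration is symmetric *within* each island pair but the
pair rates differ, as the inferred history's unequal arrow weights do:
the presets use 1×10⁻⁴ per generation for deme1↔deme2 and 1×10⁻³ for the
other two pairs.  Two considerations fixed these values.  First, rates
of order 5×10⁻³ sustained over 1400 generations homogenise three demes
of N = 500 almost completely, which honestly drives every D statistic to
zero — the regime the study system is *not* in, given its strongly
significant D values.  Second, the sister-pair test
D(deme1, deme3; deme2, outgroup) has expectation zero when all pair
rates are equal (ABBA and BABA inflows cancel), so only the *difference*
between pair rates is detectable; the chosen rates make the planted
gene-flow signal clearly significant at desk scale while keeping F_ST
structure among islands.  The rates were frozen after this calibration
and are exposed as free parameters (`pair_migration`).

**Neutral variation** is generated with msprime under that demography,
one coalescent simulation per scaffold, binary mutation model on a
discrete genome.  The default genome is a desk-scale toy: two autosomal
and two X-linked scaffolds of 250 kb.  The effective mutation rate
5×10⁻⁷ per bp per generation is deliberately inflated (the organismal
rate would give almost no variation on 1 Mb): it yields ≈55,000
segregating sites genome-wide and ≈2,300 within-island polymorphic X
sites per island.  The latter number is a designed ceiling, not an
accident: a 10-case/10-control hemizygous Fisher test can reach at best
p = 2/C(20,10) ≈ 1.1×10⁻⁵, so the Bonferroni design only has power while
the per-island test count stays below 0.05/1.1×10⁻⁵ ≈ 4,600.  X-linked
scaffolds use ¾ of the autosomal effective size.

**The focal locus** is simulated forward in time.  State is the allele
frequency on female X's (p_f) and male X's (p_m).  Each generation:
male-limited viability selection (carrier males survive with relative
fitness 1, singing males with w_normal, default 0.1; females are
unselected), then Wright–Fisher binomial sampling with X-linked
transmission — sons draw their X from mothers (p_m′ from p_f), daughters
one X from each parent (p_f′ from (p_f + p_m*)/2, where p_m* is the
post-selection male frequency).  Frequencies 0 and 1 are absorbing (no
recurrent mutation at the site).  The deterministic limit of this
recursion lifts the adult flatwing-male fraction from p₀ = 0.005 past
95% inside a dozen generations; stochastic runs at N = 1000 match, which
reproduces the observed "0% to over 95% in ca. 20–30 generations" spread
and fixation by generation 60.  The balanced deme uses negative
frequency-dependent carrier fitness 1 + α(0.45 − p), α = 4, giving a
stable polymorphism at 45% flatwing males.

**Sweep planting.**  Sampled individuals are morph-stratified (10
flatwing + 10 normal males per island, 7 mainland, 3 outgroup males —
the study's sampling design; the fixed deme's normal males stand in for
lab stock from pre-sweep collections).  Around each causal site (±30 kb)
every carrier's haplotype is replaced by the founder haplotype of the
allele's origin deme — its own deme under the parallel scenario, deme 1's
under introgression — plus a Poisson(0.5) sprinkling of carrier-private
recent mutations.  This plants exactly the signals the inference chain
looks for: depressed π and strongly negative Tajima's D in carriers,
elevated F_ST against unselected populations, elevated net divergence d
between islands under parallel origins (each island fixes a different
haplotype) but not under introgression, and cross-island carrier
monophyly only under introgression.  The causal site itself is inserted
as a genotype column (alt = carrier).

**Truth tables** carry the causal loci and origins, the per-generation
allele trajectories, and per-individual migrant-ancestry fractions from
a forward ancestry-tracking simulation run under the same migration
parameters (each generation, a fraction m of each deme is replaced by
migrants copied from the source deme; offspring average their parents'
ancestry vectors).  The ancestry tracking is deliberately decoupled from
the coalescent genotypes — it provides distributionally consistent
truth, not a lineage-for-lineage match; under the introgression scenario
carrier ancestry additionally records the origin-deme tract by
construction.

**Sequencing dressing.**  QUAL ~ N(200, 60) clipped at 1, per-call depth
Poisson around a per-individual mean drawn uniformly from 20–30×, allele
depths split binomially for heterozygotes.  These are clean by design —
the QC chain should (and does) remove < 1% of simulated sites — because
the package's QC tests assert rule arithmetic, not error-model realism.

**Synthetic CNV calls** accompany each dataset: 45 background CNV loci
on the X scaffolds (each individual carries each with probability 0.25,
copy number ∈ {0, 2, 3} around the male-X baseline of 1), plus one
duplication spanning the swept deme's causal region in carriers only,
mirroring the single-island structural-variant association the system
shows.  Forty-five loci keep the post-merge CNVR count comfortably above
20, the minimum at which a nearest-rank top-5% cutoff can flag anything.

## Statistics: conventions and numerical choices

* **π / d_xy denominators** are full window bp (10 kb windows, 2.5 kb
  step; windows overrunning a scaffold are dropped), matching the
  convention of the standard VCF toolchain; monomorphic and uncallable
  sites contribute zero to numerators, missing calls are handled by
  per-site pairwise deletion.  Note that with these estimators
  d(pop, pop) is not exactly 0 but −π/(n−1), a small sampling-bias term.
* **Tajima's D** uses k = window pairwise-difference count (absolute),
  the 1989 constants, and the rounded mean call count over segregating
  sites as n; undefined (NaN) with no segregating sites.
* **F_ST** defaults to the Weir–Cockerham ratio-of-sums form via
  allele-level analysis of variance, which handles hemizygous (haploid)
  male X data naturally; the Hudson estimator is available as a
  cross-check and both are validated against the island-model
  expectation 1/(1 + 4Nm) for haploids.
* **D statistic**: derived allele = not the outgroup major allele;
  outgroup-polymorphic sites are retained with (1 − p₄) weighting.
  Block jackknife uses the Busing delete-m_j weighted form with
  per-block denominators as weights; default block size 1 Mb for panels,
  25 kb in the desk-scale pipeline (≥ 10 non-empty blocks enforced).
* **GWAS**: monomorphic sites are skipped and excluded from the
  Bonferroni count.  The "strictest criterion" is the reference island's
  Bonferroni-corrected raw-p cutoff (0.05/n_tests_ref) applied to every
  island's raw p-values — the only interpretation that is monotone and
  robust to unequal test counts.  The fixed deme uses pooled normal-wing
  controls from all islands (its own sampled normals included), which
  suppresses population-structure false positives.
* **Verdict tree**: built from the harmonised candidate-SNP positions
  restricted to scaffolds significant on *all* islands.  Two desk-scale
  lessons are baked in: island-private scaffold hits are
  founder-structure artifacts (a deep within-deme clade can align with
  morph labels by chance), and ±1 kb flanking sites carry island
  background ancestry that swamps the trait signal — the origin deme's
  normal males sit close to the founder haplotype, breaking carrier
  monophyly spuriously.  Monophyly is assessed as an unrooted
  bipartition; the "introgression-consistent" verdict additionally
  requires bootstrap support ≥ 70 (our operationalisation of a
  criterion the source analyses applied by inspection); the mixing
  score is exact small-parsimony (unit-cost Sankoff), rooting-invariant.
* **Divergence contrast**: one-sided empirical
  p = (1 + #null ≥ obs)/(n + 1) from 1000 random reassignments of the
  in-region label.  A rotation mode that preserves window contiguity
  (and hence the autocorrelation of overlapping windows) is implemented,
  but at a few hundred windows it admits only ~n distinct null
  configurations and cannot resolve p < 0.05 reliably, so the label
  permutation is the default and the Welch t-test is reported alongside.
* **Sweep scan**: "top 5%" is strictly above the nearest-rank 95th
  percentile of finite values; ties at the cutoff are excluded
  (deterministic, conservative).  Windows with π = 0 in the selected
  group map to a +∞ log-ratio flag that always qualifies — a fully swept
  region must not be discarded.  Flagged windows merge when overlapping
  or book-ended (end + 1 = start).  Percentiles are genome-wide by
  default with a per-scaffold option.
* **V_ST** uses sample (n−1) variances throughout, with V_S weighted by
  group sizes; V_T = 0 defines V_ST = 0.  Identical groups therefore give
  V_ST ≤ 0 (exactly −V_S·0 corner cases aside), not exactly 0, and V_ST
  can be negative whenever within-group variance dominates.  CNVR
  support < 3 individuals is filtered; uncalled individuals sit at the
  baseline copy number 1.
* **QC boundaries** are strict inequalities read literally: quality
  < 30, depth strictly below mean/3 or above 3·mean (mean/6 and
  1.5·mean on the X), heterozygous male-X calls resolved only when one
  allele depth strictly exceeds 3× the other, sites dropped only when
  the unknown fraction strictly exceeds 25%.

## Problem sizes

Desk-scale defaults throughout: 1 Mb genome over 4 scaffolds, N = 500
per deme, 70 sampled males, ≈190 X windows, 100 bootstrap replicates,
1000 randomisations, 20 replicate panels of 10,000 unlinked sites for
the D-null check, 200 forward-trajectory replicates at N = 1000 for the
sweep-dynamics checks.  A full pipeline run takes ~30 s on one CPU.

## Known limitations

* The sweep is planted into coalescent haplotypes rather than arising
  from linked forward simulation; recombination-distance decay of the
  sweep signal is therefore a step function at the ±30 kb flank, and
  statistics sensitive to the shape of the sweep trough (e.g., iHS-type
  haplotype tests, which are out of scope) should not be read off these
  data.
* Migrant-ancestry truth is distributional, not lineage-matched to the
  genotypes.
* Tajima's D with heavy missingness uses an averaged sample size; the
  simulator's clean data never exercise that approximation hard.
* The GWAS has no kinship/mixed-model correction, faithfully inheriting
  the vulnerability of the basic case/control design to founder
  structure (visible at desk scale as island-private artifact hits, which
  the shared-scaffold rule absorbs).
* Passing tests demonstrate recovery of *planted* signals under this
  generator's assumptions (clean genotypes, stratified sampling, known
  demography); they do not certify performance on real resequencing
  data with calling error, relatedness, and reference bias.
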