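# Methods

## Model and assumptions

The package treats the classical MHC as a single non-recombining block within
a family: each child inherits one whole parental haplotype per parent, the
haplotypes being identical by descent across the eight classical loci
HLA-A, -C, -B, -DRB1, -DQA1, -DQB1, -DPA1, -DPB1. This is the standard
assumption behind family segregation analysis of the MHC — recombination
within the ~3.6 Mb region is rare on the scale of a single meiosis — and it is
what makes the phase of a family a finite combinatorial object: four parental
haplotypes plus one transmission label per child per parent, constant across
loci.

Alleles follow colon-delimited IMGT/HLA nomenclature. Typing resolution may
be mixed (one to four numeric fields). All population-level statistics are
computed at two-field (protein-level) resolution so that cohorts typed on
different platforms are comparable; phasing consistency is checked at the
full typed resolution, and reports keep the maximum known resolution.
Leading zeros are preserved as text but comparisons use the integer value of
each field, so `B*07:02` and `B*7:2` are the same allele. Expression-suffix
letters are accepted on parse and retained in the raw string but ignored in
comparisons; they do not occur in classical two-field data.

## Segregation phasing

Phasing is an exact constraint-satisfaction search. Child transmission-label
assignments are enumerated — 4 per child, with the global within-parent
relabelling symmetry removed by fixing the first genotyped child's labels —
and, given labels, loci are independent: at each locus the compatible
placements of the parental allele pairs are derived by constraint
propagation, with a wholly or partially ungenotyped parent's alleles entering
as free variables pinned by the children. At family scale (≤ ~8 children)
the enumeration is effectively instant, so no heuristic acceleration layer
exists; the search itself is the reference algorithm, and the test suite
additionally checks it against an independently written brute-force
enumerator on simulated families.

Diagnostics, in decreasing order of preference when explaining a conflict:

* **dropout_resolved** — a parent recorded homozygous conflicts with
  offspring in a way explainable by exactly one hidden allele (allelic
  dropout, the common typing artefact in which one allele of a heterozygote
  goes undetected). Solutions are ranked by number of repairs and the
  minimum-repair solutions are reported, i.e. dropout is only invoked when
  no repair-free explanation exists.
* **ambiguous_phase** — more than one placement class survives at a locus
  (for example, both parents share the same heterozygous pair and every
  child is heterozygous). The locus is recorded as unknown in the affected
  haplotypes and excluded from that locus's frequency denominator. Note the
  undecidability is informational, not algorithmic: no method could phase
  such a locus from genotypes alone.
* **recombination_candidate** — no label assignment is globally consistent,
  but flipping a single child's label at a single locus would rescue it.
  Such families are excluded from the founder pool by default
  (`keep_recombinants` retains them with flagged loci set to unknown),
  because the pool is defined over intact haplotypes.
* **mendel_error** — an irreparable inconsistency.

A family with one ungenotyped parent is eligible only if it has at least two
genotyped children that are not HLA-identical to each other; the missing
parent's haplotypes are then reconstructed per child as the child allele
minus the genotyped parent's contribution. Loci where subtraction is
underdetermined remain unknown. With both parents ungenotyped the family is
ineligible.

Founder haplotypes — two per genotyped-or-reconstructed founder — form the
`HaplotypePool`. Multi-generation pedigrees are decomposed into nuclear
families; only grandparents and marry-in spouses are founders, because
middle-generation haplotypes are copies. Within a parent, the two haplotypes
are ordered lexicographically by their rendered form so that output labels
(a, b for the father, c, d for the mother, onwards for marry-ins) are
reproducible.

### Known limitation: detectability of dropout

A hidden parental allele transmitted to no child is invisible (probability
2^-c per dropout with c children), and a transmitted one can still be masked
when the other parent carries the same allele and every carrier child's
genotype is {recorded, hidden} — the no-repair explanation is then globally
consistent and, being minimal, is preferred. The repair-rate guarantee in the
test suite is therefore stated over *unambiguously detectable* dropouts
(transmitted and not masked), where the observed repair rate is ≥ 99% with
zero spurious repairs.

## Locus statistics

Frequencies are estimated over founder gene copies; the default denominator
is the number of copies with a known allele at the locus (`known`), with
`total` available because printed tables sometimes divide by the full pool
size. Genotype-based statistics (observed heterozygosity, power of
discrimination, Hardy–Weinberg tests) use founder genotypes only: children
duplicate parental gene copies and would pseudo-replicate the sample. PD is
computed from observed genotype frequencies rather than HWE-expected ones;
this is the interpretation risk inherited from forensic practice and is
stated here once. The 2N/(2N−1) small-sample factor on expected
heterozygosity is available but off by default. DPA1 and DPB1 are excluded
from HWE/PIC/PD/neutrality testing by default, as conventional for the
tightly linked DP pair.

**Hardy–Weinberg (Guo–Thompson).** The test statistic is the conditional
probability of the genotype table given the allele counts. The null
distribution is sampled by direct permutation: conditional on allele counts,
HWE makes the table distributed exactly as a uniformly random pairing of the
2n gene copies, so shuffling the copies and pairing them draws i.i.d. null
tables. This replaces the often-used Markov chain with switch proposals: the
chain's proposal is not symmetric in table space, a correct implementation
needs Hastings corrections, and the permutation route is simpler and exact.
The p-value is the fraction of sampled tables (observed included) with
conditional probability at most the observed one. A full-enumeration oracle
(`hwe_exact_enumeration`) is provided for small tables and the sampler is
validated against it; under simulated HWE the p-values are
Kolmogorov–Smirnov-uniform.

**Ewens–Watterson neutrality.** Null allele-count configurations are drawn
under the Ewens sampling formula conditional on (n, k) by rejection from the
Chinese restaurant process; conditional on k the configuration law is free of
θ, so any θ gives exact draws and θ is tuned to E[k] = k purely for
acceptance efficiency (Slatkin's approach). `Fnd` is the deviation of the
observed homozygosity Σpᵢ² from the null mean in null standard-deviation
units; one-sided p-values are reported in both directions. An exact
enumeration over integer partitions of n with k parts (configuration weight
∝ n!/∏ⱼ j^{aⱼ} aⱼ!) anchors the sampler for small n. Degenerate cases k = 1
and k = n are flagged rather than tested.

## CEH detection, naming, ancestry

Five-locus C–B–DRB1–DQA1–DQB1 blocks are counted over the founder pool at
two-field resolution; haplotypes unknown at any of the five loci are excluded
from numerator and denominator. Blocks at or above the frequency cutoff are
CEHs. The literature convention for a common CEH is 0.005; the package
default is 0.02, appropriate for cohorts of a few hundred haplotypes where a
0.005 cutoff would admit single observations. A minimum-count pre-filter is
exposed separately (`min_count`, default 0) because a count threshold and a
frequency threshold disagree at the margin and the frequency cutoff is
treated as authoritative.

Names follow the serological-lineage convention: the HLA-B lineage label
(from a small packaged B-allele → lineage map, falling back to field 1 of the
B allele) plus the next sequential number within that lineage. The packaged
registry seeds the historically named 8.1, 8.2, 58.1 and 60.1–60.3 with
their five-locus compositions, and reserves 51.1 as a lineage placeholder
(its published composition is not carried here), so that a newly observed
B*51:01 CEH is minted 51.2. Queries with a missing locus are treated as
wildcards when matching the registry; pool counting always uses all five
loci.

Extension profiles tabulate the HLA-A alleles and DPA1–DPB1 blocks among
carriers of the full five-locus CEH, as percentages of the CEH count, rounded
half-up to one decimal (matching printed-table convention, e.g. 5/16 →
31.3%). Most-probable ancestry assigns every continental group whose
reference frequency for the CEH exceeds a threshold (default 0.10); ties
report all regions, absence reports unassigned. The packaged reference table
is a synthetic stand-in encoding only the ancestry assignments used in the
packaged result tables; real analyses should supply published continental
frequencies.

## Population comparison

Nei's DA is the unweighted mean over shared loci of 1 minus the Bhattacharyya
coefficient Σ√(xᵢyᵢ), with allele universes unioned per locus. It is
symmetric, zero on identity and bounded in [0, 1], but it is not a metric
(no triangle inequality), which is acceptable for neighbour joining.
Neighbour joining, the distance-matrix container and Newick serialization are
delegated to scikit-bio; negative branch lengths are clamped to zero by
default. Bootstrap support resamples loci with replacement (`loci` mode, the
classical design — degenerate with only three loci, which is reported rather
than hidden) or resamples gene copies multinomially per population per locus
(`genes` mode, requiring sample sizes); support is the percentage of
replicate trees containing each internal bipartition. PCA mean-centres the
concatenated allele-frequency matrix and takes the singular value
decomposition; scores are invariant to allele column order.

No published population frequency datasets are redistributed; the comparison
module consumes a generic population–locus–allele–frequency TSV.

## Synthetic cohorts

The generator emulates a two-generation family study design with one
three-generation pedigree: founder haplotypes are drawn per locus from
configurable spectra (default: geometric with ratio 0.8 and the per-locus
allele counts observed in the packaged tables — 31, 29, 41, 30, 13, 15, 8,
20 — giving one dominant allele and a long tail), children inherit whole
haplotypes, and typing artefacts are layered on the observed genotypes only.
Defaults are the study design: 40 two-generation families with 2–5 children,
plus a three-generation family whose 3 marry-in spouses bring the founder
pool to 170; noise rates default to zero and are switched on per experiment.
Because loci are drawn independently, unseeded cohorts contain no conserved
blocks; linkage exists only within families, and the optional CEH seeding
(a fixed five-locus block substituted into a Bernoulli fraction of draws) is
the mechanism for testing CEH recovery. Consequently, passing tests
demonstrate correctness of phasing, counting and inference mechanics — not
realism of MHC linkage disequilibrium, which the generator deliberately does
not model (no coalescent, no mutation, no population structure).

## Numerical and design choices

* Frequencies and statistics are computed in double precision from integer
  counts; printed-style outputs round half-up where tables conventionally do.
* The phasing search prefers minimum-repair solutions; among equals, the
  per-locus union of surviving placements defines ambiguity.
* NJ ties and orientation are delegated to scikit-bio's deterministic
  implementation; bootstrap and simulation randomness flow from a single
  `numpy` `default_rng` seed per entry point, so identical seeds give
  byte-identical outputs.
* Test problem sizes: phasing ground-truth recovery uses 100 seeded cohorts
  of 2 families; HWE uniformity uses 500 simulated four-allele tables of 50
  diploids at 2000 permutations each; the Ewens–Watterson sampler is checked
  against full enumeration for n ≤ 10; NJ is checked on 100 random additive
  matrices of 4–8 taxa. These sizes make the whole suite run in about a
  minute on a single core while keeping every Monte-Carlo band at 3σ.

## Known discrepancy in the packaged tables

The packaged allele-count tables reproduce their printed frequencies at
printed precision against the per-locus known denominators (170, with 169
for DQA1 and 167 for DQB1 — one and three genotypes missing) with a single
exception, DRB1*01:02 (count 6 printed as 0.03 where 6/170 rounds to 0.04),
preserved verbatim. Botstein PIC computed from the packaged HLA-DQA1 counts
is 0.813 → 0.81 at two decimals regardless of denominator choice; the
published 0.82 is not reproducible from the printed counts (the DQB1 counts
over their known denominator 167 do give 0.82, suggesting a table or input
mix-up upstream). The package reports the computed value.
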