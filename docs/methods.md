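# Methods

## Rate estimation

**Mutation classification.** All statistics rest on classifying an observed
codon change as nonsynonymous (N) or synonymous (S) under the standard
genetic code (bacterial table 11, identical to the universal code on the 61
sense codons). Codons differing at one position are classified directly by
amino-acid identity. For two or three differing positions, all minimal
mutational pathways (orderings of the single-base steps) are enumerated;
pathways passing through a stop codon are discarded and the N/S step counts
averaged over the remainder. If every pathway passes through a stop (a rare
corner of codon space), all pathways are used so the pair still receives a
classification. The N and S fractions of a pair always sum to the Hamming
distance between the codons. A 64×64 lookup table is precomputed once, so
column classification over whole alignments is vectorised.

**pN/pS (polymorphism).** A raw count ratio, intentionally not normalised
by mutational opportunity: within one genome all genes share the same code
and roughly the same opportunity structure, so raw counts preserve the
ranking while staying simple and assumption-light. Codon columns containing
a gap, an `N`, or a stop codon in any row are excluded wholly, which avoids
frame ambiguity at the cost of discarding some sites; the retained-column
count is reported per gene. With two rows (the dominant case for
closely-related-strain clusters) differing codons are classified pairwise.
With more rows the majority codon of a column is taken as the base state
(ties resolved to the reference row's codon; if the reference codon is not
among the tied modes, the lexicographically smallest mode — a deterministic
rule for a case the data rarely produce) and each *distinct* variant codon
is classified against it once. This is allele counting, not sequence
counting: duplicating a row never changes the counts. When S = 0 the ratio
is formed as N/1 and flagged `s_corrected`; this keeps genes with purely
nonsynonymous polymorphism in the analysis rather than dropping exactly the
interesting tail.

**dN/dS (divergence).** Nei–Gojobori (1986) counting on a sequence pair.
Per codon, the nine single-base mutants are enumerated; mutants that are
stop codons are removed from the opportunity, and each position contributes
the synonymous fraction of its remaining mutants to the S site count (the
rest to N), so N + S = 3 × (codons used) per sequence. Site counts are
averaged over the two sequences. Observed differences are classified with
the pathway-averaged table, giving proportions pN\* = Nd/N and pS\* = Sd/S,
each corrected for multiple hits with Jukes–Cantor, d = −(3/4)·ln(1−4p/3).
A proportion ≥ 3/4 is beyond the correction's domain; the estimate is
flagged unusable (ratio NaN) rather than extrapolated. When Sd = 0 with
Nd > 0, the ratio falls back to the uncorrected pN\* over a unit
denominator and is flagged — the divergence analogue of the pS→1 rule.
Like that rule, the fallback is discontinuous at Sd→0 and flagged estimates
should be interpreted as order-of-magnitude lower bounds on constraint.

**Recombination screen.** Recombination inflates apparent divergence
heterogeneity and undermines dN/dS. Genes are screened with the four-gamete
test: over all pairs of biallelic nucleotide sites (unambiguous bases, no
gaps), a pair exhibiting all four haplotypes implies recombination or
recurrent mutation. Flagged genes are excluded from dN/dS comparisons and
summaries but retained for pN/pS, which is robust to within-species
exchange of allelic variation. With fewer than four sequences the test
cannot trigger and returns a clean result.

## Gene-set comparison

Genes are partitioned into mutually exclusive sets: any drug target is ADT
regardless of essentiality, essential non-targets are ESS, and ALL is the
background with both other sets removed, so the comparisons are between
disjoint samples. The three pairwise comparisons (ADT–ALL, ADT–ESS,
ESS–ALL) use the two-sided Mann–Whitney U test; the null is exact when the
smaller group has ≤ 8 observations and there are no ties, and the normal
approximation with tie and continuity corrections otherwise. Unusable
estimates (no polymorphism observed, saturated divergence) are excluded
before testing and the exclusions are logged per stage, since silent
filtering is the easiest way for such an analysis to mislead.

P-values are adjusted with the Benjamini–Yekutieli step-up procedure,
valid under arbitrary dependence — appropriate because the three tests per
species share samples. Adjustment is applied jointly across the whole
family of a run (3 tests per species per statistic; 24 in an
eight-species design; when both statistics are computed each gets its own
independently adjusted family). Set means are reported with 95% percentile
bootstrap confidence intervals (default 2000 resamples, seeded) because
pN/pS distributions are strongly skewed.

## Ranking and enrichment

Usable genes are sorted ascending by ratio; rank 1 is the slowest. The
reported percentile is 100·midrank/n (tied ratios share a percentile; the
integer rank breaks ties by gene id so ranks remain a permutation of
1..n). Any standard percentile convention shifts results by under one
percentile at genome scale. KO orthology groups are summarised by the mean
and sample SD of their per-genome ratios; a group observed in a single
genome reports SD 0 by convention. The study set for enrichment is the
slowest floor(0.10·n) genes (floor, not round — a conservative study set;
boundary ties broken by gene id, logged).

GO annotations are closed upward through is_a and part_of edges only (the
standard propagation relations) before counting; the ontology graph must
be acyclic over those edges. Each term annotating at least one population
gene is tested with the one-sided hypergeometric tail
P(X ≥ study_count), X ~ Hypergeom(pop_n, pop_count, study_n). Raw
p-values are the primary output, with a Benjamini–Hochberg column
alongside; genes without any annotation remain in the denominators by
default (an `annotated_only` switch removes them), since GO coverage of a
genome is typically partial.

## Ortholog resolution

Clusters with more than one member per genome are reduced to one-to-one
pairs by reciprocal best hits under a deterministic similarity: global
protein alignment with BLOSUM62 and affine gap penalties (open −11,
extend −1, the familiar protein-search defaults). The reference genome
must be single-copy in the cluster; for each other genome the reference's
best hit is kept only if that candidate's own best hit among all other
genomes' members is the reference gene. Genomes without a reciprocal best
hit are dropped rather than guessed — conservative, and consistent with
requiring one-to-one orthology. Score ties break lexicographically by gene
id and are logged.

## The simulator and what it does (not) show

The generator emulates a strain-level polymorphism study with known truth.
Per gene, an ancestral CDS (ATG followed by uniform sense codons) is
evolved independently along each of `rows_per_cluster` branches (star
topology — appropriate for closely related conspecific strains and free of
recombination, so the four-gamete screen stays clean). Evolution proposes
Poisson(subs/codon × codons) single-base changes at uniform sites;
proposals creating stops are rejected, synonymous proposals are always
accepted, nonsynonymous ones with probability min(1, ω). Accepted counts
are recorded exactly, giving a per-gene truth table.

Defaults are the study conditions: 1000 background / 300 essential / 35
target genes (an E. coli-like genome scaled to desk size), 300-codon
genes, clusters of 2 (the dominant real cluster size), 0.2 proposed
substitutions per codon (strain-level divergence where multiple hits per
codon are uncommon), ω = 0.6 / 0.3 / 0.1 for background / essential /
targets (background below 1 because most coding sequence is under some
constraint; targets strongly constrained), and a slow GO term whose odds
are multiplied by 8 on target/essential genes over a base rate of 0.08.
Acceptance thinning makes counted pN/pS approximately proportional to ω —
exactly the property the pipeline is supposed to exploit — so passing
parameter-recovery tests demonstrates that the estimator-plus-testing
chain recovers ordinal differences in constraint. It does *not*
demonstrate robustness to alignment error, indels, codon-usage bias,
selective sweeps, demography or linkage, none of which the generator
models.

## Numerical and design choices

- Deterministic throughout: one integer seed drives simulation, bootstrap
  and everything downstream; reruns are byte-identical and every report
  carries a provenance block (config hash, seed, library versions,
  filter-step counts).
- Problem sizes in the test suite are scaled so the whole suite and the
  acceptance script each run in well under a minute on one core; the
  parameter-recovery check uses 20 replicates of the full default
  conditions.
- Columns with gaps/ambiguity are dropped rather than partially scored;
  genes reduced to zero usable columns are carried through flagged
  unusable, never silently removed from tables.
- The multi-row polymorphism path (clusters of > 2 strains) is the least
  exercised by real data (~95% of clusters are pairs) and its majority-base
  convention is a documented choice, not a community standard.

## Known limitations

- Raw-count pN/pS is not comparable across genomes with very different
  codon usage; it is a within-genome ranking statistic.
- NG86 + Jukes–Cantor underestimates ω at high divergence and is restricted
  here to sequence pairs; the estimator sits behind a single function so a
  likelihood-based alternative can be swapped in.
- The four-gamete screen cannot distinguish recombination from recurrent
  mutation and has no power below four sequences.
- The hypergeometric term-for-term test treats genes as exchangeable and
  ignores the ontology's dependence structure between terms.
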