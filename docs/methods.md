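# Methods

## The problem

Eplet and PIRCHE-II scoring both require two-field HLA genotypes; routine
deceased-donor typing provides serological split antigens, each covering
many alleles.  `epimatch` treats the missing resolution as a statistical
imputation problem: the haplotype-frequency table is the prior over
five-locus genotypes, the typing is the observation, and the epitope value
is reported as a posterior expectation over all genotypes consistent with
the observation.

## Genotype imputation

**Candidate enumeration.**  For a phenotype (per-locus sets of one or two
typing values over HLA-A, -B, -C, -DRB1, -DQB1; loci may be absent), every
unordered pair of candidate chromosomes is kept whose serological (or
two-field) projection reproduces the phenotype *exactly* at each covered
locus: each phenotype value is hit by at least one chromosome and no extra
value appears.  A single value at a locus is read as a true homozygote at
the typed resolution (the serological convention); the
`single_as_unknown` flag switches to the "second value unknown" reading.

**Linkage schemes.**  Candidate chromosomes are assembled from blocks of
linked loci.  The ladder of schemes, tried in order until one yields at
least one candidate, is

1. `A-B-C-DRB1-DQB1` (whole table haplotypes),
2. `A-B-C | DRB1-DQB1`,
3. `A | B-C | DRB1-DQB1`,
4. `A | B-C | DRB1 | DQB1`,
5. `A | B | C | DRB1 | DQB1`.

A block's frequency is its marginal in the table (sum over all haplotypes
agreeing at the block's loci); a chromosome's frequency is the product of
its block marginals, so scheme 5 reduces to per-locus allele frequencies —
an identity the acceptance suite checks directly.  Fallback is *global*:
one scheme per call, both chromosomes built under the same scheme.  A
per-chromosome mix (one side at a tighter scheme than the other) is a
conceivable alternative reading of step-wise linkage removal; we implement
and document the global form only.  All cross-block phase assignments are
enumerated and duplicate unordered genotypes merged by summing frequency.
If even scheme 5 yields nothing (a typed antigen with no mapped allele
anywhere in the table), the phenotype is *unimputable*; couple-level code
counts such cases and excludes them from statistics rather than aborting.

**Weights.**  A candidate genotype's absolute frequency is the product of
its two chromosome frequencies.  By default no Hardy-Weinberg factor 2 is
applied to heterozygous pairs — the weight is the literal frequency product
— because only relative weights within the candidate set matter and the
plain product is the simplest auditable rule; the `hw_factor` flag applies
the ×2 convention for users who want HW-correct absolute values.  Weights
are the absolute frequencies normalized to sum to one; the weighted score
is `Σ w_d · w_r · score`, with donor and recipient imputed independently.
A configurable candidate-pair cap (default 10⁶) turns combinatorial
explosions under scheme 5 into a typed error instead of an apparent hang.

## Epitope engines

**Eplets.**  The registry maps each allele to its set of eplet names.  A
mismatched eplet is present on at least one donor allele and absent from
every recipient allele, pooled across all five loci on both sides
(interlocus comparison); `per_class` restricts pooling to within class I
and class II separately, a variant some workflows use.  The count is the
size of the mismatched-eplet set.

**PIRCHE-II.**  Donor alleles absent from the recipient at two-field level
are scanned into overlapping peptides (default 15-mers, step 1 — the
class-II convention; configurable).  Each peptide is scored against each
recipient DRB1 allele by a pluggable predictor returning a 9-mer binding
core and an IC50; predictions with IC50 strictly below 1000 nM count as
binders; binders whose core occurs as a substring of *any* recipient HLA
protein (all five loci) are discarded as self.  Surviving cores are
deduplicated globally — one unique core is one PIRCHE-II regardless of how
many donor alleles or DRB1 molecules produced it; `per_drb1` switches to
counting per presenting DRB1 allele.  Global deduplication is the
conservative choice where counting scope is a modelling decision.

**Predictor contract.**  Any callable `(peptide, DRB1 allele) →
(core, IC50)` plugs in; an adapter around an external neural-network
predictor fits this contract.  The shipped `mock_predictor` is
deterministic and seed-free: the core is the 9-mer window minimizing an
MD5-based hash of `(window, allele)` (leftmost tie-break), and the IC50 is
a monotone transform of that hash into (1, 50000) nM.  With a 15-mer
peptide the minimum over seven windows lands below 1000 nM for roughly an
eighth of random peptides, so synthetic worlds contain both binders and
non-binders reproducibly.  The mock models no binding chemistry; it
exercises the pipeline's combinatorics (threshold filter, self-core
exclusion, deduplication) exactly.

## Virtual populations and couples

Individuals are two haplotypes drawn from the table.  The default `iid`
policy draws independently with probability proportional to frequency; the
`finite_pool` policy apportions a discretized pool of copies
(largest-remainder rounding) and consumes it without replacement, for users
who want draws from a finite registry.  Couples are formed per recipient:
donors are drawn uniformly from the remaining pool until one satisfies the
allocation rule — at most 3 broad-level mismatches at HLA-A plus HLA-B and
at most 1 at HLA-DR — and accepted donors leave the pool, so donors are
never reused.  Mismatches are counted on antigen *sets*, so a homozygous
donor contributes one antigen.  A retry cap (default 10⁵ draws per
recipient) guarantees termination on incompatible pools.

## Delta statistics

Observed (imputed) and reference (two-field) values are compared as
`delta = ln(observed) − ln(reference)`; |delta| > 1 is flagged as a high
deviation.  Zero counts are handled by an explicit policy: `exclude`
(default) drops the couple and reports how many were dropped; `add_one`
applies `ln(x+1)` to both sides and flags the couple.  A couple counts as
zero-delta iff |delta| < 10⁻¹²: exact float equality is meaningless after
weighted summation, and 10⁻¹² comfortably exceeds accumulated rounding
while being far below any real deviation.  Percentile spreads at 50 / 75 /
95 / 99 / 99.9 % are two-sided around the median — the quantiles at
(50 ± level/2) % — computed with linear interpolation between order
statistics (the method is named in the summary output so results are
comparable across tools).

## Synthetic worlds

`generate_world(seed, params)` builds a complete, bit-reproducible input
set.  Alleles are named `L*ss:jj` where `ss` is the split-antigen index, so
serological degeneracy is structural: `alleles_per_split` controls how many
alleles hide behind each split (the ambiguity dial), `splits_per_broad` how
splits collapse to broads.  Protein sequences are uniform random 20-letter
strings; eplet sets are draws from a shared pool, giving controlled
sharing.  The frequency table samples `n_haplotypes` distinct five-locus
combinations with Dirichlet(0.35) frequencies — skewed like real truncated
tables, so rare-haplotype behaviour and the fallback ladder are exercised.
Alleles that end up on no sampled haplotype are dropped from the world's
allele lists and reported.

What the worlds deliberately do **not** emulate: real linkage
disequilibrium structure (haplotype membership is uniform before
weighting), real protein homology (sequences are independent, so self-core
filtering fires less often than with paralogous HLA sequences), curated
eplet definitions, and a trained binding predictor.  Passing tests
therefore demonstrate the correctness of the computation — enumeration,
weighting, filtering, counting, statistics — not the clinical accuracy of
imputed scores on real registries, which depends entirely on the quality
of the supplied frequency tables, serology dictionary, registry and
predictor.

## Study conditions in `scripts/acceptance.py`

The scripted study uses a world with 8 alleles per locus, degeneracy 2, 4
splits over 2 broads per locus, an 80-haplotype table, 50-residue proteins,
and 6 eplets per allele from a 60-eplet pool; a 600-donor pool and 150
recipients.  These sizes keep split typings genuinely ambiguous (several
candidates per side) while candidate cross-products remain small enough for
exact, exhaustive scoring of every couple under every scenario; the
reported fractions are descriptive statistics of that run, seeded entirely
from `--seed`.

## Known limitations

- Serological *broad*-level typings are accepted by the data model but a
  broad value cannot be refined to split, so broad-only inputs generally
  impute poorly; split-level input is the intended resolution.
- GL strings, allele codes, and G/P-group nomenclature are not parsed.
- DRB3/4/5, DQA1 and DPB1 are rejected: the model is fixed to the five
  loci above, and frequency tables covering other loci need remapping
  before use.
- Engine scores are memoized per genotype pair; the cache is a plain dict
  with no eviction or concurrency guarantees.
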