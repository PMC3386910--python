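# Methods

## The mapping model

The unit of mapping is the transcript model, not the genome: reads are matched
against a transcriptome of predicted coding sequences (plus any auxiliary
sequences appended to the FASTA, e.g. rRNA intersegments). Reads are assumed
to be single-end, of fixed length L equal to the snippet length (36 or 42 nt
is the design point), and are matched **exactly** — no mismatches, indels or
splicing. Robustness to sequencing error is achieved not by tolerant
alignment but by removing every mapping target that could be reached from
another gene by a single substitution.

The pipeline has five phases, each shrinking the set of usable targets:

1. **Index preparation.** Every L-window of every gene becomes a snippet,
   addressed by its integer start offset in the gene-concatenated
   transcriptome (snippet 0 is the first base of the first gene). The window
   step is 1: that is forced by the integer-offset addressing, which leaves a
   status slot for every position. Genes shorter than L contribute nothing.
   A status array over all offsets starts as MAPPABLE; an auxiliary array maps
   offsets back to gene ordinals.
2. **Intra-gene duplicate masking.** Within each gene, independently, every
   snippet whose L-mer occurs two or more times in that gene is masked — *all*
   copies, not all-but-one, because the aim is to remove low-complexity
   sequence (e.g. extended trinucleotide repeats) from the target set
   entirely, and because exact-match safety requires that no ambiguous target
   survive. Snippets overlapping an ambiguous base (anything outside A/C/G/T)
   are masked here too: exact matching cannot use them, but the gene itself is
   kept at full length rather than silently dropped.
3. **Collective building.** Still-mappable snippets from different genes are
   compared; the number of identical snippets per gene pair is tallied in a
   sparse matrix. A pair links when the shared count exceeds 50 % of the
   smaller gene's still-mappable snippet count AND the two lengths differ by
   at most a factor of 2. Collectives are the connected components of the
   link graph; each gets one synthetic collective-gene entry appended after
   the real genes. Two choices here were genuinely open:
   - *Denominator of the shared fraction*: the smaller gene's mappable
     snippet count. This is the symmetric, permissive reading and makes an
     identical pair score exactly 100 % even when the gene contains internal
     repeats that phase 2 removed.
   - *Closure*: transitive (components), not pairwise. Overlapping qualifying
     pairs merge; this is what allows large families (tens of members) to form
     a single collective even when the most diverged pair of members would
     not link directly.
4. **Robust-uniqueness masking.** A snippet survives only if no snippet of a
   different gene *outside its collective* is identical to it or differs at
   exactly one position. The contract is expressed as L+1 passes: pass 0
   groups snippets by the full L-mer; pass p (1…L) groups by the L-mer with
   position p ignored. The implementation collects marks against the full
   phase-entry set and applies them at the end, so the surviving set is
   exactly the brute-force census
   `{s : no entry snippet s' with gene(s') outside collective(s) has
   Hamming(s, s') <= 1}` and is independent of pass order; the pass counter
   still reports L+1 (43 for L=42), which the `index` command logs.
   Within-collective duplicates are deliberately *not* masked — they are the
   collective gene's counting territory. Within-gene pairs at Hamming
   distance exactly 1 are also not masked: the cross-gene rule does not apply
   to them, and phase 2 already removed exact within-gene duplicates.
5. **Read mapping.** A read (or, with `orientation="both"`, its reverse
   complement when the forward sequence misses — the default, since short
   mRNA-Seq of this design is typically unstranded) is looked up among the
   surviving snippets. A surviving L-mer present in one gene credits that
   gene; one present in several genes necessarily lies within a single
   collective (phase 4 guarantees this; the mapper asserts it rather than
   tie-breaking) and credits the collective gene. Reads of the wrong length
   are tallied and skipped, not fatal; an optional flag truncates longer reads
   to their first L bases (off by default). Positional profiles count matches
   per snippet start; a collective gene's profile uses the coordinates of its
   lowest-ordinal member, a bookkeeping choice with no downstream consumer.

**Consequence for error robustness:** on a transcriptome where all cross-gene
snippet pairs are at Hamming distance ≥ 2 (masking removed everything closer),
a read carrying at most one error can never be counted to a wrong gene — it
either exactly matches a snippet of its source gene or goes unmapped. The test
suite checks this by enumerating all one-base mutants of masked snippets.

## Quantification

- **Normalized hits**: gene count / total mapped reads in the sample
  ("fitted" and "mappable" reads are treated as the same denominator — the
  total of reads assigned to any gene or collective gene; no distinct reading
  is defensible). They sum to 1 per sample.
- **RPKM** = count / (length/10³) / (total mapped/10⁶). Per gene, RPKM equals
  normalized hits × 10⁹/length, a relation the tests cross-check. A
  collective gene's nominal length is the rounded mean of its members'
  lengths; only RPKM uses it.
- **Regulation factor**: mean normalized hits over mutant replicates divided
  by the mean over wild-type replicates, computed per growth stage. When
  either side's mean raw count is zero, a pseudocount (default 0.5 reads,
  CLI-exposed) is added to every raw count on both sides before normalization;
  with a zero pseudocount and both sides zero the factor is NaN and flagged.
  Swapping the two sides inverts the factor exactly.
- **Unit-sum profiles**: a gene's time-course counts divided by their total,
  making shapes comparable across expression levels; group profiles are
  unweighted means of member profiles and also sum to 1. All-zero series are
  excluded from groups and reported.
- **Profile comparison**: Pearson χ² homogeneity test on the 2×T table of raw
  counts (two series as rows), T−1 degrees of freedom, no continuity
  correction; time points where both series are zero are dropped and the df
  reduced. This is the plain reading of "chi-squared comparison of profiles";
  which genes to pool into each series is the caller's choice.

## Selection

Candidates are genes or collectives with a linear regulation factor ≥ 2
(boundary inclusive) in growth and/or development. On the log₂ scatter of the
two factors, Euclidean distance 0.5 from the origin corresponds to a combined
linear change of 2^0.5 ≈ 1.41, i.e. ~40 % up- or down-regulation. Candidates
are screened by a pluggable two-condition count test; the built-in default is
the exact conditional binomial test (replicates pooled per condition; given
the gene's total reads k, the mutant share is Binomial(k, N_mut/(N_mut+N_wt))
under the null). This default is deterministic and dependency-free but
dispersion-blind, hence anti-conservative under biological overdispersion —
a negative-binomial test can be plugged into the same slot. Adjustment is
Benjamini–Hochberg (the standard choice where the adjustment method is
otherwise unspecified); adjusted p < 0.05 is retained. Classification into
mutant-repressed / mutant-activated / developmentally-induced-but-independent
uses disjoint fold bands (≥ 2, ≤ 1/2, and the open interval between).

## Synthetic data

`synth.SimSpec` defaults describe a modest but structurally faithful dataset:
~20 singleton genes of length 1000 ± 200 nt (floor 200), two families of three
members diverged 0.005 substitutions/site from a common ancestor, 42-nt reads,
error-free by default, 10⁴ reads per sample. Families are generated by
mutating each member independently from one random ancestor, so two members
agree at a site with probability (1−d)² + d²/3 and share a whole window with
probability ≈ that to the power L; at d = 0.4 the expected shared fraction is
~10⁻¹⁶ (no collectives), while at d ≤ 0.002 with ≥ 800-nt genes family
recovery as a single collective is essentially certain. Reads take uniform
start positions within genes, weighted by per-gene abundance × number of start
positions, with independent per-base substitution errors (an indel would have
the same effect as a substitution under exact matching — a guaranteed miss —
so the substitution-only model loses no generality). A read maps only if all
L bases are error-free, probability (1−e)^L. Programmed fold changes
multiply abundances in the "mutant" condition; the generative expectation for
the recovered regulation factor is the fold times the wild-type/mutant
total-weight ratio (`expected_regulation_factor`), since normalized hits share
a per-sample denominator. A cell-cycle mode shapes expression as a von Mises
bump around a peak phase averaged over a wrapped-normal population phase
dispersion; dispersion flattens the observed modulation, which is how
imperfect synchronization damps time-course amplitudes.

What the generator does **not** emulate: base-quality structure, GC or
positional bias, fragment-length effects, annotation errors, or expression
correlation across genes. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated generative model,
not performance on any particular real library.

## Numerical and scale choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; replicates and conditions derive decoupled
  streams from (seed, replicate, CRC32(condition)).
- Equivalence tests against the brute-force Hamming census use transcriptomes
  of a few genes × a few hundred nt, 100 random instances; fold-recovery
  fixtures use 100 genes with two replicates per side at 4–6 × 10⁴ reads per
  sample — sizes at which binomial standard errors are small relative to the
  programmed effects.
- The acceptance script simulates 50 family-bearing transcriptomes (2–4
  families of 2–7 members each, divergence 0.002, 800-nt family genes) and
  reports the minimum collective size over all runs.
- Conservation tolerances: normalized hits and unit-sum profiles are checked
  to 10⁻⁹; exact-count identities (profile sums, totals) are integer
  comparisons.

## Known limitations

- The exact conditional binomial default test ignores biological dispersion;
  with two biological replicates its calls are optimistic.
- Collective membership is decided once, after optional record splitting at
  load time; there is no interactive re-run after splits.
- Reads longer than L are not mapped unless truncation is enabled; paired-end
  data, spliced alignment and SAM/BAM output are out of scope by design.
- Memory layout is functional, not a reproduction of the original
  hash-table-in-1-GB engineering.
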