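# Methods

`bivirome` implements the post-assembly stages of a transcriptome-based
RNA-virus survey, of the kind applied to filter-feeding bivalves whose
RNA-seq samples accumulate viral sequences from both genuine infections
and environmental carry-over.  The package covers candidate screening,
abundance and contamination profiling, editing-footprint detection, a
permutation test of dinucleotide under-representation, and small-RNA
evidence for host assignment.  A synthetic-data module generates every
input, so each stage is testable without external downloads.

## Viral candidate screening (`bivirome.screen`)

Contigs are scanned in six frames for maximal open reading frames.  An ORF
qualifies when its encoded protein (start codon included, terminal stop
excluded) has at least `min_codons` residues (default 100).  Complete ORFs
run ATG→stop entirely inside the contig, using the earliest ATG after the
previous in-frame stop; ATG-initiated ranges that run off the contig edge
are reported as incomplete and never satisfy completeness.

Similarity evidence is consumed from external search tools (BLAST
tabular, HMMER `--domtblout`), not recomputed.  A query is retained with
either ≥ 5 distinct blastp subjects at E ≤ 1e-50, or one hit to a viral
RdRp PFAM domain (PF00680, PF00978, PF00998, PF02123, PF07925, PF04197)
at E ≤ 1e-5.  Duplicate HSPs against the same subject count once — the
hit-count rule is meant to demand independent corroboration, and HSP
fragmentation would inflate it.  The five-hit rule is applied to the
blastp route only; the RdRp-domain route is treated as sufficient on its
own.  Candidates matching host genome scaffolds at E ≤ 1e-5 are removed.

Candidate proteins are clustered greedily, longest first (ties broken
lexicographically), joining the first representative at identity ≥ 0.90.
Identity is defined as the maximal number of matched positions achievable
by a global alignment divided by the shorter sequence length.  With no
mismatch or gap penalties the match-maximizing alignment is the longest
common subsequence, so the identity is computed by LCS dynamic
programming — deterministic and parameter-free.

A candidate genome is *nearly complete* iff its contig exceeds 5 kb
**and** carries at least one complete ORF; both conditions are strict.
PolyA tails are called when any 3'-terminal window of ≥ 15 nt contains
≤ 10% non-A bases (windows up to 200 nt are scanned).  The window rule is
a detector of our own design; the length and purity defaults are chosen
so that a genuine tail with one or two sequencing errors still passes
while A-rich coding sequence does not.

## Abundance and contamination (`bivirome.abundance`)

A primary alignment counts for its reference when
`aligned_length / read_length ≥ min_len_frac` and
`(aligned_length − NM) / aligned_length ≥ min_sim_frac` — 0.9/0.9 for
viral references, 0.8/0.8 for COI contamination profiling.  The
similarity proxy treats the NM edit distance as mismatches over the
aligned span.  One read, one vote: secondary and supplementary alignments
are ignored.  Viral load is expressed per mille of total reads; samples
with ≥ 1000 summed viral reads are deemed informative.  TPM follows the
standard definition (`rate_i = count_i / length_i` normalized to 1e6);
COI profiles report entries holding ≥ 0.01% of COI-mapped reads,
descending.  Denominators count reads, not pairs.

## Editing-footprint detection (`bivirome.editing`)

Per-position pileups are built from SAM alignments (deletions excluded
from coverage).  A variant is called per alternate base when coverage
≥ 50, alternate count ≥ 5, alternate frequency ≥ 1%, and the mean base
quality over the 5-base window centered on the site (site ± 2), averaged
over the supporting reads, is ≥ PHRED 30.  The window is centered because
the site's own evidence should participate in its quality screen; its
half-width is configurable.  Frequencies are computed per alternate base,
not pooled over non-reference bases.  ADAR-compatible calls are the A→G
subset on the reported strand (T→C antisense evidence optional, off by
default).  The 5' neighbor is read from the reference consensus — the
analysis annotates genome positions, not individual reads — and the
neighbor distribution is reported over {A, C, G, T} with edge positions
excluded.

## Dinucleotide under-representation (`bivirome.motifs`)

For a coding sequence and a motif from the ADAR-relevant family WA, AA,
CA, GA, TA (edited adenosine second; W = A/T), the test compares the
observed sequence against 1000 codon-preserving shuffles:

* **below** p-value — fraction of shuffles with *strictly fewer* motif
  occurrences than the input.  `below_p < 0.05` ⇒ under-represented,
  `> 0.95` ⇒ over-represented.
* **repTrFrac** — of all motif occurrences, the fraction at which the
  A→G transition changes the encoded amino acid; its p-value is computed
  analogously over shuffles where the metric is defined (≥ 1 occurrence).
* **maximal under-representation** — below under *and* repTrFrac over:
  every synonymously removable motif has been removed, so the surviving
  occurrences are disproportionately mutation-constrained.

Occurrences are counted with overlap on the concatenated CDS, codon-
internal and codon-junction alike; each position counts once (WA does not
double-count its AA/TA members).  The terminal stop codon is stripped
before analysis so transitions never create or destroy termination.

**Shuffle design.**  Third positions are permuted within exchange classes
keyed by the *allowed third-base alphabet* — the set of bases encoding
the same amino acid in that codon box: the four-fold boxes ({A,C,G,T}),
the two-fold pyrimidine boxes ({T,C}), the two-fold purine boxes
({A,G}), isoleucine's three-fold box ({A,C,T}), and the fixed Met/Trp
positions ({G}).  Any permutation within a class preserves the protein
exactly, and being a permutation of the existing bases it preserves the
per-base multiset and hence GC content.  Classes are keyed by alphabet
rather than by codon box deliberately: confining exchanges to a single
box freezes all codon-internal occurrences (only junction occurrences,
which are always nonsynonymous for NA motifs, would vary), which
collapses repTrFrac into a monotone function of the motif count and
makes maximal under-representation unattainable by construction.  The
alphabet-keyed family lets third bases travel between boxes, giving the
two metrics independent variability while keeping both invariants exact.

**Numerical choices.**  The p-value uses strict "fewer than"; ties
contribute zero, which makes the test conservative on short sequences
where the shuffle distribution is coarse (a midrank option adding half
the ties is available, off by default).  Shuffles with zero occurrences
are excluded from the repTrFrac denominator; when the observed sequence
itself has none, repTrFrac is undefined and classified neutral.
Sequences composed solely of single-codon amino acids shuffle to
themselves, giving `below_p = 0` under the strict rule — a documented
degenerate case.  The permutation engine is vectorized (per-class
permutation via a grouped random sort; nonsynonymy via a precomputed
64 × 3 lookup), at roughly 0.15 ms per shuffle of a 500-codon CDS.

The test is exact (conditionally on the exchange-class multisets) when
codons are drawn i.i.d. with third bases uniform within their class, as
in the uniform-usage generator; strongly skewed codon usage within a
class makes the null slightly mis-specified, as for any third-position
shuffling scheme.

## Small-RNA evidence (`bivirome.smallrna`)

Read pairs are joined at the longest exact 3' overlap (≥ 10 nt);
unjoinable pairs are dropped and counted.  Fragments are profiled over
15–50 nt with the mode, the 20–22 nt (Dicer-typical) and 29–30 nt
(PIWI-typical) band fractions.  Fragments are assigned to targets by
exact substring matching on either strand (a 1-mismatch mode exists;
exact matching mirrors RNAi perfect complementarity), counting once per
target and once per overlapped ORF interval.  The degradation diagnostic
is the squared Pearson correlation between per-ORF fragment counts and
expression: counts that track expression indicate degradation products,
while expression-independent counts with a high 20–22 nt fraction
indicate genuine RNAi-derived small RNAs.  No hard classification
threshold is imposed — the outputs are descriptive, anchored by the two
synthetic reference points below.

## Synthetic data (`bivirome.simulate`)

The generators emulate the statistical structure the analyses assume,
with all randomness driven by a single seed (bit-reproducible outputs).

* `gen_cds` — ATG + i.i.d. sense codons + stop; `n_codons` counts all
  codons including start and stop (3·n nt).  Uniform codon usage by
  default.
* `gen_depleted_cds` — same amino-acid marginal, but synonym choices are
  re-drawn with weight `(1 − strength)^k`, `k` the number of motif
  occurrences the codon creates against its previous codon, internally,
  and against the (provisional) next codon's first base.  The one-codon
  lookahead is essential: junction occurrences are the component a
  third-position permutation test detects, so a depletion signal must
  remove them.  At strength 0 the distribution reduces to `gen_cds`; at
  strength 1 motif-creating codons are used only when unavoidable.
* `gen_edited_pileup` — single-end 100 nt reads, uniformly placed,
  ~`coverage` deep, written as valid SAM with NM tags (alignments are
  simulation ground truth; no mapper is modeled).  Edited sites are
  adenosines in the fully tiled interior, allocated across 5'-neighbor
  classes by largest-remainder rounding proportional to
  `neighbor_prefs` (defaults A 0.31, T 0.42, C 0.12, G 0.15, used purely
  as simulation parameters) and uniformly within a class — a
  low-variance implementation of preference-proportional sampling that
  makes parameter-recovery checks sharp.  Each site's injected frequency
  is drawn Uniform(0.02, 0.20) — spanning the 1% calling threshold while
  keeping most sites detectable — and realized as an exact count of
  alternate reads, so truth and realized frequencies agree within
  rounding (≤ 1/(2·coverage)).  Sequencing errors are uniform
  substitutions; qualities are constant Q40 (no quality model).
* `gen_srna_library` — degradation mode: per-ORF counts multinomial in
  expression weights, lengths uniform 15–50 nt; dicer21/piwi30 modes:
  source ORF uniform (expression-independent), lengths Normal(21 or 30,
  sd 1) truncated to [15, 50] by rejection.  Fragments are substrings of
  their source ORF on either strand.

**What the generators do not emulate:** realistic base-quality models,
indels, paired-end layout, mapping ambiguity, strand-specific library
chemistry, contamination mixtures, or genuine codon-usage bias of any
host.  Passing tests therefore demonstrate algorithmic correctness and
statistical calibration under the stated generative assumptions, not
performance on real SRA data.

## Problem sizes used in tests and the acceptance script

Shuffle invariance is verified on 100 CDSs of 100–1000 codons × 1000
shuffles; null calibration on 200 CDSs drawn from the same length range
(the strict-less p-value is discrete, and its conservative overshoot at
the 5% level shrinks as the number of exchangeable positions grows, so
calibration is assessed over the full length range rather than one short
length); depletion power on 50 replicates of 500-codon strength-1
TA-depleted CDSs; SNP calling on a 10 kb reference at 100× with
error-free reads; neighbor recovery on ~1000 injected edits over a 25 kb
reference; small-RNA mode separation on 20 ORFs × 20,000 fragments.

## Known limitations

* The similarity fraction relies on the NM tag; alignments without it
  are skipped (with a warning) rather than recomputed from MD strings.
* The SNP caller holds per-reference count/quality arrays in memory —
  appropriate for viral genomes (kilobases), not chromosomes.
* Identity clustering is O(n²) in sequence count with an O(L²) LCS per
  pair; intended for hundreds of candidate proteins, not full
  proteomes.
* `repTrFrac`'s direction is reported two-sided via the 0.05/0.95 rule;
  the metric itself is descriptive and its "over" classification is what
  enters the maximal-under-representation call.
* Fragment matching is exhaustive per (fragment, target) pair; for
  large libraries pre-indexing would be required.
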