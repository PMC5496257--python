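# Methods

## The filtering model

`equilnc` treats lncRNA discovery as sequential rejection: each filter
encodes one known property of long non-coding RNA and removes the
transcripts that violate it, so the surviving set satisfies all of them
simultaneously. The stage order is fixed (F1 expression → F2 length → F3
coding potential → rescue → F4 gene proximity) and each stage consumes
exactly the previous stage's retained set; the orchestrator asserts the
partition (retained ∪ removed = input) at every stage.

Filter semantics and the reasoning behind each boundary:

* **F1.** A transcript passes with arithmetic mean TPM across *all*
  tissues (zeros included) ≥ `mean_tpm_min` (default 0.1). Single-exon
  transcripts are a notorious source of assembly artifacts, so they must
  *additionally* reach `single_exon_tpm_min` (default 5) TPM in at least
  one tissue — the two rules stack rather than substitute. Both
  thresholds are inclusive (≥) so that a transcript sitting exactly at a
  published cutoff passes it. Transcripts absent from the expression
  matrix count as all-zero (they were never quantified, so they fail F1),
  and this is logged.
* **F2.** `length_bp < 200` is removed; 200 passes. Length is the spliced
  length (sum of exon lengths; when a FASTA sequence is attached and its
  length disagrees with the exon sum, the FASTA length wins with a
  warning). An optional category restriction exists because multi-source
  inputs are sometimes pre-filtered for length upstream, leaving only one
  category for the rule to act on.
* **F3.** An ORF is an ATG-initiated codon run ending at a stop (or,
  flagged *partial*, at the sequence end), scanned in three frames on
  both strands; within one stop-free stretch only the 5′-most ATG is
  reported (maximality). Codons containing ambiguity codes do not
  translate and break the ORF. Removal requires an ORF of ≥ 100 aa *and*
  evidence: a motif match (always qualifies) or a protein-database hit
  with e-value < 10⁻³. Long ORFs without evidence are retained — random
  sequence produces ≥ 100-aa ORFs at an appreciable rate, and length
  alone is not coding evidence. Partial ORFs count toward the 100-aa rule.
  Only ORFs ≥ 100 aa are searched, both for speed and because shorter
  ORFs are overwhelmingly false positives.
* **Rescue.** Input is exactly the F3-removed set. A transcript is
  rescued when some known-lncRNA hit has e < 10⁻⁵, query coverage
  strictly > 25% and identity strictly > 75% (strict because the
  thresholds are phrased as "over"). Rescued transcripts re-enter
  *before* F4, so a rescued UTR fragment can still be removed; a
  `rescue_bypass_f4` switch exempts them when the alternative ordering is
  wanted.
* **F4.** Gene spans are extended by `flank` (default 1000) bp on both
  sides, clamped at position 1; a candidate is removed when its genomic
  span (first exon start to last exon end, introns included) overlaps
  ≥ 1 bp of an extended span on the same chromosome and strand. Closed
  coordinates make abutting-at-distance-zero count as "within".
  Unknown-strand candidates are compared against both strands
  (conservative removal, configurable). The span rather than per-exon
  convention is deliberate: a candidate whose intron straddles a gene is
  still a likely gene fragment.

Coordinates are GTF-style (1-based, closed) everywhere internally; BED12
is produced 0-based half-open on output, and GTF output round-trips
through the reader exactly.

## Alignment statistics

External aligners are not invoked; both search steps are
Smith–Waterman (Biopython's `PairwiseAligner`, C implementation) with
Karlin–Altschul e-values computed as E = K·m·n·e^(−λS), with n summed
over the database and no edge correction (raw lengths). Scoring schemes
and their gapped parameters:

| search     | scoring                        | λ     | K     |
|------------|--------------------------------|-------|-------|
| protein    | BLOSUM62, gap open 11/extend 1 | 0.267 | 0.041 |
| nucleotide | match +2, mismatch −3, open 5/extend 2 | 0.625 | 0.41 |

The nucleotide search additionally requires an exact shared 13-mer
between query and subject before aligning — the seed-and-extend shortcut
of word-based search. This costs a little sensitivity below ~70% identity
but removes almost all random-pair alignments; with rescue requiring
identity > 75%, a true rescue pair shares many exact 13-mers. Hits are
ordered by bitscore, ties broken by lower e-value then lexicographic
subject id, so results are deterministic. Percent identity is
matches/alignment-columns; percent query coverage uses the full query
length as denominator (not the aligned span). Both searches accept
externally computed tabular hits in place of the built-in aligner.

The motif matcher implements Prosite-style patterns (`x`, `[..]`,
`{..}`, repeats `(n)`/`(n,m)`, anchors `<`/`>`, attached or standalone)
compiled to regular expressions; a motif hit carries e-value 0.

The per-transcript conservation measure is best-hit identity% ×
coverage% / 100, giving a 0–100 scale (the raw product is available via a
flag); transcripts without a significant hit (e < 10⁻⁵) score 0 and are
reported as the no-hit fraction. The curve is the empirical CDF of this
measure.

## Tissue-specificity calculus

Definitions are applied literally, including their asymmetric
boundaries: *expressed* means TPM strictly > 0.1; *uniquely present* in
tissue k means TPM ≥ 0.1 in k and < 0.1 elsewhere; *uniquely absent*
means < 0.1 in k and strictly > 0.1 elsewhere. The variable subset for
clustering needs TPM sum > 100 and sample (n−1) standard deviation > 50
across tissues. Bi-clustering uses distance 1 − Pearson correlation for
transcripts and 1 − Spearman for tissues; linkage is average
(configurable — heatmap conventions vary, and only the correlation
measures are canonical here). Zero-variance rows get the maximum
distance 2.0 with a warning. TPM from counts follows the standard
formula TPM_i = (c_i/ℓ_i)/Σ_j(c_j/ℓ_j) × 10⁶ per tissue; all-zero count
columns stay all-zero with a warning.

## The synthetic transcriptome

The generator emulates the input of a multi-tissue lncRNA annotation
study: five truth classes, each engineered to be removed by exactly one
filter (or none), on virtual chromosomes (`chrS1..chrSn` with
protein-coding gene spans every 60 kb, plus a gene-free unplaced
`chrUn_0001` scaffold). Default class sizes: 400 coding, 800 true
lncRNA, 300 UTR fragments, 250 short, 250 low-expression (2,000 total),
over eight tissues with the mixed library preparation typical of such
studies (three rRNA-depleted CNS tissues, three polyA-captured, two
Ovation-prepped embryonic tissues).

Key constructions:

* Coding transcripts embed an ORF reverse-translated (random synonymous
  codons) from a bundled fixture database of 50 generated proteins
  (110–300 aa), flanked by random sequence.
* 5% of true lncRNA are "conserved lncRNA": they carry such an ORF *and*
  a near-identical (5% mutated) copy of their full sequence in the
  lncRNA fixture database, so F3 removes them and rescue recovers them.
  The ORFs of coding transcripts and of these rescue candidates come
  from disjoint protein pools: two independent reverse-translations of
  the same protein are ~75% identical at the nucleotide level (shared
  codon prefixes), close enough to the 75% rescue cutoff to
  cross-contaminate the rescue database otherwise.
* UTR fragments are placed with their exact exon layout within 1 kb of a
  planted gene on the same strand (the generator verifies this with the
  proximity filter itself and refuses to emit a violating dataset).
* Expression is generated directly on the TPM scale — the matrix is a
  labelled subsample of a larger transcriptome, so columns do not sum to
  10⁶ (TPM computation from counts is a separate, tested operation).
  Class medians: coding 10, lncRNA 1 (log-normal, σ = 0.8, per-tissue
  jitter σ = 0.5), giving final-set mean TPM of a few units, as expected
  for lncRNA. 15% of true lncRNA are tissue-specific (expression in one
  planted tissue only). Non-polyadenylated transcripts (half of the
  non-coding ones) have TPM attenuated ×0.25 in polyA-captured and ×0.5
  in Ovation tissues, reproducing the under-detection of lncRNA in polyA
  libraries.
* The generator *guarantees* its labels: expressed classes are rescaled
  to mean TPM ≥ 0.18 (and max ≥ 5.5 for single-exon transcripts) so F1
  can never misfire on them; low-expression transcripts draw uniform
  (0, 0.09) per tissue; background lncRNA are rescaled so at least two
  tissues exceed 0.15 TPM, so only planted transcripts can be uniquely
  present.

All randomness flows through one seeded generator; a config is
byte-identical across runs, and the seed is recorded in the emitted
manifest. A `perturb` operation degrades a clean dataset (point
mutations, multiplicative expression jitter) for robustness curves; at
zero noise it is the identity.

What the synthetic data does *not* emulate: real codon usage and
composition bias, splice-isoform families, profile-HMM-detectable remote
homology, genome-level sequence (transcript FASTA is authoritative),
read-level noise and mapping ambiguity. Passing the planted-truth tests
therefore shows the *logic* of the cascade is exact under its own
definitions, not that the thresholds are optimal for any real
transcriptome.

## Numerical and design choices

* Expression and coordinate comparisons are exact floating-point
  comparisons against the documented thresholds; no tolerance is applied
  (the thresholds are definitions, not estimates).
* GC% excludes ambiguity codes from numerator and denominator, so
  GC% + AT% = 100 on the unambiguous part.
* The e-value cutoffs are applied to e-values even where original
  descriptions say "p-values" — word-search tools report e-values, and at
  these magnitudes the two are numerically indistinguishable.
* The per-category ledger charges each removed transcript's TPM (summed
  over tissues) to the stage that removed it; a transcript rescued after
  F3 is uncharged again. "Mean TPM" in summaries is the mean over
  transcripts of the per-transcript mean across tissues.
* Determinism: all output files are written in sorted order
  (chromosome, span, transcript id), and no operation iterates over
  unordered containers.
* Problem sizes in the test suite and acceptance script (2,000-transcript
  default transcriptome, 40-query conservation contrast, 95-transcript
  determinism rerun) were chosen so the full verification cycle completes
  in about a minute on one CPU while keeping every class populated well
  above counting noise.

## Known limitations

* The Smith–Waterman + Karlin–Altschul combination approximates, but is
  not identical to, word-based heuristic search statistics (no edge
  correction, no composition adjustment, single best local alignment per
  pair — no sum statistics). E-values are therefore comparable across
  runs of this package, not across tools.
* Profile-HMM motif scoring is not implemented; the motif filter is
  deterministic pattern matching and will not find remote motif
  homology.
* The 13-mer seed requirement makes the nucleotide search blind below
  roughly 60–65% identity for short queries; the conservation curve's
  no-hit fraction is correspondingly conservative.
* Filter 4 needs gene spans; when the reference transcriptome itself
  contains the candidates, the caller must remove them from the gene set
  first (`gene_spans_from_records` helps).
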