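# Methods

## Problem and model

Stable RNA processing products (tRFs, rRNA fragments, mRNA-derived sRNAs,
and free-standing small ncRNAs) are cleavage products whose hallmark in
small RNA-seq is the sharp co-occurrence of read 5′ and 3′ ends: many
full-length reads share the same two end coordinates, on top of whatever
background coverage the parent transcript contributes. `stablefrag` models
a product as a stranded genomic interval supported by coincident end
densities, and treats everything else — library cleanup, alignment,
pair merging, counting, normalisation — as bookkeeping around that signal.

## Pipeline stages and the parameters that matter

### trim
* `quality_cutoff` (Phred, default 30): running-sum 3′ trim — subtract the
  cutoff from each quality, take partial sums from the 3′ end, cut at the
  minimum (no cut if the minimum is ≥ 0). This is the standard
  BWA/cutadapt-style rule; it never touches retained bases.
* Adapter matching allows substitutions only, error rate ≤ 0.1 of the
  overlap, ties to the longest overlap (leftmost cut). `min_overlap` is 1
  in PE mode — maximal adapter removal matters more than occasional
  overtrimming because the mate covers the loss after merging — and 3 in
  SE mode, where there is no mate. SE reads with no adapter hit are
  rejected outright: their insert extends past the read, so the 3′ end of
  the RNA is unknown and end-density calling would be misled.
* `min_length` 18 nt (below the shortest insert of interest).

### align
* Ungapped only. Indels would complicate end bookkeeping downstream and are
  not expected in short-insert libraries; a read with a real indel scores
  poorly and is dropped rather than misplaced.
* Flat `mismatch_penalty` 6 per mismatch (quality-independent) and linear
  minimum score `f(L) = min_score_a + min_score_b·L = 0 − 2L`. Together
  these admit ⌊L/3⌋ mismatches — deliberately permissive so that RNAs
  carrying modifications (which reverse-transcribe as mismatches) and
  oligo(A)-tailed reads survive to the dedicated filters. The flat penalty
  keeps the scorer exactly reproducible by a brute-force oracle, which is
  how the aligner is tested.
* Seeding is staged: exact k-mer windows at stride 1 over the whole read
  (k = 22, capped at read length); if no valid alignment results, all
  one-substitution neighbours of every window are looked up too. Escalation
  cannot change an already-successful result because a chance exact ≥14-mer
  hit on a desk-scale genome is vanishingly unlikely: any alignment found
  at stage one is a genuine locus.
* All valid alignments are reported (multi-mapped reads keep every locus);
  deduplication is by (chrom, strand, start).

### sam_sort (best stratum)
* Per read, only alignments achieving the maximal score are kept; for PE,
  the unit is a concordant pair (same chromosome, FR orientation, fragment
  span ≤ `max_insert` = 400 nt) and the two scores are summed. Ties keep
  every co-optimal unit; NH is the retained unit count.
* Sensitive mode (default on): leftover reads are re-aligned with seed 14;
  reads still unaligned go through one exhaustive scan per strand
  (`exhaustive_rescue`, default on). The rescue tier exists because *no*
  seeded scheme can reach a short read dense with mismatches (e.g. 3
  mismatches in a 20-mer leaves no clean 14-mer window and ≥2 mismatches in
  every window); at desk scale one vectorised pass over the genome is
  cheap, and in practice it only ever triggers for junk or heavily tailed
  reads. Mates in PE mode that align but find no concordant partner are
  discarded (counted in the statistics): the merge stage needs both mates.

### pseudoSE
* Overlap consolidation: agreeing bases get `min(q1+q2, 41)`; disagreeing
  positions keep the higher-quality base at `q_high − q_low` (on a quality
  tie, mate 1's base at quality 0 — the evidence is contradictory and says
  so). Qmax = 41 is the Illumina Phred+33 ceiling and is also the quality
  assigned to genome-filled gap bases, which are certain by construction.
* Mismatch filter: `max_mm` 2, `max_nh` 50 (both config keys). Mappings are
  filtered individually; a read whose mappings all fail is discarded for
  mismatches, a read with more than `max_nh` surviving mappings is
  discarded as non-specific. The conservation identity
  kept + discarded_mm + discarded_multi = input reads holds exactly and is
  asserted in tests.
* 3′-oligo(A) exemption (default on, can be switched off): a maximal run of
  *mismatching* A's at the 3′ end in read orientation is excluded from the
  mismatch count and recorded; templated (genome-matching) terminal A's are
  ordinary matches and never counted as tail. Oligo(A) reads are copied to
  a sidecar for downstream tailing analysis. The mapped interval keeps the
  tail positions (the alignment is full-length); at the low tail rates of
  real libraries this adds ≤4 nt of 3′-end spread that peak masking
  absorbs.

### identify
* Size bins 18–26 / 27–40 / 41–70 / 71–120 / 121–200 / 201–300 nt
  (config-exposed). Fractionation is what lets a tRNA half and its parent
  tRNA coexist: their reads land in different fractions and are peak-called
  independently. The edges separate tRF-sized species (~18–40 nt) from
  tRNA/5S-sized ones (~70–120 nt); they are not sacred, only disjoint.
* Peak calling per fraction and chrom/strand: positions within
  `mask_window` (15 nt) of a higher peak are suppressed first — this
  implements the method's resolution limit (fragments sharing one end are
  separable only if their lengths differ by >15 nt) and absorbs the ±1–2 nt
  end jitter that transcription initiation and processing leave around true
  ends. Surviving peaks are paired greedily: highest 5′ peak, then the
  highest 3′ peak giving an in-bin length and not masked for that 5′ peak;
  the joint read support of the chosen end pair is subtracted from both
  marginals and the loop continues until no end reaches `min_end_reads`
  (default ⌈quant_threshold/2⌉ = 5, so calling and the subsequent
  end-support filter agree). All ties break to the leftmost genomic
  coordinate, making calling order-independent.
* End-support filter: keep a product iff either end's support ≥
  ⌈quant_threshold/2⌉.
* Counting: stranded; a mapping is assigned to a product if ≤2 read bases
  fall outside it and ≤2 product bases are uncovered (`nonoverlap_read`,
  `nonoverlap_feature`); every mapping of a multi-mapped read may count,
  and one mapping may count toward several overlapping products.
  Identically-called products from different fractions are deduplicated
  (max supports kept) before clustering.

### cluster
* Relative coverage = mean depth from assigned reads over the product
  interval ÷ mean depth from all same-strand reads there; candidates need
  ≥ `min_count` (10) reads and relative coverage ≥ `min_relcov` (0.5).
  The background filter removes shoulders of abundant transcripts that
  accumulate enough coincident ends to be called but are mostly covered by
  unrelated reads.
* Overlap clustering: distance = |Δstart| + |Δend| (∞ across
  chrom/strand), tolerance 2 — mirroring the counting tolerance, since both
  absorb the same end wobble. Greedy maximum-coverage selection: repeatedly
  pick the unrepresented product that represents the most unrepresented
  products (ties → higher total count, then leftmost). Verified against an
  exhaustive re-scan oracle.
* Sequence clustering: longest-first greedy; a product joins a
  representative iff its 5′→3′ sequence occurs verbatim in the
  representative's (100 % identity of the shorter over its full length,
  ungapped) *and* the coverage contigs containing them match at ≥90 %
  ungapped sliding identity with a shorter/longer length ratio ≥0.5. The
  contig gate keeps identical sequences from genuinely different genomic
  contexts apart; without it, merging would silently discard positional
  information. Contigs are maximal intervals of positive pooled coverage
  per chrom/strand.

### quantify
* Counting reuses the identify assignment rule against the final
  representatives, per library. Library totals are mapped pseudo-SE
  *reads* after filtering (multi-mapped reads count once in the total,
  though each mapping can contribute a count) — "per million of mapped
  reads", not raw reads.
* RPM-of-biotype divides by the summed raw count of that biotype's products
  in that library (biotype groups analogously, default grouping:
  rRNA+tRNA → structural, ncRNA → ncRNA, CDS → mRNA-derived,
  intergenic+antisense → other). A zero class total with a nonzero count is
  impossible by construction and asserted.
* Biotype assignment: highest-priority same-strand overlapping annotation
  feature (rRNA > tRNA > ncRNA > CDS); opposite-strand-only overlap →
  "antisense"; none → "intergenic".
* Uniqueness = fraction of assigned mappings with NH == 1 (the statistic is
  named but not defined elsewhere; this is the definition used throughout).
* Consensus: per-position majority base among covering reads, ties to the
  genomic base; consensus quality is the rounded mean Phred of the
  contributing bases; uncovered positions take the genomic base at
  quality 0. Reported 5′→3′.
* Retention: keep a product iff it reaches `rpm_threshold` (10) RPM in at
  least one library.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of a TruSeq-style small-RNA PE
library: 18–300 nt inserts (mixture peaked at ~25, ~34 and ~90 nt — the
real insert distribution of gel-cut libraries is not known, so this is a
free choice covering tRF- and structured-RNA-sized species), 3′ adapter
read-through, independent rounded-Gaussian jitter on both ends (the
positional wobble of transcription initiation and processing), 1–4 nt
untemplated oligo(A) tails at a configurable rate, uniformly placed noise
reads, optional duplicated loci for multi-mapping, and qualities uniform in
32–40 with an optional 3′ decay to exercise the Q30 rule. Planted products
sit inside annotated features (one per feature) or intergenic space with
≥20 nt clearance, so their end densities are mutually resolvable —
emulating distinct loci.

It does **not** model sequencing substitution errors beyond the optional
uniform noise, PCR duplication, UMIs, ligation bias, or expression
heterogeneity within a locus. Passing recovery tests therefore shows the
pipeline's logic is correct under realistic read structure; it does not
certify performance on real libraries with correlated errors or extreme
abundance skew.

## Numerical choices, tie-breaks, degenerate inputs

* All coordinates are 0-based half-open internally; SAM (1-based) and GFF3
  (1-based inclusive) conversions happen only at file boundaries, tested by
  round-trips. BED output is 0-based half-open.
* Deterministic tie-breaks everywhere: leftmost coordinate in peak calling
  and clustering, higher count before position in representative selection,
  mate 1's base on merge-quality ties, genomic base on consensus ties.
* Empty inputs are legal: empty libraries produce all-zero statistics rows;
  a product with no assigned reads gets genomic consensus at quality 0.
* Recovery scoring matches one-to-one, consuming candidate pairs in order
  of smallest total end offset.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; equal seeds give byte-identical output files.

## Problem sizes

Tests and the acceptance script run on 12–50 kb genomes with 20–30 planted
products at 40–100 read pairs each (a few thousand reads per library) —
sizes chosen so the complete suite runs in seconds on one core while every
code path (multi-mapping, oligo(A), both strands, all six size fractions'
logic) is exercised. The implementation is pure Python over numpy and
scales linearly in reads and genome length; bacterial-genome scale is
feasible but not the design point of this reference implementation.

## Known limitations

* The aligner is ungapped by design; indel-bearing reads are lost, not
  recovered.
* The exhaustive rescue tier makes alignment sensitivity exact but costs a
  full genome pass per unseedable read; on large genomes with much junk
  input it should be disabled (`exhaustive_rescue = false`).
* Fragments sharing one end whose lengths differ by ≤15 nt within the same
  size fraction are unresolvable (the stronger peak wins) — an inherent
  resolution limit of end-density pairing.
* RPM-of-biotype uses product-count sums as the denominator; reads assigned
  to no product do not enter any biotype total.
* Differential expression is out of scope: the raw count matrix is exported
  in an edgeR-ready TSV instead.
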