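# Methods

## Overview

`rslariat` implements lariat-based detection of recursive splice (RS) sites:
motif-driven candidate and decoy generation in constitutive introns,
junction head/tail construction, linear-read subtraction, split-read lariat
mapping with branchpoint inference, a six-stage filter cascade with a
decoy-based empirical FDR, an informative-read probability model, and a
distal-exonic mode for cassette exons. A seeded simulator provides data with
the statistical structure the pipeline assumes, so every stage is testable
without external downloads.

## Coordinate model

All intervals are 0-based, half-open, stored on the forward genomic strand.
Sequence logic runs on transcription-order sequence (minus-strand features
are reverse-complemented on retrieval). A 5′ splice site is the first
intronic base in transcription order (the G of GT); a 3′ splice site is the
last intronic base (the G of AG). An RS site's single coordinate `pos` is
the G of its reconstituted donor GT; the same site acting as an acceptor
ends at `pos − 1`. These conventions remove ±1 ambiguity between the two
roles of one site.

## Candidate and decoy sites

The motif is `Y₅₊ N₀₋₄ YAG GT`: a run of **≥5 consecutive** C/T ending 0–4 nt
upstream of a YAG that is immediately followed by GT. The scanner checks
every GT position; when several spacer widths would match, the smallest gap
is taken and the pyrimidine run is extended maximally leftward (this affects
only the reported motif span, not the site position). `N` matches nothing
except the spacer. The motif semantics are pinned by an independent
regex-based oracle in the test-suite; note that a single greedy regex scan
is *not* equivalent (backtracking can hide an overlapping match), so the
oracle evaluates every GT position with anchored expressions.

Per putative site, 5 decoy positions are drawn uniformly **without
replacement** from the intron, then screened: candidates with GT at the
position, or within 250 nt (the tail mapping range) of a cryptic 3′ss motif
(`Y₅₊N₀₋₄YAG`), another putative site, or the intron's own annotated 3′ss
are removed and **not redrawn** — so the realised decoy count is below
5× the putative count, which is why the FDR normalises per decoy site.
Screening is against the host intron's annotated 3′ss only; acceptors of
neighbouring introns lie across an exon and outside the junction tails being
mapped.

Junctions for one intron and one site set (putative and decoy sets are built
independently, never mixed) comprise the conventional pair, both mixed pairs
per site, and ordered site–site pairs (donor upstream of acceptor). Each
junction stores its first 20 nt (head) and last ≤250 nt (tail); junctions
shorter than 20 nt cannot form a head and are dropped with a log record.

## Read prefiltering

Reads with ≥5 % non-ACGT bases are removed (strict "fewer than 5 %"). A
read is then discarded if it has an end-to-end, indel-free alignment to the
spliced transcriptome or the genome (either strand) with at most
`floor(0.0133 × read_length)` mismatches — a conservative translation of a
linear alignment score floor of −0.24 per base. The built-in matcher finds
candidates by pigeonhole seeding (split into `budget+1` chunks; one chunk of
any qualifying alignment must match exactly) and verifies by Hamming
distance, so it implements the contract exactly rather than heuristically.
The rate is a config knob (`linear_mismatch_rate`), and the subtraction
order (transcriptome, then genome) cannot change the retained set because a
read is dropped iff it matches either reference.

## Lariat mapping

Heads are located as exact 20-mer occurrences inside reads; a read matching
more than one distinct head *sequence* is discarded (ambiguous 5′ss). The
prefix upstream of the head match (≥20 nt required) is aligned end-to-end
inside each candidate tail with no indels; allowed alignments have zero
mismatches or exactly one at the final base — equivalently, `prefix[:-1]`
occurs verbatim, which is how the scan is implemented. Zero-mismatch reads
are retained because downstream filters operate on the *fraction* of
branchpoint-mismatch reads; requiring the mismatch on every read would
contradict a ≥5 % fraction criterion. The branchpoint is the tail base under
the alignment's final position; `bp_to_3ss = tail_len − 1 − end_offset`.

Tie-breaks: within one tail, equal-score alignments resolve to the most
3′-ward end offset (the branchpoint closest to the acceptor — deterministic,
and consistent with branchpoint positional biology); across junctions, ties
are retained and resolved by weighting. Alignments spanning more than one
gene discard the read. Weights are exact `Fraction(1, k)` over the k
junction resolutions of one (read, 5′ss, branchpoint) group, so group sums
are exactly 1 in rational arithmetic.

## Filter cascade

Intronic order: branchpoint-mismatch existence → high confidence →
proximity → repeats → branchpoint distance → self-primed. The self-primed
check runs last, where its effect on the decoy rate is interpretable after
the generic filters. Distal mode swaps proximity/repeats for the
exonic-branchpoint stage.

Every stage is a **pure predicate on the original mapped support**:
junction-level stages (mismatch existence; high confidence; proximity;
repeats) flag junctions, read-level stages (branchpoint distance;
self-primed; exonic branchpoint) flag reads, and a junction survives a
cascade prefix iff it passes all junction predicates so far and keeps ≥1
read passing all read predicates so far. Because stages combine by
intersection, the final surviving set is independent of stage order (a
property test permutes the order); order shapes only the per-stage counts
and FDR trajectory. Consequences worth noting: the ≥5 % mismatch fraction
uses weighted counts over the *original* support (weights encode mapping
ambiguity, not evidence strength; the "at least one mismatch read" rule is
deliberately unweighted existence), and the 20-mer uniqueness and repeat
windows use the junction's *best-supported* branchpoint (highest summed
weight; ties resolve toward the 3′ss, then by coordinate).

Stage details: uniqueness requires the 20-mer starting at the 5′ss and the
20-mer ending at the branchpoint to occur exactly once in the genome, both
strands searched. Proximity drops a junction when its non-annotated site
lies ≤100 nt from an annotated site of the same type (5′ vs 3′), same
contig and strand — boundary inclusive. Repeat filtering drops a junction
when either 20-nt window overlaps a simple-repeat or low-complexity
interval by ≥1 base (other RepeatMasker classes are ignored at load time).
Branchpoint distance keeps 10 ≤ `bp_to_3ss` ≤ 60, both ends inclusive.
Self-priming compares the genome 5-mer upstream of and including the
branchpoint with the genome 5-mer upstream of the 5′ss, in transcription
order; identical 5-mers drop the read. If a 5-mer window would leave the
contig, the read is kept with a warning. The distal exonic-branchpoint stage
keeps reads whose branchpoint lies strictly inside the exon (not its first
or last base, strand-aware).

## Empirical FDR

```
FDR = (decoy_hits / n_decoy_sites × n_putative_sites) / putative_hits
```

clipped to [0, 1]; NaN when `putative_hits = 0`; hits are weighted read
counts, site totals are the generated (pre-mapping) counts. The per-site
normalisation corrects for decoy screening leaving fewer than 5 decoys per
putative site. The estimator is scale-invariant in the hit counts. On the
bundled artifact-rich simulation the trajectory declines across stages at
the documented seeds; because it is a ratio of small counts, a stage that
removes putative but not decoy support can tick the estimate up slightly in
small simulations — typical behaviour, not a guarantee.

## Informative-read model

Assume the branchpoint sits 25 nt upstream of the 3′ss (median U2 position);
the lariat loop runs from the intron start to the branchpoint
(`loop_len = intron_len − 25`; introns ≤25 nt get probability 0). A read of
length n starting at a uniformly random loop position is informative when
the branchpoint lies ≥20 nt downstream of the start (branchpoint-side
mappable region) and the read retains ≥20 nt past the branchpoint for the
donor side — i.e. distance d to the branchpoint satisfies
`20 ≤ d ≤ n − 21`. Closed form:

```
P(informative) = max(0, min(n − 40, loop_len − 20)) / loop_len
```

The brute-force enumeration over loop positions — not the closed form — is
the source of truth in tests; the Monte-Carlo estimator (1000 positions with
replacement by default) must converge to it. The boundary convention
("at least 20 nt upstream" read as d ≥ 20) is pinned by that oracle. Fitting
`log y = log a + b log x` by least squares over per-intron probabilities
(zeros excluded and counted; ≥3 positive pairs required) yields the
power-law decay `y = a·xᵇ` across intron lengths; the weighted length
distribution re-weights each intron's log-length mass by its probability,
emulating what an equal-expression lariat survey would observe.

## Simulator

The generator emulates exactly the read structure the mapper assumes:

* genes on both strands with GT..AG introns (exon/intron lengths log-normal,
  medians 150 nt / 1800 nt, σ = 0.3 / 0.45, minima 80 / 120 nt — typical
  mammalian short-intron scales that keep desk runtimes small);
* planted RS sites embed the motif verbatim ≥350 nt from either intron end
  (clearing the 100-nt proximity window and the 250-nt tail range), with a
  branchpoint adenosine planted 10–60 nt upstream of every lariat-emitting
  acceptor (redrawn if its 5-mer window would collide with the motif span,
  which truncates only offsets ≤12 for the longest motifs);
* lariat reads concatenate loop-suffix + donor-prefix, substitute the
  branchpoint base with probability 0.3 (the RT signature), then apply
  uniform sequencing errors (0.001/nt) outside the branchpoint. By default
  prefixes are drawn uniform over [20, read_len−20] ("informative-only", so
  reads-per-junction means usable reads); setting `informative_only=False`
  samples read starts uniformly over the loop, which ties the simulated
  informative fraction to the closed-form model and is how that property is
  tested;
* artifact classes: self-primed points whose branchpoint 5-mer is engineered
  to equal the 5-mer upstream of the donor (cycling through plain /
  duplicated-context / repeat-masked flavors, since self-priming and
  mis-mapping concentrate in repetitive sequence — this also gives the
  high-confidence and repeat stages decoy-side work); trap sites whose
  diagnostic 20-mers are duplicated elsewhere; trap sites inside planted
  simple-repeat intervals; linear mRNA/pre-mRNA/genomic background; a few
  reads salted with >5 % Ns;
* accidental 5-mer equality at genuine branchpoints is resolved by mutating
  one adjacent base, so the self-primed filter has zero collateral damage by
  construction (a property of the generator, verified against truth labels);
* background composition is uniform with pyrimidine runs suppressed
  (probability 0.8 of forcing a purine after 4 consecutive Y), keeping
  spurious motif density low but non-zero — spurious candidates attract no
  reads but realistically inflate the discovered-site denominator;
* default scale: 200 genes (~1.5 Mb), 50 clean planted sites, 16 self-primed
  introns × 6 points, 8 duplicated and 4 repeat traps, 50 conventional-lariat
  introns, 12 cassette genes, ~2000 reads of 100 nt. Every output byte is a
  function of the seed.

What the simulator does **not** model — and what passing tests therefore do
not show about real data: expression-level variation (all junctions get
equal read counts), indels and structured (non-uniform) sequencing error,
paired-end reads, quality-score information, genuine repeat families beyond
planted intervals, alternative splicing beyond single skipped exons, and
template-switching artifacts other than the 5-mer self-priming model.

## Problem sizes and determinism

The test-suite runs the full 200-gene simulation once (session fixture,
seeds fixed at 1) plus scaled-down 25–40-gene simulations for unit tests;
the whole suite completes in well under a minute on one CPU.
`scripts/acceptance.py` re-runs the 200-gene pipeline end-to-end (~25 s).
All randomness flows from explicit seeds (Python `random` for generation,
numpy `default_rng` for Monte-Carlo); per-intron decoy draws are seeded by a
CRC of the intron id so results do not depend on iteration order.

## Known limitations

* Head matching is exact; a sequencing error inside the 20-nt donor head
  loses the read (no mismatch-tolerant head search), mirroring the
  zero-mismatch head contract.
* Reads containing a second junction head — e.g. a decoy donor 20-mer inside
  the donor-side segment — are discarded as 5′ss-ambiguous; with a decoy
  library present this affects a few percent of genuine lariat reads, which
  is why round-trip identity is stated conditional on a single-head read.
* The built-in linear matcher is contract-faithful but not tuned for large
  genomes; for real datasets an external aligner can be substituted behind
  the same interface (`subtract_mapped(matcher_factory=...)`).
* A single annotation file serves as both the intron source and the
  linear-subtraction transcriptome; merged multi-source annotations are out
  of scope.
* The distal mode enumerates every exonic base as a candidate acceptor, so
  acceptor-position evidence is diffuse by construction; distal findings are
  best summarised by their (5′ss, branchpoint) support.
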