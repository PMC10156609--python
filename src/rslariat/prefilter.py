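"""Read pre-filtering: ambiguity filter and linear-alignment subtraction.

Before lariat mapping, reads that can be explained by an ordinary linear
alignment to the transcriptome or the genome are removed; only the remainder
can contain the inverted (branchpoint-first) structure of a lariat-spanning
read.

The linear-alignment contract is deliberately a *contract*, not a tool: a
read "aligns" if some reference position matches it end-to-end, on either
strand, with at most ``floor(rate * read_length)`` mismatches and no indels
(default rate 0.0133, a conservative translation of a linear score floor of
-0.24 per base at a mismatch penalty of 6 with quality-independent scoring).
The built-in matcher implements this exactly via pigeonhole seeding; real
datasets can substitute an external aligner as long as it honours the same
contract (see :func:`subtract_mapped`'s ``matcher`` argument).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genome import GenomeSequence, Transcript, reverse_complement


@dataclass
class ReadRecord:
    read_id: str
    seq: str
    qual: str | None = None
    passed_prefilter: bool = True

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"read {self.read_id!r} has empty sequence")

    @property
    def ambiguous_fraction(self) -> float:
        n = sum(1 for c in self.seq if c not in "ACGT")
        return n / len(self.seq)


def read_fastq(path) -> list[ReadRecord]:
    from Bio import SeqIO

    return [
        ReadRecord(rec.id, str(rec.seq).upper(),
                   "".join(chr(q + 33) for q in rec.letter_annotations.get(
                       "phred_quality", [])) or None)
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual or "I" * len(r.seq)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")


def filter_ambiguous(
    reads: list[ReadRecord], max_frac: float = 0.05
) -> list[ReadRecord]:
    """Keep reads whose fraction of non-ACGT bases is strictly below
    *max_frac* ("fewer than 5% ambiguous bases")."""
    return [r for r in reads if r.ambiguous_fraction < max_frac]


class LinearMatcher:
    """End-to-end, indel-free linear matcher against a set of references.

    A read matches if it aligns at some position of some reference (forward
    read orientation against both reference strands) with at most
    ``floor(rate * len(read))`` mismatches.  Candidate positions are found by
    pigeonhole seeding: the read is split into ``budget + 1`` chunks, at least
    one of which must match exactly in any qualifying alignment.
    """

    def __init__(self, references: list[str], rate: float = 0.0133):
        self.rate = rate
        # one search space containing both strands; '#' separators prevent
        # alignments bridging references
        parts = []
        for ref in references:
            parts.append(ref)
            parts.append(reverse_complement(ref))
        self.space = "#".join(parts)

    def budget(self, read_len: int) -> int:
        return math.floor(self.rate * read_len)

    def matches(self, seq: str) -> bool:
        m = self.budget(len(seq))
        n_chunks = m + 1
        L = len(seq)
        chunk_len = L // n_chunks
        if chunk_len == 0:
            return seq in self.space
        space = self.space
        for c in range(n_chunks):
            cs = c * chunk_len
            ce = L if c == n_chunks - 1 else cs + chunk_len
            chunk = seq[cs:ce]
            i = space.find(chunk)
            while i != -1:
                start = i - cs
                if 0 <= start and start + L <= len(space):
                    window = space[start : start + L]
                    if "#" not in window:
                        mm = sum(1 for a, b in zip(seq, window) if a != b)
                        if mm <= m:
                            return True
                i = space.find(chunk, i + 1)
        return False


def transcriptome_sequences(
    transcripts: list[Transcript], genome: GenomeSequence
) -> list[str]:
    return [tx.spliced_sequence(genome) for tx in transcripts]


@dataclass
class PrefilterStats:
    n_input: int = 0
    n_ambiguous: int = 0
    n_transcriptome: int = 0
    n_genome: int = 0
    n_retained: int = 0


def subtract_mapped(
    reads: list[ReadRecord],
    genome: GenomeSequence,
    transcriptome: list[str],
    rate: float = 0.0133,
    matcher_factory=LinearMatcher,
) -> tuple[list[ReadRecord], PrefilterStats]:
    """Discard reads explicable by a linear alignment, transcriptome first,
    then genome.  Returns the surviving lariat-search set and per-stage
    counts.  The retained set is independent of the subtraction order because
    a read is dropped iff it matches either reference."""
    stats = PrefilterStats(n_input=len(reads))
    tx_matcher = matcher_factory(transcriptome, rate=rate)
    g_matcher = matcher_factory(list(genome.contigs.values()), rate=rate)
    kept = []
    for r in reads:
        if tx_matcher.matches(r.seq):
            stats.n_transcriptome += 1
            r.passed_prefilter = False
        elif g_matcher.matches(r.seq):
            stats.n_genome += 1
            r.passed_prefilter = False
        else:
            kept.append(r)
    stats.n_retained = len(kept)
    return kept, stats


def prefilter_reads(
    reads: list[ReadRecord],
    genome: GenomeSequence,
    transcripts: list[Transcript],
    max_ambiguous_frac: float = 0.05,
    rate: float = 0.0133,
) -> tuple[list[ReadRecord], PrefilterStats]:
    """Full prefilter: ambiguity filter followed by linear subtraction."""
    unambiguous = filter_ambiguous(reads, max_ambiguous_frac)
    kept, stats = subtract_mapped(
        unambiguous, genome, transcriptome_sequences(transcripts, genome), rate
    )
    stats.n_input = len(reads)
    stats.n_ambiguous = len(reads) - len(unambiguous)
    return kept, stats
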