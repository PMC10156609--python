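"""Split-read lariat mapping, branchpoint inference, and read weighting.

A lariat-spanning cDNA read traverses the branched junction in inverted
order: branchpoint-proximal loop sequence first, then the 5' splice-site
sequence.  Mapping therefore proceeds in two steps:

1. the 20-nt **head** of every junction (its 5'ss-proximal end) is located as
   an exact substring of the read;
2. the read **prefix** upstream of the head match is aligned end-to-end,
   without indels, inside the junction's 250-nt **tail** (its 3'ss-proximal
   end).

The final base of the prefix alignment is the inferred branchpoint.  Reverse
transcriptase misincorporates when traversing the 2'-5' linkage, so a single
mismatch located exactly at that final base is tolerated (and is the
diagnostic lariat signature); any other mismatch or indel rejects the
alignment.  Zero-mismatch alignments are retained too -- downstream filters
require only a *fraction* of a junction's reads to carry the branchpoint
mismatch.

When one (read, 5'ss, branchpoint) combination is compatible with several
acceptor sites (their tails overlap), each resolution receives weight
1/k as an exact rational, so weights per combination sum to exactly 1.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction

from .prefilter import ReadRecord
from .sites import Junction


@dataclass
class HeadHit:
    read_id: str
    head_seq: str
    offsets: tuple[int, ...]  # all occurrences of the head within the read
    junctions: tuple[Junction, ...]


@dataclass
class TailAlignment:
    junction: Junction
    end_offset: int  # 0-based offset of the alignment's last base in the tail
    n_mismatch: int  # 0 or 1 (the 1 is at the final base)
    prefix_len: int


@dataclass
class LariatRead:
    read_id: str
    junction: Junction
    bp_pos: int  # forward-strand genomic coordinate of the branchpoint
    bp_mismatch: bool
    prefix_len: int
    bp_to_3ss: int
    weight: Fraction = Fraction(1)


@dataclass
class MappingStats:
    n_reads: int = 0
    n_multi_head: int = 0
    n_head_hit: int = 0
    n_short_prefix: int = 0
    n_no_tail: int = 0
    n_cross_gene: int = 0
    n_lariat: int = 0


def map_heads(
    junctions: list[Junction],
    reads: list[ReadRecord],
    head_len: int = 20,
    stats: MappingStats | None = None,
) -> list[HeadHit]:
    """Exact occurrences of junction heads within reads.

    A read matching more than one distinct head *sequence* is discarded
    (ambiguous 5'ss); all offsets of the single matching head are kept.
    """
    index: dict[str, list[Junction]] = defaultdict(list)
    for j in junctions:
        index[j.head_seq].append(j)
    hits = []
    for r in reads:
        found: dict[str, list[int]] = {}
        seq = r.seq
        for i in range(len(seq) - head_len + 1):
            k = seq[i : i + head_len]
            if k in index:
                found.setdefault(k, []).append(i)
        if not found:
            continue
        if len(found) > 1:
            if stats:
                stats.n_multi_head += 1
            continue
        (head, offsets), = found.items()
        hits.append(HeadHit(r.read_id, head, tuple(offsets), tuple(index[head])))
        if stats:
            stats.n_head_hit += 1
    return hits


def trim_read(read_seq: str, offset: int, min_prefix: int = 20) -> str | None:
    """Branchpoint-proximal prefix of the read (everything before the head
    match); rejected when shorter than the minimum mappable region."""
    if offset < min_prefix:
        return None
    return read_seq[:offset]


def map_tail(
    prefix: str, junctions: list[Junction]
) -> list[TailAlignment]:
    """End-to-end prefix alignments inside junction tails.

    Allowed alignments have zero mismatches, or exactly one mismatch at the
    prefix's final base (the branchpoint).  Equivalently: ``prefix[:-1]``
    occurs exactly, with one more tail base available for the final position.
    Only the best-scoring alignments (fewest mismatches) are returned; a tie
    within one tail is broken toward the most 3'-ward end offset, and ties
    across junctions are all retained for fractional weighting.
    """
    core = prefix[:-1]
    last = prefix[-1]
    plen = len(prefix)
    best: list[TailAlignment] = []
    best_mm = 2
    for j in junctions:
        tail = j.tail_seq
        per_tail: dict[int, TailAlignment] = {}
        i = tail.find(core)
        while i != -1:
            end = i + plen - 1
            if end < len(tail):
                mm = 0 if tail[end] == last else 1
                aln = TailAlignment(j, end, mm, plen)
                prev = per_tail.get(mm)
                if prev is None or end > prev.end_offset:
                    per_tail[mm] = aln
            i = tail.find(core, i + 1)
        for aln in per_tail.values():
            if aln.n_mismatch < best_mm:
                best, best_mm = [aln], aln.n_mismatch
            elif aln.n_mismatch == best_mm:
                best.append(aln)
    return best


def infer_branchpoint(aln: TailAlignment) -> LariatRead:
    """Branchpoint = last nucleotide of the trimmed-read alignment; distance
    to the junction's own 3'ss is the tail length past the alignment end."""
    j = aln.junction
    tail_len = len(j.tail_seq)
    bp_pos = j.tail_offset_to_genomic(aln.end_offset)
    return LariatRead(
        read_id="",
        junction=j,
        bp_pos=bp_pos,
        bp_mismatch=aln.n_mismatch == 1,
        prefix_len=aln.prefix_len,
        bp_to_3ss=tail_len - 1 - aln.end_offset,
    )


def assign_weights(lariats: list[LariatRead]) -> list[LariatRead]:
    """Fractional weights over ambiguous acceptor resolutions.

    Reads are grouped by (read_id, 5'ss, branchpoint); each of the k distinct
    junction resolutions in a group receives weight 1/k (exact rationals, so
    each group sums to exactly 1)."""
    groups: dict[tuple, list[LariatRead]] = defaultdict(list)
    for lr in lariats:
        groups[(lr.read_id, lr.junction.five_genomic, lr.bp_pos)].append(lr)
    out = []
    for members in groups.values():
        k = len({m.junction.junction_id for m in members})
        seen = set()
        for m in members:
            if m.junction.junction_id in seen:
                continue
            seen.add(m.junction.junction_id)
            m.weight = Fraction(1, k)
            out.append(m)
    return out


def map_lariats(
    junctions: list[Junction],
    reads: list[ReadRecord],
    head_len: int = 20,
    min_prefix: int = 20,
) -> tuple[list[LariatRead], MappingStats]:
    """Full split-read mapping of prefiltered reads against a junction
    library."""
    stats = MappingStats(n_reads=len(reads))
    by_id = {r.read_id: r for r in reads}
    hits = map_heads(junctions, reads, head_len, stats)
    lariats: list[LariatRead] = []
    for hit in hits:
        read = by_id[hit.read_id]
        alignments: list[TailAlignment] = []
        usable = False
        for offset in hit.offsets:
            prefix = trim_read(read.seq, offset, min_prefix)
            if prefix is None:
                continue
            usable = True
            alignments.extend(map_tail(prefix, list(hit.junctions)))
        if not usable:
            stats.n_short_prefix += 1
            continue
        if not alignments:
            stats.n_no_tail += 1
            continue
        # best score across all offsets
        best_mm = min(a.n_mismatch for a in alignments)
        alignments = [a for a in alignments if a.n_mismatch == best_mm]
        genes = {a.junction.gene_id for a in alignments}
        if len(genes) > 1:
            stats.n_cross_gene += 1
            continue
        for aln in alignments:
            lr = infer_branchpoint(aln)
            lr.read_id = read.read_id
            lariats.append(lr)
        stats.n_lariat += 1
    return assign_weights(lariats), stats
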