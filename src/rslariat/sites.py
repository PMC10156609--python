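"""Recursive splice-site discovery and junction library construction.

A recursive splice (RS) site is an intronic position where a 3' splice site
(polypyrimidine tract + YAG) is immediately followed by a reconstituted
minimal 5' splice site (GT).  The motif scanned for is

    Y(5+)  N(0-4)  YAG | GT

i.e. a run of at least five consecutive pyrimidines, then 0-4 arbitrary
bases, then YAG, then GT.  A site's coordinate ``pos`` is the first base of
the GT (the recursive donor); the same site acting as an acceptor ends at
``pos - 1`` (the G of YAG).  One coordinate serves both roles.

All scanning operates on transcription-order sequence; N never matches a
pyrimidine or a literal base, only the 0-4 nt spacer.
"""

from __future__ import annotations

import bisect
import logging
import random
import zlib
from dataclasses import dataclass

from .genome import GenomeSequence, Intron

logger = logging.getLogger(__name__)

PYRIMIDINES = frozenset("CT")

# junction side classes
ANNOTATED = "annotated"
RS = "RS"
DECOY = "decoy"
EXONIC = "exonic"


@dataclass(frozen=True)
class RSSite:
    """A putative or decoy recursive splice position within one intron.

    ``local`` is the transcription-order offset of the first base of the GT
    within the intron (0 = first intronic base); ``pos`` is the same base as a
    forward-strand genomic coordinate.  ``motif_span`` is the transcription-
    order (start, end) interval of the full motif match, None for decoys.
    """

    intron: Intron
    local: int
    kind: str  # "putative" | "decoy"
    motif_span: tuple[int, int] | None = None

    @property
    def pos(self) -> int:
        return self.intron.local_to_genomic(self.local)

    @property
    def acceptor_pos(self) -> int:
        """Genomic coordinate of the site acting as a 3'ss (G of YAG)."""
        return self.intron.local_to_genomic(self.local - 1)


def _has_py_run_upstream(seq: str, yag_start: int, max_gap: int = 4) -> int | None:
    """Return the start index of a maximal >=5-pyrimidine run ending 0..max_gap
    bases upstream of *yag_start*, or None.  The smallest gap wins."""
    for gap in range(max_gap + 1):
        run_end = yag_start - gap
        if run_end - 5 < 0:
            return None
        if all(c in PYRIMIDINES for c in seq[run_end - 5 : run_end]):
            start = run_end - 5
            while start > 0 and seq[start - 1] in PYRIMIDINES:
                start -= 1
            return start
    return None


def scan_rs_motif(seq: str) -> list[tuple[int, tuple[int, int]]]:
    """All RS-motif matches in a transcription-order sequence.

    Returns ``(pos, (span_start, span_end))`` tuples where ``pos`` indexes the
    G of the GT and the span covers the full Y-run..GT match (half-open).
    Overlapping matches are all reported; matches are collapsed by ``pos``.
    """
    out = []
    p = seq.find("GT", 8)  # earliest possible donor: 5 Y + YAG before it
    while p != -1:
        if seq[p - 3] in PYRIMIDINES and seq[p - 2 : p] == "AG":
            run_start = _has_py_run_upstream(seq, p - 3)
            if run_start is not None:
                out.append((p, (run_start, p + 2)))
        p = seq.find("GT", p + 1)
    return out


def scan_cryptic_3ss(seq: str) -> list[int]:
    """Positions of cryptic 3' splice sites: Y(5+) N(0-4) YAG with no GT
    requirement.  Reported position is the G of the AG (last motif base)."""
    out = []
    i = seq.find("AG", 6)
    while i != -1:
        # i is the A; YAG ends at i+1
        if i >= 1 and seq[i - 1] in PYRIMIDINES:
            if _has_py_run_upstream(seq, i - 1) is not None:
                out.append(i + 1)
        i = seq.find("AG", i + 1)
    return out


def find_putative_sites(intron: Intron, genome: GenomeSequence) -> list[RSSite]:
    """Scan one intron for putative RS sites (strictly inside the intron)."""
    seq = intron.sequence(genome)
    sites = []
    for pos, span in scan_rs_motif(seq):
        if 0 < pos < len(seq) - 1:
            sites.append(RSSite(intron, pos, "putative", span))
    return sites


def generate_decoys(
    intron: Intron,
    genome: GenomeSequence,
    putative: list[RSSite],
    n_per_site: int = 5,
    rng_seed: int = 0,
    mapping_range: int = 250,
) -> list[RSSite]:
    """Random decoy positions for an intron carrying putative RS sites.

    ``n_per_site`` positions per putative site are drawn uniformly without
    replacement from the intron.  Candidates are then removed if they

    * have a GT dinucleotide at the drawn position ("adjacent GT"), or
    * lie within *mapping_range* nt of a cryptic 3'ss motif (Y5+ N0-4 YAG),
      another putative RS site, or the intron's annotated 3'ss.

    Filtered-away decoys are **not** redrawn, so the surviving decoy count per
    intron is at most ``n_per_site`` times the putative count.
    """
    if not putative:
        return []
    seq = intron.sequence(genome)
    L = len(seq)
    rng = random.Random(rng_seed)
    n_draw = min(n_per_site * len(putative), L)
    candidates = rng.sample(range(L), n_draw)

    exclusion = set()
    for c in scan_cryptic_3ss(seq):
        exclusion.add(c)
    for s in putative:
        exclusion.add(s.local)
    exclusion.add(L - 1)  # annotated 3'ss (last intronic base)
    exclusion = sorted(exclusion)

    def near_exclusion(d: int) -> bool:
        i = bisect.bisect_left(exclusion, d)
        for j in (i - 1, i):
            if 0 <= j < len(exclusion) and abs(exclusion[j] - d) <= mapping_range:
                return True
        return False

    decoys = []
    for d in candidates:
        if seq[d : d + 2] == "GT":
            continue
        if near_exclusion(d):
            continue
        decoys.append(RSSite(intron, d, "decoy"))
    return decoys


@dataclass(frozen=True)
class Junction:
    """An ordered (5'ss, 3'ss) pair within one intron (or intron + exon for
    distal junctions), with the head/tail sequences used for split-read
    mapping.

    ``five_local``/``three_local`` are transcription-order offsets of the
    donor G and the acceptor G within the junction's reference interval
    (the intron, or intron+exon for distal junctions).  The junction sequence
    runs from the donor through the acceptor in transcription order;
    ``head_seq`` is its first *head_len* nt and ``tail_seq`` its last
    ``<= tail_len`` nt.
    """

    gene_id: str
    contig: str
    strand: str
    intron: Intron
    five_local: int
    three_local: int
    five_class: str
    three_class: str
    head_seq: str
    tail_seq: str
    # genomic span of the reference interval used for local coordinates; for
    # ordinary junctions this is the intron itself.
    ref_start: int
    ref_end: int

    @property
    def junction_len(self) -> int:
        return self.three_local - self.five_local + 1

    def local_to_genomic(self, local: int) -> int:
        if self.strand == "+":
            return self.ref_start + local
        return self.ref_end - 1 - local

    @property
    def five_genomic(self) -> int:
        return self.local_to_genomic(self.five_local)

    @property
    def three_genomic(self) -> int:
        return self.local_to_genomic(self.three_local)

    def tail_offset_to_genomic(self, offset: int) -> int:
        """Genomic coordinate of tail position *offset* (0-based within the
        tail, whose last base is the acceptor G)."""
        local = self.three_local - (len(self.tail_seq) - 1) + offset
        return self.local_to_genomic(local)

    @property
    def kind(self) -> str:
        """FDR accounting class: decoy if either side is a decoy site,
        putative if either side is an RS/exonic candidate, else conventional."""
        classes = {self.five_class, self.three_class}
        if DECOY in classes:
            return "decoy"
        if RS in classes or EXONIC in classes:
            return "putative"
        return "conventional"

    @property
    def junction_id(self) -> str:
        return (
            f"{self.gene_id}|{self.five_class}:{self.five_genomic}"
            f"|{self.three_class}:{self.three_genomic}"
        )


def _make_junction(
    intron: Intron,
    seq: str,
    f: int,
    t: int,
    five_class: str,
    three_class: str,
    head_len: int,
    tail_len: int,
    ref_start: int | None = None,
    ref_end: int | None = None,
) -> Junction | None:
    span = t - f + 1
    if span < head_len:
        logger.debug(
            "junction %s:%d-%d span %d < head length %d, skipped",
            intron.intron_id, f, t, span, head_len,
        )
        return None
    jseq = seq[f : t + 1]
    return Junction(
        gene_id=intron.gene_id,
        contig=intron.contig,
        strand=intron.strand,
        intron=intron,
        five_local=f,
        three_local=t,
        five_class=five_class,
        three_class=three_class,
        head_seq=jseq[:head_len],
        tail_seq=jseq[-tail_len:],
        ref_start=intron.start if ref_start is None else ref_start,
        ref_end=intron.end if ref_end is None else ref_end,
    )


def build_junctions(
    intron: Intron,
    genome: GenomeSequence,
    sites: list[RSSite],
    head_len: int = 20,
    tail_len: int = 250,
    include_site_pairs: bool = True,
) -> list[Junction]:
    """All pairwise junctions for one intron and one set of sites.

    Emits the conventional (annotated 5'ss -> annotated 3'ss) junction, the
    (annotated 5'ss -> site-as-3'ss) and (site-as-5'ss -> annotated 3'ss)
    mixed junctions, and -- when ``include_site_pairs`` -- ordered site-site
    pairs with the donor upstream of the acceptor in transcription order.
    Junctions spanning fewer than *head_len* nt are dropped (logged).
    """
    seq = intron.sequence(genome)
    L = len(seq)
    site_class = {s.local: (RS if s.kind == "putative" else DECOY) for s in sites}
    locals_sorted = sorted(site_class)

    pairs: list[tuple[int, int, str, str]] = [(0, L - 1, ANNOTATED, ANNOTATED)]
    for s in locals_sorted:
        pairs.append((0, s - 1, ANNOTATED, site_class[s]))
        pairs.append((s, L - 1, site_class[s], ANNOTATED))
    if include_site_pairs:
        for a in locals_sorted:
            for b in locals_sorted:
                if a < b:
                    pairs.append((a, b - 1, site_class[a], site_class[b]))

    out = []
    for f, t, fc, tc in pairs:
        j = _make_junction(intron, seq, f, t, fc, tc, head_len, tail_len)
        if j is not None:
            out.append(j)
    return out


def build_distal_junctions(
    exon,
    upstream_intron: Intron,
    genome: GenomeSequence,
    head_len: int = 20,
    tail_len: int = 250,
) -> list[Junction]:
    """Junctions pairing the upstream intron's annotated 5'ss with every
    candidate 3'ss position inside the exon, with no motif requirement.

    The reference interval for local coordinates is the intron plus the exon
    in transcription order; candidate acceptor positions run over every exonic
    base (the junction's last base).
    """
    # contiguous genomic span intron+exon
    if upstream_intron.strand == "+":
        ref_start, ref_end = upstream_intron.start, exon.end
    else:
        ref_start, ref_end = exon.start, upstream_intron.end
    seq = genome.fetch(exon.contig, ref_start, ref_end, exon.strand)
    intron_len = upstream_intron.length
    exon_len = exon.end - exon.start

    # reuse the intron's gene id for reporting
    out = []
    for j_off in range(exon_len):
        t = intron_len + j_off
        j = _make_junction(
            upstream_intron,
            seq,
            0,
            t,
            ANNOTATED,
            EXONIC,
            head_len,
            tail_len,
            ref_start=ref_start,
            ref_end=ref_end,
        )
        if j is not None:
            out.append(j)
    return out


def discover_sites(
    introns: list[Intron],
    genome: GenomeSequence,
    n_decoys_per_site: int = 5,
    seed: int = 0,
) -> tuple[list[RSSite], list[RSSite]]:
    """Putative and decoy RS sites over a set of introns.

    Decoy draws are seeded per intron (seed + a stable hash of the intron id)
    so results do not depend on iteration order.
    """
    putative_all, decoy_all = [], []
    for intron in introns:
        putative = find_putative_sites(intron, genome)
        if not putative:
            continue
        sub_seed = (seed * 1_000_003 + zlib.crc32(intron.intron_id.encode())) % (
            2**31
        )
        decoys = generate_decoys(
            intron, genome, putative, n_decoys_per_site, rng_seed=sub_seed
        )
        putative_all.extend(putative)
        decoy_all.extend(decoys)
    return putative_all, decoy_all
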