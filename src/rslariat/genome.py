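"""Genome and annotation handling.

Coordinate model used throughout the package: 0-based, half-open intervals on
the forward genomic strand.  All motif and splice-site logic downstream
operates on *transcription-order* sequence, obtained by reverse-complementing
minus-strand features; stored coordinates always stay forward-strand.

Splice-site coordinate conventions (single genomic positions):

* a 5' splice site is the **first intronic base** in transcription order
  (the G of the GT dinucleotide);
* a 3' splice site is the **last intronic base** in transcription order
  (the G of the AG dinucleotide).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome: a mapping of contig name to uppercase sequence.

    Provides strand-aware sequence retrieval and genome-wide exact k-mer
    occurrence counting (used by the uniqueness filter).
    """

    def __init__(self, contigs: dict[str, str]):
        for name, seq in contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
        self.contigs = contigs

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def contig_length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on *contig*; minus strand returns the
        reverse complement (i.e. transcription-order sequence for a minus-strand
        feature)."""
        if start < 0 or end > len(self.contigs[contig]) or end < start:
            raise ValueError(
                f"interval [{start}, {end}) out of range for contig {contig!r}"
            )
        seq = self.contigs[contig][start:end]
        return reverse_complement(seq) if strand == "-" else seq

    def count_occurrences(self, kmer: str, both_strands: bool = True) -> int:
        """Number of (possibly overlapping) exact occurrences of *kmer* in the
        genome; with ``both_strands`` the reverse complement is also counted."""
        queries = [kmer]
        if both_strands:
            rc = reverse_complement(kmer)
            if rc != kmer:
                queries.append(rc)
        n = 0
        for seq in self.contigs.values():
            for q in queries:
                i = seq.find(q)
                while i != -1:
                    n += 1
                    i = seq.find(q, i + 1)
        return n


def load_genome(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; duplicate contig names and characters outside
    A/C/G/T/N are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    return GenomeSequence(contigs)


@dataclass(frozen=True)
class Intron:
    """A single intron as a forward-strand genomic interval.

    ``five_prime_ss`` / ``three_prime_ss`` are the first and last intronic
    bases in transcription order (see module docstring).
    """

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    constitutive: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("intron end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime_ss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime_ss(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def intron_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}:{self.strand}"

    def local_to_genomic(self, local: int) -> int:
        """Map a transcription-order offset (0 = first intronic base) to a
        forward-strand genomic coordinate."""
        if self.strand == "+":
            return self.start + local
        return self.end - 1 - local

    def genomic_to_local(self, pos: int) -> int:
        if self.strand == "+":
            return pos - self.start
        return self.end - 1 - pos

    def sequence(self, genome: GenomeSequence) -> str:
        """Transcription-order intron sequence."""
        return genome.fetch(self.contig, self.start, self.end, self.strand)


@dataclass(frozen=True)
class ExonRecord:
    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_ids: tuple[str, ...] = ()
    is_internal: bool = False
    is_cassette: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}:{self.strand}"


@dataclass
class Transcript:
    """An ordered exon chain; exons are sorted by genomic coordinate."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def sort_and_validate(self) -> None:
        self.exons.sort()
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon [{s},{e})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = e

    def intron_intervals(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (genomic order)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def introns(self, constitutive: bool = False) -> list[Intron]:
        return [
            Intron(self.contig, s, e, self.strand, self.gene_id, constitutive)
            for s, e in self.intron_intervals()
        ]

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        """mRNA sequence (transcription order)."""
        seq = "".join(
            genome.contigs[self.contig][s:e] for s, e in self.exons
        )
        return reverse_complement(seq) if self.strand == "-" else seq

    def pre_mrna_sequence(self, genome: GenomeSequence) -> str:
        return genome.fetch(
            self.contig, self.exons[0][0], self.exons[-1][1], self.strand
        )


def _load_gtf(path: Path) -> list[Transcript]:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, Transcript] = {}
    for feat in db.features_of_type("exon"):
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes["gene_id"][0]
        tx = by_tx.get(tx_id)
        if tx is None:
            tx = Transcript(tx_id, gene_id, feat.seqid, feat.strand)
            by_tx[tx_id] = tx
        if feat.seqid != tx.contig:
            raise ValueError(f"transcript {tx_id} spans contigs")
        # GTF is 1-based inclusive
        tx.exons.append((feat.start - 1, feat.end))
    for tx in by_tx.values():
        tx.sort_and_validate()
    return list(by_tx.values())


def _load_bed12(path: Path) -> list[Transcript]:
    transcripts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"not a BED12 line: {line[:60]!r}")
            contig, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            block_sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(block_sizes) != int(f[9]) or len(block_starts) != int(f[9]):
                raise ValueError(f"blockCount mismatch in BED12 line {name!r}")
            # gene id conventionally encoded as "gene|transcript" in the name
            gene_id, _, tx_id = name.partition("|")
            tx = Transcript(tx_id or name, gene_id, contig, strand)
            tx.exons = [
                (chrom_start + bs, chrom_start + bs + sz)
                for bs, sz in zip(block_starts, block_sizes)
            ]
            tx.sort_and_validate()
            transcripts.append(tx)
    return transcripts


def load_annotation(path: str | Path) -> list[Transcript]:
    """Load transcripts from a GTF (``.gtf``) or BED12 (``.bed``) file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".bed", ".bed12"}:
        return _load_bed12(path)
    return _load_gtf(path)


def constitutive_introns(transcripts: list[Transcript]) -> list[Intron]:
    """Introns present (as identical intervals) in *every* transcript of their
    gene.

    Genes whose transcripts share no intron -- including any gene with a
    single-exon transcript -- contribute nothing.
    """
    by_gene: dict[str, list[Transcript]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    result: list[Intron] = []
    for gene_id, txs in sorted(by_gene.items()):
        keys_per_tx = [
            {(tx.contig, s, e, tx.strand) for s, e in tx.intron_intervals()}
            for tx in txs
        ]
        shared = set.intersection(*keys_per_tx)
        for contig, s, e, strand in sorted(shared):
            result.append(Intron(contig, s, e, strand, gene_id, constitutive=True))
    return result


def internal_cassette_exons(transcripts: list[Transcript]) -> list[ExonRecord]:
    """Classify exons as internal and/or cassette across all transcripts.

    An exon is *internal* only if it is neither first nor last in every
    transcript (of any gene) that contains it.  It is *cassette* if some
    transcript of its gene lacks it while another contains it.
    """
    containing: dict[tuple, list[tuple[Transcript, int]]] = {}
    for tx in transcripts:
        for i, (s, e) in enumerate(tx.exons):
            containing.setdefault((tx.contig, s, e, tx.strand), []).append((tx, i))
    by_gene: dict[str, list[Transcript]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    records = []
    for (contig, s, e, strand), hits in sorted(containing.items()):
        internal = all(0 < i < len(tx.exons) - 1 for tx, i in hits)
        gene_ids = {tx.gene_id for tx, _ in hits}
        # cassette: some transcript of a containing gene lacks this exon
        cassette = False
        for g in gene_ids:
            for other in by_gene.get(g, []):
                if (s, e) not in set(other.exons):
                    cassette = True
                    break
            if cassette:
                break
        records.append(
            ExonRecord(
                contig,
                s,
                e,
                strand,
                sorted(gene_ids)[0],
                tuple(sorted(tx.transcript_id for tx, _ in hits)),
                is_internal=internal,
                is_cassette=cassette,
            )
        )
    return records


def upstream_intron_of(
    exon: ExonRecord, transcripts: list[Transcript]
) -> Intron | None:
    """The intron immediately upstream (transcription order) of *exon* in a
    transcript containing it; ``None`` if the exon is first everywhere or the
    upstream intron differs between transcripts (ambiguous)."""
    candidates = set()
    for tx in transcripts:
        key = (exon.start, exon.end)
        if tx.contig != exon.contig or tx.strand != exon.strand:
            continue
        if key not in set(tx.exons):
            continue
        i = tx.exons.index(key)
        if tx.strand == "+":
            if i == 0:
                continue
            s, e = tx.exons[i - 1][1], tx.exons[i][0]
        else:
            if i == len(tx.exons) - 1:
                continue
            s, e = tx.exons[i][1], tx.exons[i + 1][0]
        candidates.add((s, e, tx.gene_id))
    if len(candidates) != 1:
        return None
    s, e, gene_id = candidates.pop()
    return Intron(exon.contig, s, e, exon.strand, gene_id)


def annotated_splice_sites(
    transcripts: list[Transcript],
) -> tuple[set[tuple[str, str, int]], set[tuple[str, str, int]]]:
    """All annotated 5' and 3' splice-site coordinates as
    ``(contig, strand, position)`` sets, pooled over every transcript."""
    five, three = set(), set()
    for tx in transcripts:
        for intron in tx.introns():
            five.add((intron.contig, intron.strand, intron.five_prime_ss))
            three.add((intron.contig, intron.strand, intron.three_prime_ss))
    return five, three


def write_bed6(features, path: str | Path, name_attr: str = "intron_id") -> None:
    """Dump introns or exons as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for f in features:
            name = getattr(f, name_attr, None) or getattr(f, "exon_id", ".")
            fh.write(
                f"{f.contig}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n"
            )
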