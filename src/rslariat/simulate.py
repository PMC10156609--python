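"""Seeded simulator for recursive-splicing lariat data.

Generates a genome, multi-transcript annotation, repeat intervals, total
RNA-seq style reads and truth labels with the statistical structure the
pipeline assumes, so every stage can be tested without external data:

* genes with GT..AG introns; a subset of introns carry a planted recursive
  splice site embedding the Y(5+) N(0-4) YAG GT motif verbatim;
* every lariat-emitting acceptor (planted RS sites, annotated 3'ss of
  lariat-emitting introns, distal exonic acceptors) gets a planted
  branchpoint adenosine 10-60 nt upstream;
* lariat-spanning reads are built in inverted order -- loop sequence ending
  at the branchpoint, then sequence starting at the 5' splice site -- with
  the branchpoint base substituted at a configurable rate (the reverse-
  transcriptase signature);
* artifact classes: self-primed circularisation reads (the 5-mer at the fake
  branchpoint is engineered to equal the 5-mer upstream of the 5'ss),
  planted-site "traps" whose diagnostic 20-mers are duplicated elsewhere in
  the genome, sites overlapping planted simple-repeat intervals, and
  linear mRNA / pre-mRNA / genomic background reads;
* background base composition is uniform with pyrimidine runs probabilistically
  suppressed outside planted motifs, keeping the spurious motif density low
  but non-zero (knob: ``py_suppression``).

Every output byte is a deterministic function of the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pandas as pd

from .genome import GenomeSequence, Intron, Transcript
from .prefilter import ReadRecord

PURINES = "AG"
BASES = "ACGT"


@dataclass
class SimConfig:
    n_genes: int = 200
    n_rs_sites: int = 50           # clean planted recursive splice sites
    n_selfprimed_introns: int = 16  # introns emitting self-primed artifacts
    n_duplicated_sites: int = 8     # trap sites with duplicated 20-mers
    n_repeat_trap_sites: int = 4    # trap sites inside planted simple repeats
    n_conv_lariat_introns: int = 50
    n_cassette_genes: int = 12      # genes with a skipped internal exon

    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len_median: int = 150
    exon_len_sigma: float = 0.3
    min_exon_len: int = 80
    intron_len_median: int = 1800
    intron_len_sigma: float = 0.45
    min_intron_len: int = 120
    intergenic_len: tuple[int, int] = (200, 500)
    site_margin: int = 350          # planted-site distance from intron ends
    py_suppression: float = 0.8     # P(force purine after 4 consecutive Y)

    read_len: int = 100
    reads_per_junction: int = 5
    bp_mismatch_prob: float = 0.3
    seq_error_rate: float = 0.001
    informative_only: bool = True   # sample only mappable lariat prefixes
    artifact_reads_per_intron: int = 6
    artifact_bp_mismatch_prob: float = 0.3
    n_mrna_reads: int = 600
    n_pre_mrna_reads: int = 200
    n_genomic_reads: int = 200
    n_ambiguous_reads: int = 10
    distal_reads_per_site: int = 5

    seed: int = 1

    def validate(self) -> None:
        for name in (
            "bp_mismatch_prob", "seq_error_rate", "artifact_bp_mismatch_prob",
            "py_suppression",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_len < 41:
            raise ValueError("read_len must exceed 40 for mappable lariats")
        if 2 * self.site_margin + 20 >= int(
            self.intron_len_median * 3
        ):
            raise ValueError(
                "site_margin too large for the intron length distribution"
            )


def scaled_config(n_genes: int, seed: int = 1, **overrides) -> SimConfig:
    """A :class:`SimConfig` whose planted-class and background-read counts are
    scaled proportionally from the 200-gene defaults down (or up) to
    *n_genes*.  Explicit keyword overrides win."""
    base = SimConfig()
    f = n_genes / base.n_genes
    scaled = {
        name: max(1, round(getattr(base, name) * f))
        for name in (
            "n_rs_sites", "n_selfprimed_introns", "n_duplicated_sites",
            "n_repeat_trap_sites", "n_conv_lariat_introns",
            "n_cassette_genes", "n_mrna_reads", "n_pre_mrna_reads",
            "n_genomic_reads", "n_ambiguous_reads",
        )
    }
    scaled.update(n_genes=n_genes, seed=seed)
    scaled.update(overrides)
    return SimConfig(**scaled)


@dataclass(frozen=True)
class TruthSite:
    contig: str
    pos: int              # genomic coordinate of the donor G (transcription order)
    strand: str
    intron_id: str
    gene_id: str
    bp_pos: int           # branchpoint of the site acting as acceptor
    category: str         # clean | selfprimed | duplicated | repeat_trap


@dataclass(frozen=True)
class TruthDistalSite:
    contig: str
    acceptor_pos: int     # genomic coordinate of the exonic acceptor base
    strand: str
    gene_id: str
    exon_start: int
    exon_end: int
    bp_pos: int


@dataclass
class SimTruth:
    rs_sites: list[TruthSite] = field(default_factory=list)
    selfprimed_sites: list[TruthSite] = field(default_factory=list)
    duplicated_sites: list[TruthSite] = field(default_factory=list)
    repeat_trap_sites: list[TruthSite] = field(default_factory=list)
    distal_sites: list[TruthDistalSite] = field(default_factory=list)
    read_rows: list[dict] = field(default_factory=list)

    @property
    def reads(self) -> pd.DataFrame:
        return pd.DataFrame(self.read_rows)


@dataclass
class Simulation:
    config: SimConfig
    genome: GenomeSequence
    transcripts: list[Transcript]
    repeats: list[tuple[str, int, int, str]]  # contig, start, end, class
    reads: list[ReadRecord]
    truth: SimTruth
    introns: list[Intron] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sequence generation helpers

def _random_seq(rng: random.Random, n: int, py_suppression: float) -> list[str]:
    out: list[str] = []
    run = 0
    for _ in range(n):
        if run >= 4 and rng.random() < py_suppression:
            c = rng.choice(PURINES)
        else:
            c = rng.choice(BASES)
        run = run + 1 if c in "CT" else 0
        out.append(c)
    return out


def _lognormal_len(rng: random.Random, median: int, sigma: float, floor: int) -> int:
    import math

    return max(floor, int(round(median * math.exp(rng.gauss(0.0, sigma)))))


class _IntronBuild:
    """Mutable transcription-order intron under construction."""

    def __init__(self, chars: list[str]):
        self.chars = chars
        self.protected: list[tuple[int, int]] = [(0, 2), (len(chars) - 2, len(chars))]
        self.site_local: int | None = None
        self.site_bp_local: int | None = None
        self.end_bp_local: int | None = None
        self.category: str | None = None
        # (position, flavor) pairs; flavor 0 = plain self-primed point,
        # 1 = point in a duplicated context, 2 = point in a masked repeat
        self.artifact_ps: list[tuple[int, int]] = []

    def __len__(self) -> int:
        return len(self.chars)

    def protect(self, s: int, e: int) -> None:
        self.protected.append((s, e))

    def is_free(self, s: int, e: int) -> bool:
        return all(e <= ps or s >= pe for ps, pe in self.protected)


def _plant_motif(rng: random.Random, ib: _IntronBuild, margin: int) -> bool:
    """Embed a Y(5+) N(0-4) YAG GT motif; returns False if no room."""
    L = len(ib)
    if L < 2 * margin + 20:
        return False
    for _ in range(50):
        pos = rng.randrange(margin, L - margin)
        run_len = rng.randint(5, 8)
        gap = rng.randint(0, 2)
        start = pos - 3 - gap - run_len
        if not ib.is_free(start, pos + 2):
            continue
        motif = (
            [rng.choice("CT") for _ in range(run_len)]
            + [rng.choice(BASES) for _ in range(gap)]
            + [rng.choice("CT"), "A", "G", "G", "T"]
        )
        ib.chars[start : pos + 2] = motif
        ib.protect(start, pos + 2)
        ib.site_local = pos
        return True
    return False


def _plant_bp(rng: random.Random, ib: _IntronBuild, acceptor_local: int) -> int:
    """Plant a branchpoint adenosine 10-60 nt upstream of an acceptor
    position (the G of its AG); the 5-mer window around the branchpoint must
    not collide with protected spans."""
    for _ in range(100):
        d = rng.randint(10, 60)
        bp = acceptor_local - d
        if bp - 4 < 0:
            continue
        if ib.is_free(bp - 4, bp + 1):
            ib.chars[bp] = "A"
            ib.protect(bp - 4, bp + 1)
            return bp
    raise RuntimeError("could not place branchpoint; intron too crowded")


def _fix_selfprime_collision(
    rng: random.Random, ib: _IntronBuild, bp: int, upstream_5mers: list[str]
) -> None:
    """Ensure the 5-mer ending at *bp* differs from every listed 5-mer
    (upstream of the junction 5'ss); mutates one base next to the bp if not."""
    for _ in range(20):
        mer = "".join(ib.chars[bp - 4 : bp + 1])
        if all(mer != u for u in upstream_5mers):
            return
        ib.chars[bp - 1] = rng.choice(
            [c for c in BASES if c != ib.chars[bp - 1]]
        )
    raise RuntimeError("could not resolve self-priming 5-mer collision")


# ---------------------------------------------------------------------------
# genome simulation

class _GeneBuild:
    def __init__(self, gene_id: str, strand: str):
        self.gene_id = gene_id
        self.strand = strand
        self.exons: list[list[str]] = []       # transcription order
        self.introns: list[_IntronBuild] = []
        self.skip_exon: int | None = None      # cassette exon index (t-order)
        self.distal: dict | None = None
        # filled at assembly:
        self.start = 0
        self.length = 0
        self.contig = ""

    def upstream_exon_5mer(self, intron_idx: int) -> str:
        """Last 5 nt (transcription order) of the exon preceding an intron."""
        return "".join(self.exons[intron_idx][-5:])

    def t_offsets(self) -> tuple[list[int], list[int]]:
        """Transcription-order start offsets of exons and introns."""
        ex_off, in_off = [], []
        cur = 0
        for i, ex in enumerate(self.exons):
            ex_off.append(cur)
            cur += len(ex)
            if i < len(self.introns):
                in_off.append(cur)
                cur += len(self.introns[i])
        self.length = cur
        return ex_off, in_off

    def t_to_genomic(self, t: int) -> int:
        if self.strand == "+":
            return self.start + t
        return self.start + self.length - 1 - t


def simulate_genome(config: SimConfig) -> Simulation:
    """Build the genome, annotation, repeats and planted-site truth (reads are
    added separately by :func:`simulate_reads`)."""
    config.validate()
    rng = random.Random(config.seed)
    truth = SimTruth()

    genes: list[_GeneBuild] = []
    for gi in range(config.n_genes):
        gene = _GeneBuild(f"gene{gi:04d}", rng.choice("+-"))
        n_ex = rng.randint(*config.exons_per_gene)
        if gi < config.n_cassette_genes:
            n_ex = max(n_ex, 4)
        for ei in range(n_ex):
            gene.exons.append(
                _random_seq(
                    rng,
                    _lognormal_len(
                        rng, config.exon_len_median, config.exon_len_sigma,
                        config.min_exon_len,
                    ),
                    config.py_suppression,
                )
            )
            if ei < n_ex - 1:
                body = _random_seq(
                    rng,
                    _lognormal_len(
                        rng, config.intron_len_median, config.intron_len_sigma,
                        config.min_intron_len,
                    ) - 4,
                    config.py_suppression,
                )
                gene.introns.append(
                    _IntronBuild(["G", "T"] + body + ["A", "G"])
                )
        if gi < config.n_cassette_genes:
            gene.skip_exon = rng.randrange(1, n_ex - 1)
        genes.append(gene)

    # choose introns for the various planted classes
    eligible = [
        (g, k)
        for g in genes
        for k in range(len(g.introns))
        if len(g.introns[k]) >= 2 * config.site_margin + 20
        # keep cassette-exon flanking introns free of planted sites
        and not (g.skip_exon is not None and k in (g.skip_exon - 1, g.skip_exon))
    ]
    rng.shuffle(eligible)
    need = (
        config.n_rs_sites
        + config.n_selfprimed_introns
        + config.n_duplicated_sites
        + config.n_repeat_trap_sites
        + config.n_conv_lariat_introns
    )
    if len(eligible) < need:
        raise ValueError(
            f"infeasible config: need {need} long introns, only "
            f"{len(eligible)} available; increase n_genes or intron length"
        )
    cursor = 0

    def take(n):
        nonlocal cursor
        block = eligible[cursor : cursor + n]
        cursor += n
        return block

    planted: list[tuple[_GeneBuild, int, str]] = []
    for category, n in (
        ("clean", config.n_rs_sites),
        ("selfprimed", config.n_selfprimed_introns),
        ("duplicated", config.n_duplicated_sites),
        ("repeat_trap", config.n_repeat_trap_sites),
    ):
        for g, k in take(n):
            ib = g.introns[k]
            if not _plant_motif(rng, ib, config.site_margin):
                raise ValueError(
                    "infeasible config: intron too short/crowded for the motif"
                )
            ib.category = category
            ib.site_bp_local = _plant_bp(rng, ib, ib.site_local - 1)
            ib.end_bp_local = _plant_bp(rng, ib, len(ib) - 1)
            planted.append((g, k, category))
    conv_introns = take(config.n_conv_lariat_introns)
    for g, k in conv_introns:
        ib = g.introns[k]
        ib.category = "conv"
        ib.end_bp_local = _plant_bp(rng, ib, len(ib) - 1)

    # self-priming: resolve accidental 5-mer collisions for genuine lariat
    # branchpoints, and engineer deliberate matches for artifact introns
    for g, k, category in planted:
        ib = g.introns[k]
        up_annot = g.upstream_exon_5mer(k)
        up_site = "".join(ib.chars[ib.site_local - 5 : ib.site_local])
        if category == "selfprimed":
            # one fake circularisation point per artifact read, each carrying
            # a copy of the 5-mer that makes it look self-primed; self-priming
            # concentrates in repetitive contexts, so points cycle through
            # plain / duplicated-20-mer / masked-repeat flavors
            for idx in range(config.artifact_reads_per_intron):
                for _try in range(200):
                    p = rng.randrange(30, len(ib) - 30)
                    if ib.is_free(p - 19, p + 1):
                        ib.chars[p - 4 : p + 1] = list(up_annot)
                        ib.protect(p - 19, p + 1)
                        ib.artifact_ps.append((p, idx % 3))
                        break
                else:
                    raise RuntimeError("no room for self-primed artifact point")
        else:
            _fix_selfprime_collision(rng, ib, ib.site_bp_local, [up_annot])
            _fix_selfprime_collision(
                rng, ib, ib.end_bp_local, [up_site, up_annot]
            )
    for g, k in conv_introns:
        ib = g.introns[k]
        _fix_selfprime_collision(
            rng, ib, ib.end_bp_local, [g.upstream_exon_5mer(k)]
        )

    # distal exonic acceptors in cassette exons
    for g in genes:
        if g.skip_exon is None:
            continue
        exon = g.exons[g.skip_exon]
        ib = g.introns[g.skip_exon - 1]  # upstream intron (transcription order)
        d = rng.randint(10, min(60, len(exon) - 2))
        acceptor_off = len(exon) - 1          # exon's last base
        bp_off = acceptor_off - d
        exon[bp_off] = "A"
        up_annot = g.upstream_exon_5mer(g.skip_exon - 1)
        if "".join(exon[bp_off - 4 : bp_off + 1]) == up_annot:
            exon[bp_off - 1] = rng.choice(
                [c for c in BASES if c != exon[bp_off - 1]]
            )
        g.distal = {"acceptor_off": acceptor_off, "bp_off": bp_off, "d": d}

    # planted low-complexity stretches in a few unused introns
    repeats: list[tuple[str, int, int, str]] = []
    lowc_introns = [
        (g, k) for (g, k) in eligible[cursor:]
        if g.introns[k].category is None
    ][:6]
    lowc_marks = []
    for g, k in lowc_introns:
        ib = g.introns[k]
        s = rng.randrange(10, len(ib) - 50)
        ib.chars[s : s + 30] = list("TA" * 15)
        lowc_marks.append((g, k, s, s + 30))

    # ------------------------------------------------------------------
    # assembly onto one forward-strand contig
    contig_name = "chrS"
    parts: list[str] = []
    cur = 0
    transcripts: list[Transcript] = []
    introns_out: list[Intron] = []
    gene_of_intron: dict[str, tuple[_GeneBuild, int]] = {}

    for g in genes:
        cur += _append_spacer(parts, rng, config, cur)
        g.contig = contig_name
        g.start = cur
        ex_off, in_off = g.t_offsets()
        gene_seq = "".join(
            "".join(g.exons[i]) + ("".join(g.introns[i].chars) if i < len(g.introns) else "")
            for i in range(len(g.exons))
        )
        if g.strand == "-":
            from .genome import reverse_complement

            parts.append(reverse_complement(gene_seq))
        else:
            parts.append(gene_seq)
        cur += len(gene_seq)

        # forward-strand exon intervals, transcription order -> genomic
        def block(t_start, length):
            if g.strand == "+":
                return (g.start + t_start, g.start + t_start + length)
            return (
                g.start + g.length - t_start - length,
                g.start + g.length - t_start,
            )

        ex_blocks = [block(o, len(e)) for o, e in zip(ex_off, g.exons)]
        tx1 = Transcript(f"{g.gene_id}|tx1", g.gene_id, contig_name, g.strand)
        tx1.exons = sorted(ex_blocks)
        transcripts.append(tx1)
        if g.skip_exon is not None:
            tx2 = Transcript(f"{g.gene_id}|tx2", g.gene_id, contig_name, g.strand)
            tx2.exons = sorted(
                b for i, b in enumerate(ex_blocks) if i != g.skip_exon
            )
            transcripts.append(tx2)
        for k, o in enumerate(in_off):
            s, e = block(o, len(g.introns[k]))
            intr = Intron(contig_name, s, e, g.strand, g.gene_id)
            introns_out.append(intr)
            gene_of_intron[intr.intron_id] = (g, k)
            g.introns[k].genomic = intr  # type: ignore[attr-defined]

        # repeat intervals for low-complexity marks and repeat traps
        for gg, k, rs, re_ in lowc_marks:
            if gg is g:
                o = in_off[k]
                s, e = block(o + rs, re_ - rs)
                repeats.append((contig_name, s, e, "Low_complexity"))
        for k, ib in enumerate(g.introns):
            windows = []
            if ib.category == "repeat_trap":
                # cover the donor 20-mer window and the bp 20-mer window
                windows += [
                    (ib.site_local, ib.site_local + 20),
                    (ib.site_bp_local - 19, ib.site_bp_local + 1),
                ]
            if ib.category == "selfprimed":
                windows += [
                    (p - 19, p + 1) for p, flavor in ib.artifact_ps if flavor == 2
                ]
            for ls, le in windows:
                intr = ib.genomic
                a = intr.local_to_genomic(ls)
                b = intr.local_to_genomic(le - 1)
                repeats.append(
                    (contig_name, min(a, b), max(a, b) + 1, "Simple_repeat")
                )
    cur += _append_spacer(parts, rng, config, cur)

    # duplicated 20-mer traps: append copies after the genes
    dup_kmers: list[str] = []
    for g, k, category in planted:
        ib = g.introns[k]
        if category == "duplicated":
            dup_kmers.append(
                "".join(ib.chars[ib.site_local : ib.site_local + 20])
            )
            dup_kmers.append(
                "".join(ib.chars[ib.site_bp_local - 19 : ib.site_bp_local + 1])
            )
        if category == "selfprimed":
            dup_kmers.extend(
                "".join(ib.chars[p - 19 : p + 1])
                for p, flavor in ib.artifact_ps
                if flavor == 1
            )
    for kmer in dup_kmers:
        filler = "".join(_random_seq(rng, 40, config.py_suppression))
        parts.append(kmer + filler)
        cur += len(kmer) + 40

    genome = GenomeSequence({contig_name: "".join(parts)})

    # truth sites with genomic coordinates
    for g, k, category in planted:
        ib = g.introns[k]
        intr: Intron = ib.genomic
        site = TruthSite(
            contig=contig_name,
            pos=intr.local_to_genomic(ib.site_local),
            strand=g.strand,
            intron_id=intr.intron_id,
            gene_id=g.gene_id,
            bp_pos=intr.local_to_genomic(ib.site_bp_local),
            category=category,
        )
        {
            "clean": truth.rs_sites,
            "selfprimed": truth.selfprimed_sites,
            "duplicated": truth.duplicated_sites,
            "repeat_trap": truth.repeat_trap_sites,
        }[category].append(site)
    for g in genes:
        if g.distal is None:
            continue
        exon_block = _exon_genomic_block(g)
        acc = _exon_t_to_genomic(g, g.distal["acceptor_off"])
        bp = _exon_t_to_genomic(g, g.distal["bp_off"])
        truth.distal_sites.append(
            TruthDistalSite(
                contig=contig_name,
                acceptor_pos=acc,
                strand=g.strand,
                gene_id=g.gene_id,
                exon_start=exon_block[0],
                exon_end=exon_block[1],
                bp_pos=bp,
            )
        )

    sim = Simulation(
        config=config,
        genome=genome,
        transcripts=transcripts,
        repeats=sorted(repeats),
        reads=[],
        truth=truth,
        introns=introns_out,
    )
    sim._genes = genes  # type: ignore[attr-defined]
    return sim


def _append_spacer(parts, rng, config, cur) -> int:
    n = rng.randint(*config.intergenic_len)
    parts.append("".join(_random_seq(rng, n, config.py_suppression)))
    return n


def _exon_genomic_block(g: _GeneBuild) -> tuple[int, int]:
    ex_off, _ = g.t_offsets()
    o = ex_off[g.skip_exon]
    length = len(g.exons[g.skip_exon])
    if g.strand == "+":
        return (g.start + o, g.start + o + length)
    return (g.start + g.length - o - length, g.start + g.length - o)


def _exon_t_to_genomic(g: _GeneBuild, off_in_exon: int) -> int:
    ex_off, _ = g.t_offsets()
    t = ex_off[g.skip_exon] + off_in_exon
    return g.t_to_genomic(t)


# ---------------------------------------------------------------------------
# read simulation

def _apply_errors(
    rng: random.Random, chars: list[str], rate: float, skip: int | None
) -> int:
    n = 0
    if rate <= 0:
        return 0
    for i in range(len(chars)):
        if i == skip:
            continue
        if rng.random() < rate:
            chars[i] = rng.choice([c for c in BASES if c != chars[i]])
            n += 1
    return n


def _lariat_read(
    rng: random.Random,
    config: SimConfig,
    segment: str,
    f_local: int,
    bp_local: int,
    mismatch_prob: float,
) -> tuple[str, int, bool, int, bool]:
    """Construct one lariat-spanning read over a junction segment.

    Returns (seq, prefix_len, bp_substituted, n_errors, informative)."""
    n = config.read_len
    loop_len = bp_local - f_local + 1
    if config.informative_only:
        prefix_len = rng.randint(20, min(n - 20, loop_len))
    else:
        # read start uniform over the loop, as the informative-read model
        # assumes; short/long prefixes yield unmappable reads on purpose
        prefix_len = rng.randint(1, loop_len)
    prefix = segment[bp_local - prefix_len + 1 : bp_local + 1]
    suffix_len = max(0, n - prefix_len)
    suffix = segment[f_local : f_local + suffix_len]
    chars = list((prefix + suffix)[:n])
    bp_idx = prefix_len - 1 if prefix_len <= n else None
    substituted = False
    if bp_idx is not None and bp_idx < len(chars) and rng.random() < mismatch_prob:
        chars[bp_idx] = rng.choice([c for c in BASES if c != chars[bp_idx]])
        substituted = True
    n_err = _apply_errors(rng, chars, config.seq_error_rate, bp_idx)
    informative = (prefix_len - 1) >= 20 and prefix_len <= n - 20
    return "".join(chars), prefix_len, substituted, n_err, informative


def simulate_reads(sim: Simulation) -> Simulation:
    """Generate all read classes and their truth labels (in place)."""
    config = sim.config
    rng = random.Random(config.seed + 7_777_777)
    genes: list[_GeneBuild] = sim._genes  # type: ignore[attr-defined]
    counter = 0

    def emit(label: str, seq: str, **info):
        nonlocal counter
        rid = f"r{counter:06d}_{label}"
        counter += 1
        sim.reads.append(ReadRecord(rid, seq))
        row = {"read_id": rid, "label": label}
        row.update(info)
        sim.truth.read_rows.append(row)

    def lariat_reads(
        ib: _IntronBuild, f_local: int, bp_local: int, label: str,
        n_reads: int, mismatch_prob: float, five_genomic: int, bp_genomic: int,
        segment: str | None = None,
    ):
        seg = segment if segment is not None else "".join(ib.chars)
        for _ in range(n_reads):
            seq, plen, sub, nerr, inf = _lariat_read(
                rng, config, seg, f_local, bp_local, mismatch_prob
            )
            emit(
                label, seq,
                five_pos=five_genomic, bp_pos=bp_genomic, prefix_len=plen,
                bp_substituted=sub, n_errors=nerr, informative=inf,
                loop_len=bp_local - f_local + 1,
            )

    for g in genes:
        for k, ib in enumerate(g.introns):
            if ib.category is None:
                continue
            intr: Intron = ib.genomic  # type: ignore[attr-defined]
            if ib.category in ("clean", "duplicated", "repeat_trap"):
                # annotated 5'ss -> site-as-acceptor
                lariat_reads(
                    ib, 0, ib.site_bp_local, "rs_lariat",
                    config.reads_per_junction, config.bp_mismatch_prob,
                    intr.five_prime_ss, intr.local_to_genomic(ib.site_bp_local),
                )
                # site-as-donor -> annotated 3'ss
                lariat_reads(
                    ib, ib.site_local, ib.end_bp_local, "rs_lariat",
                    config.reads_per_junction, config.bp_mismatch_prob,
                    intr.local_to_genomic(ib.site_local),
                    intr.local_to_genomic(ib.end_bp_local),
                )
            elif ib.category == "conv":
                lariat_reads(
                    ib, 0, ib.end_bp_local, "conventional_lariat",
                    config.reads_per_junction, config.bp_mismatch_prob,
                    intr.five_prime_ss, intr.local_to_genomic(ib.end_bp_local),
                )
            elif ib.category == "selfprimed":
                seg = "".join(ib.chars)
                for p, _flavor in ib.artifact_ps:
                    plen = rng.randint(20, min(config.read_len - 20, p + 1))
                    prefix = seg[p - plen + 1 : p + 1]
                    suffix = seg[0 : config.read_len - plen]
                    chars = list(prefix + suffix)
                    sub = False
                    if rng.random() < config.artifact_bp_mismatch_prob:
                        chars[plen - 1] = rng.choice(
                            [c for c in BASES if c != chars[plen - 1]]
                        )
                        sub = True
                    nerr = _apply_errors(
                        rng, chars, config.seq_error_rate, plen - 1
                    )
                    emit(
                        "self_primed_artifact", "".join(chars),
                        five_pos=intr.five_prime_ss,
                        bp_pos=intr.local_to_genomic(p),
                        prefix_len=plen, bp_substituted=sub, n_errors=nerr,
                        informative=True, loop_len=p + 1,
                    )
        # distal exonic lariats
        if g.distal is not None and config.distal_reads_per_site > 0:
            k = g.skip_exon - 1
            ib = g.introns[k]
            seg = "".join(ib.chars) + "".join(g.exons[g.skip_exon])
            bp_seg = len(ib.chars) + g.distal["bp_off"]
            intr: Intron = ib.genomic  # type: ignore[attr-defined]
            lariat_reads(
                ib, 0, bp_seg, "rs_lariat_distal",
                config.distal_reads_per_site, config.bp_mismatch_prob,
                intr.five_prime_ss,
                _exon_t_to_genomic(g, g.distal["bp_off"]),
                segment=seg,
            )

    # background classes
    contig = sim.genome.contigs["chrS"]

    def linear_read(seq_pool: str) -> str | None:
        if len(seq_pool) < config.read_len:
            return None
        s = rng.randrange(0, len(seq_pool) - config.read_len + 1)
        chars = list(seq_pool[s : s + config.read_len])
        _apply_errors(rng, chars, config.seq_error_rate, None)
        return "".join(chars)

    mrna_pool = [tx for tx in sim.transcripts]
    for _ in range(config.n_mrna_reads):
        tx = rng.choice(mrna_pool)
        seq = linear_read(tx.spliced_sequence(sim.genome))
        if seq:
            emit("mrna", seq)
    for _ in range(config.n_pre_mrna_reads):
        tx = rng.choice(mrna_pool)
        seq = linear_read(tx.pre_mrna_sequence(sim.genome))
        if seq:
            emit("pre_mrna", seq)
    for _ in range(config.n_genomic_reads):
        seq = linear_read(contig)
        if seq:
            from .genome import reverse_complement

            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            emit("genomic", seq)
    for _ in range(config.n_ambiguous_reads):
        tx = rng.choice(mrna_pool)
        seq = linear_read(tx.spliced_sequence(sim.genome))
        if seq:
            chars = list(seq)
            n_amb = max(1, int(0.06 * len(chars)) + 1)
            for i in rng.sample(range(len(chars)), n_amb):
                chars[i] = "N"
            emit("mrna", "".join(chars), n_ambiguous=n_amb)
    return sim


def simulate(config: SimConfig | None = None) -> Simulation:
    """Genome + reads in one call."""
    sim = simulate_genome(config or SimConfig())
    return simulate_reads(sim)


# ---------------------------------------------------------------------------
# writers

def write_simulation(sim: Simulation, outdir) -> dict[str, str]:
    """Write FASTA / GTF / BED12 / repeats BED / FASTQ / truth TSVs."""
    from pathlib import Path

    from .prefilter import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    fa = outdir / "genome.fa"
    with open(fa, "w") as fh:
        for name, seq in sim.genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = str(fa)

    gtf = outdir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for tx in sim.transcripts:
            for s, e in tx.exons:
                fh.write(
                    f"{tx.contig}\tsim\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";\n'
                )
    paths["annotation"] = str(gtf)

    bed = outdir / "annotation.bed12"
    with open(bed, "w") as fh:
        for tx in sim.transcripts:
            s0 = tx.exons[0][0]
            e_last = tx.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in tx.exons) + ","
            starts = ",".join(str(s - s0) for s, e in tx.exons) + ","
            fh.write(
                f"{tx.contig}\t{s0}\t{e_last}\t{tx.transcript_id}\t0\t"
                f"{tx.strand}\t{s0}\t{e_last}\t0\t{len(tx.exons)}\t{sizes}\t{starts}\n"
            )
    paths["annotation_bed12"] = str(bed)

    rep = outdir / "repeats.bed"
    with open(rep, "w") as fh:
        for contig, s, e, cls in sim.repeats:
            fh.write(f"{contig}\t{s}\t{e}\t{cls}\t0\t+\n")
    paths["repeats"] = str(rep)

    fq = outdir / "reads.fastq"
    write_fastq(sim.reads, fq)
    paths["reads"] = str(fq)

    sites = outdir / "truth_sites.tsv"
    rows = []
    for lst, cat in (
        (sim.truth.rs_sites, "clean"),
        (sim.truth.selfprimed_sites, "selfprimed"),
        (sim.truth.duplicated_sites, "duplicated"),
        (sim.truth.repeat_trap_sites, "repeat_trap"),
    ):
        for s in lst:
            rows.append(
                {
                    "contig": s.contig, "pos": s.pos, "strand": s.strand,
                    "intron_id": s.intron_id, "gene_id": s.gene_id,
                    "bp_pos": s.bp_pos, "category": cat,
                }
            )
    pd.DataFrame(rows).to_csv(sites, sep="\t", index=False)
    paths["truth_sites"] = str(sites)

    reads_tsv = outdir / "truth_reads.tsv"
    sim.truth.reads.to_csv(reads_tsv, sep="\t", index=False)
    paths["truth_reads"] = str(reads_tsv)
    return paths
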