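"""The six-stage filter cascade applied to mapped junctions.

Intronic mode order: branchpoint mismatch -> high confidence -> proximity ->
repeats -> branchpoint distance -> self-primed.  Distal-exon mode replaces
the proximity and repeat stages with the exonic-branchpoint stage.

Every filter is a pure predicate evaluated against the *original* mapped
support: junction-level stages flag whole junctions, read-level stages flag
individual reads (a junction dies when none of its reads survive all enabled
read-level stages).  Because the stages are pure and combined by
intersection, the final surviving set does not depend on stage order; the
order only shapes the per-stage survivor counts and empirical FDR trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

from intervaltree import IntervalTree

from .genome import GenomeSequence
from .mapping import LariatRead
from .model import empirical_fdr
from .sites import ANNOTATED, Junction

logger = logging.getLogger(__name__)

INTRONIC_ORDER = [
    "bp_mismatch",
    "high_confidence",
    "proximity",
    "repeats",
    "bp_distance",
    "self_primed",
]
DISTAL_ORDER = [
    "bp_mismatch",
    "high_confidence",
    "bp_distance",
    "exonic_bp",
    "self_primed",
]


@dataclass
class JunctionSupport:
    """All mapped lariat reads supporting one junction."""

    junction: Junction
    reads: list[LariatRead] = field(default_factory=list)

    @property
    def total_weight(self) -> Fraction:
        return sum((r.weight for r in self.reads), Fraction(0))

    @property
    def mismatch_weight(self) -> Fraction:
        return sum(
            (r.weight for r in self.reads if r.bp_mismatch), Fraction(0)
        )

    @property
    def has_mismatch_read(self) -> bool:
        return any(r.bp_mismatch for r in self.reads)

    @property
    def primary_bp(self) -> int:
        """Best-supported branchpoint: highest summed weight, ties broken
        toward the 3'ss, then by coordinate (deterministic)."""
        acc: dict[int, Fraction] = {}
        dist: dict[int, int] = {}
        for r in self.reads:
            acc[r.bp_pos] = acc.get(r.bp_pos, Fraction(0)) + r.weight
            dist[r.bp_pos] = min(dist.get(r.bp_pos, r.bp_to_3ss), r.bp_to_3ss)
        return min(acc, key=lambda bp: (-acc[bp], dist[bp], bp))


def group_support(lariats: list[LariatRead]) -> list[JunctionSupport]:
    by_junction: dict[str, JunctionSupport] = {}
    for lr in lariats:
        sup = by_junction.get(lr.junction.junction_id)
        if sup is None:
            sup = by_junction[lr.junction.junction_id] = JunctionSupport(
                lr.junction
            )
        sup.reads.append(lr)
    return list(by_junction.values())


@dataclass
class CascadeContext:
    """Static inputs the stage predicates need."""

    genome: GenomeSequence
    annotated_5ss: set[tuple[str, str, int]] = field(default_factory=set)
    annotated_3ss: set[tuple[str, str, int]] = field(default_factory=set)
    repeat_trees: dict[str, IntervalTree] = field(default_factory=dict)
    n_putative_sites: int = 0
    n_decoy_sites: int = 0
    exon_bounds: dict[str, tuple[int, int]] | None = None  # intron_id -> exon

    proximity_window: int = 100
    mismatch_fraction: float = 0.05
    bp_dist_min: int = 10
    bp_dist_max: int = 60
    selfprime_k: int = 5
    uniq_k: int = 20


# ---------------------------------------------------------------------------
# individual predicates

def require_bp_mismatch(support: JunctionSupport) -> bool:
    """At least one supporting read with the branchpoint mismatch
    (unweighted existence)."""
    return support.has_mismatch_read


def _five_ss_kmer(j: Junction, genome: GenomeSequence, k: int) -> str | None:
    """k-mer starting at the junction's 5'ss, transcription order."""
    pos = j.five_genomic
    if j.strand == "+":
        s, e = pos, pos + k
    else:
        s, e = pos - k + 1, pos + 1
    if s < 0 or e > genome.contig_length(j.contig):
        return None
    return genome.fetch(j.contig, s, e, j.strand)


def _bp_kmer(j: Junction, genome: GenomeSequence, bp: int, k: int) -> str | None:
    """k-mer ending at (and including) the branchpoint, transcription order."""
    if j.strand == "+":
        s, e = bp - k + 1, bp + 1
    else:
        s, e = bp, bp + k
    if s < 0 or e > genome.contig_length(j.contig):
        return None
    return genome.fetch(j.contig, s, e, j.strand)


def high_confidence(support: JunctionSupport, ctx: CascadeContext) -> bool:
    """>=5% of mapping reads (weighted) carry a clean branchpoint mismatch,
    and the 20-mers at the 5'ss and ending at the best-supported branchpoint
    each occur exactly once in the genome (both strands searched)."""
    total = support.total_weight
    if total == 0 or support.mismatch_weight / total < Fraction(
        str(ctx.mismatch_fraction)
    ):
        return False
    j = support.junction
    five_kmer = _five_ss_kmer(j, ctx.genome, ctx.uniq_k)
    bp_kmer = _bp_kmer(j, ctx.genome, support.primary_bp, ctx.uniq_k)
    if five_kmer is None or bp_kmer is None:
        return False
    return (
        ctx.genome.count_occurrences(five_kmer) == 1
        and ctx.genome.count_occurrences(bp_kmer) == 1
    )


def filter_proximity(support: JunctionSupport, ctx: CascadeContext) -> bool:
    """Drop junctions whose RS/decoy site lies within ``proximity_window`` nt
    of an annotated splice site of the same type (5' or 3')."""
    j = support.junction

    def near(pos: int, sites: set) -> bool:
        return any(
            c == j.contig and s == j.strand
            and abs(p - pos) <= ctx.proximity_window
            for (c, s, p) in sites
        )

    if j.five_class != ANNOTATED and near(j.five_genomic, ctx.annotated_5ss):
        return False
    if j.three_class != ANNOTATED and near(j.three_genomic, ctx.annotated_3ss):
        return False
    return True


def filter_repeats(support: JunctionSupport, ctx: CascadeContext) -> bool:
    """Drop junctions whose 20-nt 5'ss window (including and downstream of the
    5'ss) or branchpoint window (upstream of and including the best-supported
    branchpoint) overlaps a simple-repeat / low-complexity interval by >=1
    base."""
    j = support.junction
    tree = ctx.repeat_trees.get(j.contig)
    if tree is None:
        return True
    k = ctx.uniq_k
    five = j.five_genomic
    bp = support.primary_bp
    if j.strand == "+":
        windows = [(five, five + k), (bp - k + 1, bp + 1)]
    else:
        windows = [(five - k + 1, five + 1), (bp, bp + k)]
    for s, e in windows:
        if tree.overlap(max(s, 0), e):
            return False
    return True


def filter_bp_distance(
    lariat: LariatRead, ctx: CascadeContext
) -> bool:
    """Keep reads whose branchpoint-to-3'ss distance falls inside the
    configured window (default 10-60 nt, both ends inclusive)."""
    return ctx.bp_dist_min <= lariat.bp_to_3ss <= ctx.bp_dist_max


def filter_self_primed(lariat: LariatRead, ctx: CascadeContext) -> bool:
    """Drop reads whose 5-mer upstream of and including the branchpoint
    equals the 5-mer immediately upstream of the 5' splice site -- the
    signature of an intramolecular self-priming artifact."""
    j = lariat.junction
    genome = ctx.genome
    k = ctx.selfprime_k
    five = j.five_genomic
    bp = lariat.bp_pos
    if j.strand == "+":
        up5 = (five - k, five)
        upbp = (bp - k + 1, bp + 1)
    else:
        up5 = (five + 1, five + k + 1)
        upbp = (bp, bp + k)
    clen = genome.contig_length(j.contig)
    for s, e in (up5, upbp):
        if s < 0 or e > clen:
            logger.warning(
                "self-primed filter: 5-mer unavailable near contig edge for "
                "read %s; keeping", lariat.read_id,
            )
            return True
    a = genome.fetch(j.contig, *up5, j.strand)
    b = genome.fetch(j.contig, *upbp, j.strand)
    return a != b


def filter_exonic_bp(lariat: LariatRead, ctx: CascadeContext) -> bool:
    """Distal mode: the branchpoint must lie within the exon body, excluding
    its first and last base."""
    if ctx.exon_bounds is None:
        return True
    bounds = ctx.exon_bounds.get(lariat.junction.junction_id)
    if bounds is None:
        return False
    start, end = bounds
    return start + 1 <= lariat.bp_pos <= end - 2


# ---------------------------------------------------------------------------
# cascade

JUNCTION_STAGES = {
    "bp_mismatch": lambda sup, ctx: require_bp_mismatch(sup),
    "high_confidence": high_confidence,
    "proximity": filter_proximity,
    "repeats": filter_repeats,
}
READ_STAGES = {
    "bp_distance": filter_bp_distance,
    "self_primed": filter_self_primed,
    "exonic_bp": filter_exonic_bp,
}


@dataclass
class StageReport:
    stage: str
    n_putative: int
    n_decoy: int
    putative_weight: float
    decoy_weight: float
    fdr: float  # NaN when undefined


@dataclass
class FilterReport:
    stages: list[StageReport]
    surviving: list[JunctionSupport]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "putative_junctions": s.n_putative,
                    "decoy_junctions": s.n_decoy,
                    "putative_weight": s.putative_weight,
                    "decoy_weight": s.decoy_weight,
                    "fdr": s.fdr,
                }
                for s in self.stages
            ]
        )


def run_cascade(
    supports: list[JunctionSupport],
    ctx: CascadeContext,
    order: list[str] | None = None,
    disabled: set[str] | None = None,
) -> FilterReport:
    """Apply the stage cascade and tally survivors and empirical FDR.

    Conventional (annotated-annotated) junctions pass through untouched by
    site-specific stages but are excluded from the putative/decoy accounting.
    """
    order = list(order if order is not None else INTRONIC_ORDER)
    disabled = disabled or set()
    order = [s for s in order if s not in disabled]

    # pure per-stage verdicts on the original support
    jpass: dict[str, list[bool]] = {}
    rmask: dict[str, list[list[bool]]] = {}
    for stage in order:
        if stage in JUNCTION_STAGES:
            pred = JUNCTION_STAGES[stage]
            jpass[stage] = [pred(sup, ctx) for sup in supports]
            rmask[stage] = [[True] * len(sup.reads) for sup in supports]
        else:
            pred = READ_STAGES[stage]
            jpass[stage] = [True] * len(supports)
            rmask[stage] = [
                [pred(r, ctx) for r in sup.reads] for sup in supports
            ]

    def tally(alive_masks) -> StageReport:
        n_put = n_dec = 0
        w_put = w_dec = Fraction(0)
        for sup, (alive, mask) in zip(supports, alive_masks):
            if not alive or not any(mask):
                continue
            w = sum(
                (r.weight for r, keep in zip(sup.reads, mask) if keep),
                Fraction(0),
            )
            if sup.junction.kind == "putative":
                n_put += 1
                w_put += w
            elif sup.junction.kind == "decoy":
                n_dec += 1
                w_dec += w
        est = empirical_fdr(
            float(w_put), float(w_dec), ctx.n_putative_sites, ctx.n_decoy_sites
        )
        return StageReport(
            "", n_put, n_dec, float(w_put), float(w_dec), est.fdr
        )

    alive = [(True, [True] * len(sup.reads)) for sup in supports]
    stages = []
    initial = tally(alive)
    initial.stage = "mapped"
    stages.append(initial)
    for stage in order:
        alive = [
            (
                ok and jpass[stage][i],
                [m and k for m, k in zip(mask, rmask[stage][i])],
            )
            for i, (ok, mask) in enumerate(alive)
        ]
        rep = tally(alive)
        rep.stage = stage
        stages.append(rep)

    surviving = []
    for sup, (ok, mask) in zip(supports, alive):
        if ok and any(mask):
            kept = [r for r, k in zip(sup.reads, mask) if k]
            surviving.append(JunctionSupport(sup.junction, kept))
    return FilterReport(stages, surviving)


def surviving_sites(report: FilterReport) -> list[tuple[str, int, str, str]]:
    """Distinct non-annotated sites supported by >=1 surviving junction, as
    (contig, genomic position of the site's donor G, strand, class)."""
    sites = set()
    for sup in report.surviving:
        j = sup.junction
        if j.five_class != ANNOTATED:
            sites.add((j.contig, j.five_genomic, j.strand, j.five_class))
        if j.three_class != ANNOTATED:
            # acceptor coordinate is pos-1; report the donor-G convention pos
            if j.strand == "+":
                sites.add((j.contig, j.three_genomic + 1, j.strand, j.three_class))
            else:
                sites.add((j.contig, j.three_genomic - 1, j.strand, j.three_class))
    return sorted(sites)
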