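"""End-to-end orchestration: discovery -> junctions -> prefilter -> mapping ->
filter cascade -> FDR, for the intronic and distal-exonic modes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .config import PipelineConfig
from .filters import (
    DISTAL_ORDER,
    INTRONIC_ORDER,
    CascadeContext,
    FilterReport,
    group_support,
    run_cascade,
    surviving_sites,
)
from .genome import (
    GenomeSequence,
    Intron,
    Transcript,
    annotated_splice_sites,
    constitutive_introns,
    internal_cassette_exons,
    upstream_intron_of,
)
from .mapping import MappingStats, map_lariats
from .model import (
    fit_power_law,
    informative_probability_table,
    weighted_length_distribution,
)
from .prefilter import PrefilterStats, ReadRecord, prefilter_reads
from .sites import (
    Junction,
    RSSite,
    build_distal_junctions,
    build_junctions,
    discover_sites,
)

logger = logging.getLogger(__name__)

REPEAT_CLASSES = {"simple_repeat", "low_complexity"}


def load_repeats(path) -> list[tuple[str, int, int, str]]:
    """Repeat intervals from BED (4th column = class) or RepeatMasker .out.

    Only simple-repeat and low-complexity classes are retained.
    """
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    is_rmout = any(
        ln.strip().startswith("SW") or "matching repeat" in ln
        for ln in lines[:3]
    )
    if is_rmout:
        for ln in lines[3:]:
            f = ln.split()
            if len(f) < 11:
                continue
            contig, s, e, cls = f[4], int(f[5]) - 1, int(f[6]), f[10]
            if cls.lower().replace("/", "_") in REPEAT_CLASSES:
                out.append((contig, s, e, cls))
    else:
        for ln in lines:
            if not ln.strip() or ln.startswith(("#", "track")):
                continue
            f = ln.split("\t")
            cls = f[3] if len(f) > 3 else ""
            if cls.lower() in REPEAT_CLASSES:
                out.append((f[0], int(f[1]), int(f[2]), cls))
    return out


def repeat_trees(
    repeats: list[tuple[str, int, int, str]]
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for contig, s, e, _cls in repeats:
        trees.setdefault(contig, IntervalTree()).addi(s, e)
    return trees


@dataclass
class PipelineResult:
    config: PipelineConfig
    introns: list[Intron]
    putative: list[RSSite]
    decoys: list[RSSite]
    junctions: list[Junction]
    prefilter_stats: PrefilterStats
    mapping_stats: MappingStats
    supports: list  # pre-cascade JunctionSupport records
    report: FilterReport
    sites: list[tuple[str, int, str, str]]

    def lariat_frame(self) -> pd.DataFrame:
        """The mapped (pre-cascade) weighted lariat table."""
        rows = []
        for sup in self.supports:
            for r in sup.reads:
                rows.append(
                    {
                        "read_id": r.read_id,
                        "gene_id": r.junction.gene_id,
                        "junction_id": r.junction.junction_id,
                        "five_class": r.junction.five_class,
                        "five_pos": r.junction.five_genomic,
                        "three_class": r.junction.three_class,
                        "three_pos": r.junction.three_genomic,
                        "bp_pos": r.bp_pos,
                        "bp_mismatch": r.bp_mismatch,
                        "weight": float(r.weight),
                        "bp_to_3ss": r.bp_to_3ss,
                    }
                )
        return pd.DataFrame(rows)

    def site_frame(self) -> pd.DataFrame:
        rows = []
        for sup in self.report.surviving:
            j = sup.junction
            rows.append(
                {
                    "junction_id": j.junction_id,
                    "gene_id": j.gene_id,
                    "contig": j.contig,
                    "strand": j.strand,
                    "five_class": j.five_class,
                    "five_pos": j.five_genomic,
                    "three_class": j.three_class,
                    "three_pos": j.three_genomic,
                    "primary_bp": sup.primary_bp,
                    "n_reads": len(sup.reads),
                    "total_weight": float(sup.total_weight),
                    "mismatch_weight": float(sup.mismatch_weight),
                }
            )
        return pd.DataFrame(rows)


def build_junction_library(
    introns: list[Intron],
    genome: GenomeSequence,
    putative: list[RSSite],
    decoys: list[RSSite],
    config: PipelineConfig,
) -> list[Junction]:
    """Conventional junctions for every intron, plus putative-set and
    decoy-set junction libraries (built independently per set)."""
    by_intron: dict[str, dict[str, list[RSSite]]] = {}
    for s in putative:
        by_intron.setdefault(s.intron.intron_id, {}).setdefault(
            "putative", []
        ).append(s)
    for s in decoys:
        by_intron.setdefault(s.intron.intron_id, {}).setdefault(
            "decoy", []
        ).append(s)
    junctions: dict[str, Junction] = {}
    for intron in introns:
        groups = by_intron.get(intron.intron_id, {})
        for sites in (groups.get("putative", []), groups.get("decoy", [])):
            for j in build_junctions(
                intron, genome, sites, config.head_len, config.tail_len,
                include_site_pairs=config.include_site_pairs,
            ):
                junctions.setdefault(j.junction_id, j)
    return list(junctions.values())


def run_intronic(
    genome: GenomeSequence,
    transcripts: list[Transcript],
    reads: list[ReadRecord],
    repeats: list[tuple[str, int, int, str]] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    introns = constitutive_introns(transcripts)
    logger.info("constitutive introns: %d", len(introns))
    putative, decoys = discover_sites(
        introns, genome, config.decoys_per_site, config.seed
    )
    logger.info("putative sites: %d, decoy sites: %d", len(putative), len(decoys))
    junctions = build_junction_library(introns, genome, putative, decoys, config)
    logger.info("junction library: %d", len(junctions))

    kept, prestats = prefilter_reads(
        reads, genome, transcripts,
        config.max_ambiguous_frac, config.linear_mismatch_rate,
    )
    logger.info(
        "prefilter: %d in, %d ambiguous, %d transcriptome, %d genome, %d kept",
        prestats.n_input, prestats.n_ambiguous, prestats.n_transcriptome,
        prestats.n_genome, prestats.n_retained,
    )
    lariats, mapstats = map_lariats(
        junctions, kept, config.head_len, config.min_prefix
    )
    logger.info("lariat reads mapped: %d", mapstats.n_lariat)

    five_set, three_set = annotated_splice_sites(transcripts)
    ctx = CascadeContext(
        genome=genome,
        annotated_5ss=five_set,
        annotated_3ss=three_set,
        repeat_trees=repeat_trees(repeats or []),
        n_putative_sites=max(1, len(putative)),
        n_decoy_sites=max(1, len(decoys)),
        proximity_window=config.proximity_window,
        mismatch_fraction=config.mismatch_fraction,
        bp_dist_min=config.bp_dist_min,
        bp_dist_max=config.bp_dist_max,
        selfprime_k=config.selfprime_k,
        uniq_k=config.head_len,
    )
    supports = group_support(lariats)
    report = run_cascade(
        supports, ctx, INTRONIC_ORDER, disabled=set(config.disabled_filters)
    )
    return PipelineResult(
        config, introns, putative, decoys, junctions, prestats, mapstats,
        supports, report, surviving_sites(report),
    )


def run_distal(
    genome: GenomeSequence,
    transcripts: list[Transcript],
    reads: list[ReadRecord],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Distal-exonic mode: junctions pair annotated 5'ss of upstream introns
    with every exonic acceptor candidate of internal cassette exons; the
    cascade swaps proximity/repeat stages for the exonic-branchpoint stage."""
    config = config or PipelineConfig(mode="distal")
    exons = [
        e for e in internal_cassette_exons(transcripts)
        if e.is_internal and e.is_cassette
    ]
    junctions: list[Junction] = []
    exon_bounds: dict[str, tuple[int, int]] = {}
    for exon in exons:
        upstream = upstream_intron_of(exon, transcripts)
        if upstream is None:
            continue
        js = build_distal_junctions(
            exon, upstream, genome, config.head_len, config.tail_len
        )
        for j in js:
            exon_bounds[j.junction_id] = (exon.start, exon.end)
        junctions.extend(js)
    logger.info(
        "distal junctions: %d over %d cassette exons", len(junctions), len(exons)
    )

    kept, prestats = prefilter_reads(
        reads, genome, transcripts,
        config.max_ambiguous_frac, config.linear_mismatch_rate,
    )
    lariats, mapstats = map_lariats(
        junctions, kept, config.head_len, config.min_prefix
    )
    five_set, three_set = annotated_splice_sites(transcripts)
    ctx = CascadeContext(
        genome=genome,
        annotated_5ss=five_set,
        annotated_3ss=three_set,
        n_putative_sites=max(1, len(junctions)),
        n_decoy_sites=1,  # no decoy library in distal mode
        exon_bounds=exon_bounds,
        mismatch_fraction=config.mismatch_fraction,
        bp_dist_min=config.bp_dist_min,
        bp_dist_max=config.bp_dist_max,
        selfprime_k=config.selfprime_k,
        uniq_k=config.head_len,
    )
    supports = group_support(lariats)
    report = run_cascade(
        supports, ctx, DISTAL_ORDER, disabled=set(config.disabled_filters)
    )
    return PipelineResult(
        config, [], [], [], junctions, prestats, mapstats, supports, report,
        surviving_sites(report),
    )


@dataclass
class ModelResult:
    probabilities: pd.DataFrame
    fits: dict[int, tuple[float, float, int]]  # read_len -> (a, b, n_used)
    length_distribution: pd.DataFrame


def run_informative_model(
    introns: list[Intron], config: PipelineConfig | None = None
) -> ModelResult:
    """Informative-read probabilities over the intron set, power-law fits per
    read length, and the 100-nt weighted length distribution."""
    config = config or PipelineConfig()
    lens = [i.length for i in introns]
    table = informative_probability_table(
        lens, config.read_len_grid, config.bp_offset
    )
    fits = {}
    for n in config.read_len_grid:
        try:
            fits[n] = fit_power_law(table["intron_len"], table[f"p_read{n}"])
        except ValueError:
            logger.warning("power-law fit skipped for read length %d", n)
    dist = weighted_length_distribution(lens, 100, config.bp_offset)
    return ModelResult(table, fits, dist)
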