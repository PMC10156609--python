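import random
from fractions import Fraction

import pytest
from intervaltree import IntervalTree

from rslariat import (
    CascadeContext,
    GenomeSequence,
    JunctionSupport,
    filter_bp_distance,
    filter_exonic_bp,
    filter_proximity,
    filter_repeats,
    filter_self_primed,
    high_confidence,
    require_bp_mismatch,
    run_cascade,
)
from rslariat.filters import DISTAL_ORDER, INTRONIC_ORDER
from rslariat.mapping import LariatRead

from .conftest import make_junction
from .helpers import random_dna


def _junction(seed=0, length=1000, **kw):
    rng = random.Random(seed)
    seq = list(random_dna(rng, length))
    seq[0:2] = "GT"
    seq[-2:] = "AG"
    return make_junction("".join(seq), **kw)


def lariat(j, bp_pos=500, bp_mismatch=False, bp_to_3ss=25, weight=1, rid="r"):
    return LariatRead(
        read_id=rid,
        junction=j,
        bp_pos=bp_pos,
        bp_mismatch=bp_mismatch,
        prefix_len=30,
        bp_to_3ss=bp_to_3ss,
        weight=Fraction(weight),
    )


def ctx_for(genome, **kw):
    return CascadeContext(genome=genome, **kw)


class TestBpMismatchExistence:
    def test_no_mismatch_fails(self, small_sim):
        j, g = _junction()
        sup = JunctionSupport(j, [lariat(j, rid=f"r{i}") for i in range(10)])
        assert not require_bp_mismatch(sup)

    def test_one_mismatch_passes(self):
        j, g = _junction()
        sup = JunctionSupport(j, [lariat(j, bp_mismatch=True)])
        assert require_bp_mismatch(sup)

    def test_fractional_weight_still_counts(self):
        j, g = _junction()
        sup = JunctionSupport(
            j, [lariat(j, bp_mismatch=True, weight=Fraction(1, 2))]
        )
        assert require_bp_mismatch(sup)


class TestHighConfidence:
    def test_five_percent_boundary(self):
        j, g = _junction(seed=1, length=2000)
        bp = j.tail_offset_to_genomic(224)
        reads = [lariat(j, bp_pos=bp, rid=f"r{i}") for i in range(19)]
        reads.append(lariat(j, bp_pos=bp, bp_mismatch=True, rid="m"))
        assert high_confidence(JunctionSupport(j, reads), ctx_for(g))
        # 1 of 21 = 4.8 % fails
        reads.append(lariat(j, bp_pos=bp, rid="extra"))
        assert not high_confidence(JunctionSupport(j, reads), ctx_for(g))

    def test_zero_mismatch_reads_fail(self):
        j, g = _junction(seed=2, length=2000)
        bp = j.tail_offset_to_genomic(224)
        reads = [lariat(j, bp_pos=bp, rid=f"r{i}") for i in range(19)]
        assert not high_confidence(JunctionSupport(j, reads), ctx_for(g))

    def test_duplicated_donor_kmer_fails(self):
        j, g = _junction(seed=3, length=2000)
        bp = j.tail_offset_to_genomic(224)
        sup = JunctionSupport(j, [lariat(j, bp_pos=bp, bp_mismatch=True)])
        assert high_confidence(sup, ctx_for(g))
        donor_kmer = g.fetch(j.contig, j.five_genomic, j.five_genomic + 20, "+")
        dup = GenomeSequence(
            {j.contig: g.contigs[j.contig] + "A" * 30 + donor_kmer}
        )
        assert not high_confidence(sup, ctx_for(dup))

    def test_duplicated_bp_kmer_fails(self):
        j, g = _junction(seed=4, length=2000)
        bp = j.tail_offset_to_genomic(224)
        sup = JunctionSupport(j, [lariat(j, bp_pos=bp, bp_mismatch=True)])
        bp_kmer = g.fetch(j.contig, bp - 19, bp + 1, "+")
        dup = GenomeSequence(
            {j.contig: g.contigs[j.contig] + "A" * 30 + bp_kmer}
        )
        assert not high_confidence(sup, ctx_for(dup))


class TestProximity:
    @pytest.mark.parametrize("distance,kept", [(100, False), (101, True)])
    def test_same_type_boundary(self, distance, kept):
        j, g = _junction(five_class="RS")
        annotated = {(j.contig, j.strand, j.five_genomic + distance)}
        ctx = ctx_for(g, annotated_5ss=annotated)
        assert filter_proximity(JunctionSupport(j, []), ctx) is kept

    def test_different_type_ignored(self):
        j, g = _junction(five_class="RS")
        ctx = ctx_for(
            g, annotated_3ss={(j.contig, j.strand, j.five_genomic + 50)}
        )
        assert filter_proximity(JunctionSupport(j, []), ctx)

    def test_annotated_sides_exempt(self):
        j, g = _junction()  # both sides annotated
        ctx = ctx_for(
            g,
            annotated_5ss={(j.contig, j.strand, j.five_genomic + 1)},
            annotated_3ss={(j.contig, j.strand, j.three_genomic + 1)},
        )
        assert filter_proximity(JunctionSupport(j, []), ctx)


class TestRepeats:
    def _sup(self, seed=5):
        j, g = _junction(seed=seed, length=2000)
        bp = j.tail_offset_to_genomic(224)
        return JunctionSupport(j, [lariat(j, bp_pos=bp)]), j, g, bp

    def test_bp_window_inside_repeat_dropped(self):
        sup, j, g, bp = self._sup()
        tree = IntervalTree()
        tree.addi(bp - 30, bp + 10)
        assert not filter_repeats(sup, ctx_for(g, repeat_trees={j.contig: tree}))

    def test_single_base_overlap_dropped(self):
        sup, j, g, bp = self._sup()
        tree = IntervalTree()
        tree.addi(bp, bp + 1)  # exactly the branchpoint base
        assert not filter_repeats(sup, ctx_for(g, repeat_trees={j.contig: tree}))

    def test_adjacent_interval_kept(self):
        sup, j, g, bp = self._sup()
        tree = IntervalTree()
        tree.addi(bp + 1, bp + 30)  # starts one base past the window
        assert filter_repeats(sup, ctx_for(g, repeat_trees={j.contig: tree}))

    def test_non_simple_classes_not_loaded(self, tmp_path):
        from rslariat import load_repeats

        bed = tmp_path / "r.bed"
        bed.write_text(
            "c\t10\t50\tSimple_repeat\t0\t+\n"
            "c\t60\t90\tLINE\t0\t+\n"
            "c\t95\t99\tLow_complexity\t0\t+\n"
        )
        got = load_repeats(bed)
        assert [(s, e) for _, s, e, _ in got] == [(10, 50), (95, 99)]


class TestBpDistance:
    @pytest.mark.parametrize(
        "d,kept", [(9, False), (10, True), (25, True), (60, True), (61, False)]
    )
    def test_window_boundaries(self, d, kept):
        j, g = _junction(seed=6)
        assert filter_bp_distance(lariat(j, bp_to_3ss=d), ctx_for(g)) is kept


class TestSelfPrimed:
    def _genome_with_5mers(self, bp_mer, up_mer):
        # layout: [up_mer][donor GT...](intron)  bp at a known position
        rng = random.Random(7)
        body = random_dna(rng, 400)
        intron = "GT" + body + "AG"
        contig = up_mer + intron
        j, _ = make_junction(intron, intron_start=len(up_mer))
        g = GenomeSequence({"chrT": contig + "A" * 10})
        # choose a bp 100 nt into the intron, then overwrite its 5-mer
        bp = len(up_mer) + 100
        chars = list(g.contigs["chrT"])
        chars[bp - 4 : bp + 1] = list(bp_mer)
        return j, GenomeSequence({"chrT": "".join(chars)}), bp

    def test_exact_match_dropped(self):
        j, g, bp = self._genome_with_5mers("ACGTA", "ACGTA")
        assert not filter_self_primed(lariat(j, bp_pos=bp), ctx_for(g))

    def test_single_difference_kept(self):
        j, g, bp = self._genome_with_5mers("ACGTT", "ACGTA")
        assert filter_self_primed(lariat(j, bp_pos=bp), ctx_for(g))

    def test_contig_edge_kept_with_warning(self, caplog):
        j, g, bp = self._genome_with_5mers("ACGTA", "ACGTA")
        # junction whose donor sits at the very start of the contig
        intron = g.fetch("chrT", 5, 407, "+")
        j2, _ = make_junction(intron, intron_start=0)
        g2 = GenomeSequence({"chrT": intron + "A" * 10})
        with caplog.at_level("WARNING"):
            assert filter_self_primed(lariat(j2, bp_pos=100), ctx_for(g2))
        assert "5-mer unavailable" in caplog.text

    def test_simulated_artifacts_all_flagged(self, small_sim, small_result):
        artifact_ids = set(
            small_sim.truth.reads.query(
                "label == 'self_primed_artifact'"
            ).read_id
        )
        five_set, three_set = set(), set()
        ctx = ctx_for(small_sim.genome)
        flagged, clean_dropped = 0, 0
        n_artifact = 0
        for sup in small_result.supports:
            for r in sup.reads:
                keep = filter_self_primed(r, ctx)
                if r.read_id in artifact_ids:
                    n_artifact += 1
                    flagged += not keep
                elif not keep:
                    clean_dropped += 1
        assert n_artifact > 0
        assert flagged == n_artifact       # 100 % of artifacts removed
        assert clean_dropped == 0          # no collateral removal


class TestExonicBp:
    def _ctx(self, g, j, start=600, end=720):
        return ctx_for(g, exon_bounds={j.junction_id: (start, end)})

    @pytest.mark.parametrize(
        "bp,kept",
        [(600, False), (601, True), (718, True), (719, False), (500, False)],
    )
    def test_exon_body_boundaries(self, bp, kept):
        j, g = _junction(seed=8)
        ctx = self._ctx(g, j)
        assert filter_exonic_bp(lariat(j, bp_pos=bp), ctx) is kept

    def test_disabled_outside_distal_mode(self):
        j, g = _junction(seed=9)
        assert filter_exonic_bp(lariat(j, bp_pos=0), ctx_for(g))


class TestCascade:
    def test_monotone_survivor_counts(self, small_result):
        df = small_result.report.to_frame()
        for col in ("putative_junctions", "decoy_junctions",
                    "putative_weight", "decoy_weight"):
            vals = df[col].tolist()
            assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_disabling_a_filter_gives_superset(self, small_sim):
        from rslariat import PipelineConfig, run_intronic

        cfg = PipelineConfig(seed=7)
        full = run_intronic(
            small_sim.genome, small_sim.transcripts, small_sim.reads,
            small_sim.repeats, cfg,
        )
        relaxed = run_intronic(
            small_sim.genome, small_sim.transcripts, small_sim.reads,
            small_sim.repeats,
            cfg.model_copy(update={"disabled_filters": ["bp_distance"]}),
        )
        full_ids = {s.junction.junction_id for s in full.report.surviving}
        relaxed_ids = {s.junction.junction_id for s in relaxed.report.surviving}
        assert full_ids <= relaxed_ids

    def test_stage_order_does_not_change_final_set(self, small_sim, small_result):
        """All stages are pure predicates combined by intersection, so any
        permutation of the cascade yields the same surviving set."""
        from rslariat.genome import annotated_splice_sites
        from rslariat.pipeline import repeat_trees

        five_set, three_set = annotated_splice_sites(small_sim.transcripts)
        ctx = CascadeContext(
            genome=small_sim.genome,
            annotated_5ss=five_set,
            annotated_3ss=three_set,
            repeat_trees=repeat_trees(small_sim.repeats),
            n_putative_sites=max(1, len(small_result.putative)),
            n_decoy_sites=max(1, len(small_result.decoys)),
        )
        reference = None
        rng = random.Random(0)
        for _ in range(3):
            order = INTRONIC_ORDER[:]
            rng.shuffle(order)
            rep = run_cascade(small_result.supports, ctx, order)
            ids = {
                (s.junction.junction_id, tuple(r.read_id for r in s.reads))
                for s in rep.surviving
            }
            if reference is None:
                reference = ids
            assert ids == reference

    def test_distal_order_swaps_stages(self):
        assert "exonic_bp" in DISTAL_ORDER
        assert "proximity" not in DISTAL_ORDER and "repeats" not in DISTAL_ORDER

    def test_decoy_only_input_reports_nan_fdr(self):
        import math

        j, g = _junction(seed=10, five_class="decoy")
        sup = JunctionSupport(j, [lariat(j, bp_mismatch=True)])
        rep = run_cascade([sup], ctx_for(g, n_putative_sites=10,
                                         n_decoy_sites=10))
        assert rep.stages[0].n_putative == 0
        assert math.isnan(rep.stages[0].fdr)
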