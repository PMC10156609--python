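import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rslariat import (
    GenomeSequence,
    Intron,
    build_distal_junctions,
    build_junctions,
    find_putative_sites,
    generate_decoys,
    reverse_complement,
    scan_cryptic_3ss,
    scan_rs_motif,
)
from rslariat.genome import ExonRecord

from .helpers import random_dna, regex_motif_oracle


class TestMotifScan:
    @pytest.mark.parametrize(
        "seq,positions",
        [
            ("TTTTTCAGGT", [8]),      # Y5, gap 0, CAG, GT at 8
            ("AAAAACAGGT", []),       # no polypyrimidine tract
            ("TTTTTTTTAGGT", [10]),   # long run, TAG, GT at 10
            ("TTTTTNCAGGT", [9]),     # N allowed only in the spacer
            ("TTTTNCAGGT", []),       # N breaks the pyrimidine run
            ("TTTTTCAGGTAGGT", [8, 12]),  # overlapping matches both found
        ],
    )
    def test_examples(self, seq, positions):
        assert [p for p, _ in scan_rs_motif(seq)] == positions

    def test_motif_span_covers_run_through_gt(self):
        ((pos, (s, e)),) = scan_rs_motif("AATTTTTCCAGGTAA")
        assert pos == 11 and (s, e) == (2, 13)

    def test_agrees_with_regex_oracle_random(self):
        rng = random.Random(42)
        for _ in range(500):
            seq = random_dna(rng, 200, "ACGTN")
            assert [p for p, _ in scan_rs_motif(seq)] == regex_motif_oracle(seq)

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=80))
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_regex_oracle_hypothesis(self, seq):
        assert [p for p, _ in scan_rs_motif(seq)] == regex_motif_oracle(seq)

    def test_cryptic_scan_drops_gt_requirement(self):
        # YAG without GT: cryptic only
        assert scan_cryptic_3ss("TTTTTCAGAA") == [7]
        assert scan_rs_motif("TTTTTCAGAA") == []


def _intron_with_motif(rng, length=2000, site_local=900):
    seq = list(random_dna(rng, length))
    seq[0:2] = "GT"
    seq[-2:] = "AG"
    seq[site_local - 8 : site_local + 2] = list("TTTTTCAGGT")
    genome = GenomeSequence({"c": "".join(seq)})
    intron = Intron("c", 0, length, "+", "g")
    return intron, genome


class TestDecoys:
    def test_seeded_determinism(self):
        rng = random.Random(0)
        intron, genome = _intron_with_motif(rng)
        putative = find_putative_sites(intron, genome)
        a = generate_decoys(intron, genome, putative, rng_seed=7)
        b = generate_decoys(intron, genome, putative, rng_seed=7)
        assert [d.local for d in a] == [d.local for d in b]
        assert len(a) <= 5 * len(putative)

    def test_decoy_constraints_post_hoc(self):
        # decoy screening guarantees, re-checked by independent scanning
        rng = random.Random(1)
        for seed in range(5):
            intron, genome = _intron_with_motif(rng)
            seq = intron.sequence(genome)
            putative = find_putative_sites(intron, genome)
            cryptic = set(scan_cryptic_3ss(seq))
            exclusion = (
                cryptic | {s.local for s in putative} | {len(seq) - 1}
            )
            for d in generate_decoys(intron, genome, putative, rng_seed=seed):
                assert seq[d.local : d.local + 2] != "GT"
                assert all(abs(d.local - x) > 250 for x in exclusion)

    def test_decoy_near_annotated_3ss_removed(self):
        rng = random.Random(3)
        intron, genome = _intron_with_motif(rng)
        putative = find_putative_sites(intron, genome)
        for seed in range(10):
            for d in generate_decoys(intron, genome, putative, rng_seed=seed):
                assert (len(intron.sequence(genome)) - 1) - d.local > 250


class TestJunctions:
    @pytest.mark.parametrize("n_sites,expected", [(0, 1), (1, 3), (2, 6), (3, 10)])
    def test_pair_enumeration(self, n_sites, expected):
        # brute-force oracle: conventional + 2 per site + ordered site pairs
        rng = random.Random(5)
        intron, genome = _intron_with_motif(rng)
        sites = []
        from rslariat.sites import RSSite

        for i in range(n_sites):
            sites.append(RSSite(intron, 500 + 400 * i, "putative", None))
        got = build_junctions(intron, genome, sites)
        assert len(got) == expected

    def test_head_tail_verbatim_slices(self):
        rng = random.Random(6)
        intron, genome = _intron_with_motif(rng, length=300 + 4)
        seq = intron.sequence(genome)
        (j,) = build_junctions(intron, genome, [])
        assert j.junction_len == 304
        assert j.head_seq == seq[:20]
        assert j.tail_seq == seq[-250:]
        # head and tail are verbatim substrings of the junction sequence
        assert seq.startswith(j.head_seq) and seq.endswith(j.tail_seq)

    def test_short_junction_uses_full_tail(self):
        rng = random.Random(7)
        intron, genome = _intron_with_motif(rng, length=100, site_local=50)
        (j,) = build_junctions(intron, genome, [])
        assert len(j.tail_seq) == 100

    def test_sub_head_junctions_dropped(self):
        rng = random.Random(8)
        intron, genome = _intron_with_motif(rng, length=2000, site_local=900)
        from rslariat.sites import RSSite

        # site 10 nt into the intron: the donor->annotated junction survives,
        # the annotated->acceptor junction spans 10 nt and is dropped
        sites = [RSSite(intron, 10, "putative", None)]
        got = build_junctions(intron, genome, sites)
        assert {(j.five_local, j.three_local) for j in got} == {
            (0, 1999), (10, 1999),
        }

    def test_tail_offset_to_genomic_roundtrip_minus(self):
        rng = random.Random(9)
        length = 1000
        seq = list(random_dna(rng, length))
        seq[0:2] = "GT"
        seq[-2:] = "AG"
        t_order = "".join(seq)
        genome = GenomeSequence({"c": "A" * 7 + reverse_complement(t_order)})
        intron = Intron("c", 7, 7 + length, "-", "g")
        assert intron.sequence(genome) == t_order
        (j,) = build_junctions(intron, genome, [])
        for off in (0, 100, len(j.tail_seq) - 1):
            g = j.tail_offset_to_genomic(off)
            base = genome.fetch("c", g, g + 1, "-")
            assert base == j.tail_seq[off]


class TestDistalJunctions:
    def _setup(self, strand="+"):
        rng = random.Random(11)
        intron_t = list(random_dna(rng, 600))
        intron_t[0:2] = "GT"
        intron_t[-2:] = "AG"
        exon_t = random_dna(rng, 120)
        t_order = "".join(intron_t) + exon_t
        if strand == "+":
            genome = GenomeSequence({"c": t_order})
            intron = Intron("c", 0, 600, "+", "g")
            exon = ExonRecord("c", 600, 720, "+", "g", is_internal=True,
                              is_cassette=True)
        else:
            genome = GenomeSequence({"c": reverse_complement(t_order)})
            intron = Intron("c", 120, 720, "-", "g")
            exon = ExonRecord("c", 0, 120, "-", "g", is_internal=True,
                              is_cassette=True)
        return genome, intron, exon, t_order

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_one_junction_per_exonic_position(self, strand):
        genome, intron, exon, t_order = self._setup(strand)
        got = build_distal_junctions(exon, intron, genome)
        assert len(got) == 120
        # the last candidate spans intron + whole exon
        last = max(got, key=lambda j: j.three_local)
        assert last.junction_len == 720
        assert last.tail_seq == t_order[-250:]
        # all heads are the intron's annotated donor head
        assert {j.head_seq for j in got} == {t_order[:20]}

    def test_minus_strand_tail_roundtrip(self):
        genome, intron, exon, t_order = self._setup("-")
        got = build_distal_junctions(exon, intron, genome)
        j = max(got, key=lambda j: j.three_local)
        for off in (0, len(j.tail_seq) - 1):
            g = j.tail_offset_to_genomic(off)
            assert genome.fetch("c", g, g + 1, "-") == j.tail_seq[off]


class TestOnSimulation:
    def test_planted_sites_all_rediscovered(self, small_sim):
        from rslariat import constitutive_introns

        introns = {
            i.intron_id: i for i in constitutive_introns(small_sim.transcripts)
        }
        planted = (
            small_sim.truth.rs_sites
            + small_sim.truth.selfprimed_sites
            + small_sim.truth.duplicated_sites
            + small_sim.truth.repeat_trap_sites
        )
        assert planted
        for site in planted:
            intron = introns[site.intron_id]
            found = {
                s.pos for s in find_putative_sites(intron, small_sim.genome)
            }
            assert site.pos in found
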