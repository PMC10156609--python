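import pytest

from rslariat import (
    GenomeSequence,
    Intron,
    PipelineConfig,
    SimConfig,
    run_intronic,
    simulate,
)
from rslariat.simulate import scaled_config
from rslariat.sites import Junction


@pytest.fixture(scope="session")
def full_sim():
    """Default-condition simulation: 200 genes, 50 clean planted RS sites,
    artifact classes on."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def full_result(full_sim):
    return run_intronic(
        full_sim.genome,
        full_sim.transcripts,
        full_sim.reads,
        full_sim.repeats,
        PipelineConfig(seed=1),
    )


@pytest.fixture(scope="session")
def small_sim():
    return simulate(scaled_config(40, seed=7))


@pytest.fixture(scope="session")
def small_result(small_sim):
    return run_intronic(
        small_sim.genome,
        small_sim.transcripts,
        small_sim.reads,
        small_sim.repeats,
        PipelineConfig(seed=7),
    )


def make_junction(
    intron_seq: str,
    five_local: int = 0,
    three_local: int | None = None,
    strand: str = "+",
    contig: str = "chrT",
    intron_start: int = 0,
    five_class: str = "annotated",
    three_class: str = "annotated",
    head_len: int = 20,
    tail_len: int = 250,
) -> tuple[Junction, GenomeSequence]:
    """A single junction over a hand-given transcription-order intron
    sequence, together with a one-contig genome that contains it."""
    if three_local is None:
        three_local = len(intron_seq) - 1
    if strand == "+":
        contig_seq = "A" * intron_start + intron_seq + "A" * 10
        start = intron_start
    else:
        from rslariat import reverse_complement

        contig_seq = "A" * 10 + reverse_complement(intron_seq) + "A" * intron_start
        start = 10
    genome = GenomeSequence({contig: contig_seq})
    intron = Intron(contig, start, start + len(intron_seq), strand, "geneT")
    jseq = intron_seq[five_local : three_local + 1]
    return (
        Junction(
            gene_id="geneT",
            contig=contig,
            strand=strand,
            intron=intron,
            five_local=five_local,
            three_local=three_local,
            five_class=five_class,
            three_class=three_class,
            head_seq=jseq[:head_len],
            tail_seq=jseq[-tail_len:],
            ref_start=intron.start,
            ref_end=intron.end,
        ),
        genome,
    )
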