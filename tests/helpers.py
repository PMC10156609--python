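"""Independent oracles shared by unit and acceptance tests."""

import random
import re

# A site is the G of a GT immediately preceded by YAG, with a run of >=5
# consecutive pyrimidines ending 0-4 nt upstream of the YAG.  The oracle
# checks every GT position independently with anchored regexes, so it finds
# every overlapping match (a single greedy scan would not).
_YAGGT = re.compile(r"[CT]AGGT")
_RUN = re.compile(r"[CT]{5}[ACGTN]{0,4}\Z")


def regex_motif_oracle(seq: str) -> list[int]:
    """All RS-motif donor positions in *seq*, by brute-force regex."""
    out = []
    for p in range(3, len(seq) - 1):
        if not _YAGGT.fullmatch(seq, p - 3, p + 2):
            continue
        if _RUN.search(seq, 0, p - 3):
            out.append(p)
    return out


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def enumerate_informative(loop_len: int, read_len: int) -> float:
    """Brute-force informative-read probability: every loop position tested
    against the two mapping constraints."""
    bp = loop_len - 1
    n_ok = 0
    for p in range(loop_len):
        d = bp - p
        if d >= 20 and d + 1 <= read_len - 20:
            n_ok += 1
    return n_ok / loop_len


def single_head_reads(junctions, reads, head_len=20):
    """Read ids containing exactly one distinct junction-head sequence
    (an independent reimplementation of the head-ambiguity rule)."""
    heads = {j.head_seq for j in junctions}
    out = set()
    for r in reads:
        found = set()
        for i in range(len(r.seq) - head_len + 1):
            k = r.seq[i : i + head_len]
            if k in heads:
                found.add(k)
        if len(found) == 1:
            out.add(r.read_id)
    return out
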