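"""Decoy-based empirical FDR and the informative-read probability model.

Empirical FDR
-------------
Decoy sites are random intronic positions screened to lack splice-like
context; any lariat support they accrue estimates the false-hit rate of the
mapping procedure.  Because decoy filtering leaves fewer decoys than the
nominal five per putative site, the decoy hit count is normalised per decoy
site and scaled to the putative site count before dividing by the observed
putative hits:

    FDR = (decoy_hits / n_decoy_sites * n_putative_sites) / putative_hits

clipped to [0, 1]; undefined (NaN) when there are no putative hits.

Informative reads
-----------------
A lariat read is *informative* when both of its segments are long enough to
map: at least 20 nt of loop sequence upstream of the branchpoint, and at
least 20 nt of 5'ss sequence after the jump.  For a read of length n whose
start is uniform over the lariat loop (intron start through the branchpoint,
the branchpoint assumed 25 nt upstream of the 3'ss), the number of start
positions that satisfy both constraints is

    count = max(0, min(n - 40, loop_len - 20))

and the probability is count / loop_len.  The Monte-Carlo estimator samples
positions with replacement (1,000 by default) and must converge to this
closed form; the enumeration oracle in the test-suite, not the closed form,
is the source of truth.  Across intron lengths the probability decays
approximately as a power law y = a * x**b, fitted by least squares in
log-log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FdrEstimate:
    stage: str
    putative_hits: float
    decoy_hits: float
    n_putative_sites: int
    n_decoy_sites: int
    fdr: float  # in [0, 1], or NaN when undefined


def empirical_fdr(
    putative_hits: float,
    decoy_hits: float,
    n_putative_sites: int,
    n_decoy_sites: int,
    stage: str = "",
) -> FdrEstimate:
    """Per-site-normalised decoy FDR (see module docstring)."""
    if min(putative_hits, decoy_hits) < 0:
        raise ValueError("hit counts must be non-negative")
    if n_decoy_sites <= 0:
        raise ValueError("n_decoy_sites must be positive")
    if putative_hits == 0:
        fdr = math.nan
    else:
        expected_false = decoy_hits / n_decoy_sites * n_putative_sites
        fdr = min(1.0, max(0.0, expected_false / putative_hits))
    return FdrEstimate(
        stage, putative_hits, decoy_hits, n_putative_sites, n_decoy_sites, fdr
    )


MIN_REGION = 20  # minimum mappable segment on either side of the junction


def informative_probability_exact(loop_len: int, read_len: int) -> float:
    """Closed form for the informative-read probability (uniform read start
    over the loop, branchpoint at the loop's last base)."""
    if loop_len < 1:
        raise ValueError("loop_len must be >= 1")
    count = min(read_len - 2 * MIN_REGION, loop_len - MIN_REGION)
    count = max(0, min(count, loop_len))
    return count / loop_len


def informative_probability_mc(
    loop_len: int,
    read_len: int,
    n_samples: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate: sample *n_samples* read-start positions uniformly
    (with replacement) over the loop; a position is informative when the
    branchpoint lies at least 20 nt downstream of it and the read retains at
    least 20 nt beyond the branchpoint for the 5'ss segment."""
    if loop_len < 1:
        raise ValueError("loop_len must be >= 1")
    rng = np.random.default_rng(seed)
    # distance from sampled position to the branchpoint (loop's last base)
    d = loop_len - 1 - rng.integers(0, loop_len, size=n_samples)
    ok = (d >= MIN_REGION) & (d + 1 <= read_len - MIN_REGION)
    return float(ok.mean())


def fit_power_law(lengths, probabilities) -> tuple[float, float, int]:
    """Least-squares fit of ``y = a * x**b`` in log-log space.

    Pairs with non-positive x or y are excluded (their count is returned as
    part of the result: ``n_used``).  Requires at least 3 usable pairs.
    """
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(probabilities, dtype=float)
    keep = (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(
            f"need >= 3 positive (x, y) pairs to fit, got {x.size}"
        )
    b, log_a = np.polyfit(np.log(x), np.log(y), 1)
    return float(np.exp(log_a)), float(b), int(x.size)


BP_OFFSET = 25  # assumed median U2 branchpoint position upstream of the 3'ss


def intron_informative_probability(
    intron_len: int, read_len: int, bp_offset: int = BP_OFFSET
) -> float:
    """Informative probability for a real intron: the loop runs from the
    intron start to the branchpoint, assumed *bp_offset* nt upstream of the
    3'ss.  Introns too short to hold a loop get probability 0."""
    loop_len = intron_len - bp_offset
    if loop_len < 1:
        return 0.0
    return informative_probability_exact(loop_len, read_len)


def informative_probability_table(
    intron_lens,
    read_lens=(75, 100, 150),
    bp_offset: int = BP_OFFSET,
) -> pd.DataFrame:
    """Per-intron informative probabilities across a read-length grid."""
    rows = []
    for L in intron_lens:
        row = {"intron_len": L}
        for n in read_lens:
            row[f"p_read{n}"] = intron_informative_probability(L, n, bp_offset)
        rows.append(row)
    return pd.DataFrame(rows)


def weighted_length_distribution(
    intron_lens, read_len: int = 100, bp_offset: int = BP_OFFSET
) -> pd.DataFrame:
    """Weighted and unweighted intron log-length distributions.

    The unweighted distribution places equal mass on every intron; the
    weighted one re-weights each intron by its informative-read probability
    (weights normalised to sum to 1), emulating what a lariat-based survey of
    equal-expression introns would observe."""
    lens = np.asarray(list(intron_lens), dtype=float)
    if lens.size == 0:
        raise ValueError("no introns")
    probs = np.array(
        [intron_informative_probability(int(L), read_len, bp_offset) for L in lens]
    )
    unweighted = np.full(lens.size, 1.0 / lens.size)
    total = probs.sum()
    weighted = probs / total if total > 0 else np.zeros_like(probs)
    return pd.DataFrame(
        {
            "intron_len": lens,
            "log10_len": np.log10(lens),
            "prob_informative": probs,
            "weight_unweighted": unweighted,
            "weight_informative": weighted,
        }
    )
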