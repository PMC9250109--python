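"""Shared fixtures: study simulation and an independent alignment oracle."""

from functools import lru_cache

import pytest

from exaptscan import simulate
from exaptscan.records import SequenceRecord


@pytest.fixture(scope="session")
def study():
    """Default simulated study: 20 aged copies, 4 homologs, chimeric locus."""
    return simulate.simulate_study(seed=5)


@pytest.fixture(scope="session")
def te_with_source():
    te = simulate.generate_te_consensus(1000, 14, seed=1)
    return simulate.add_exon_source(te, seed=2)


@pytest.fixture(scope="session")
def candidate_and_homologs(study):
    ex4 = study.truth.chimeric.exon_intervals[3]
    candidate = SequenceRecord(
        "candidate", study.genome.sequence[ex4[0] : ex4[1]]
    )
    homologs = simulate.extract_homolog_fragments(study)
    return candidate, homologs


def brute_force_local(a: str, b: str, match: int, mismatch: int,
                      gap_open: int, gap_extend: int) -> int:
    """Exhaustive affine-gap local alignment score by state recursion.

    Independent of the production kernel: plain memoized recursion over
    (i, j, state) with states M (last column aligned), X (gap in a),
    Y (gap in b); the local score is the best M-state value over all
    (i, j), floored at zero.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if state == "M":
            if i == 0 or j == 0:
                return -1e18
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = max(0.0, best(i - 1, j - 1, "M"),
                       best(i - 1, j - 1, "X"), best(i - 1, j - 1, "Y"))
            return prev + s
        if state == "X":  # gap in a, consumes b[j-1]
            if j == 0:
                return -1e18
            return max(
                best(i, j - 1, "M") + gap_open + gap_extend,
                best(i, j - 1, "X") + gap_extend,
            )
        # state Y: gap in b, consumes a[i-1]
        if i == 0:
            return -1e18
        return max(
            best(i - 1, j, "M") + gap_open + gap_extend,
            best(i - 1, j, "Y") + gap_extend,
        )

    top = 0.0
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            top = max(top, best(i, j, "M"))
    return int(top)
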