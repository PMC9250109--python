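"""Homology-block segmentation and terminal-inverted-repeat detection.

``segment_blocks`` aligns a locus to a reference element, slides a
window along the alignment, thresholds windowed identity into high/low
states and reports the resulting runs as labeled blocks (A, B, C, ...)
with exact per-block identity — the procedure behind partitioning a
transposon-derived locus into alternating high/low-identity regions.

``find_tir`` reports the longest terminal inverted repeat within a
length range, allowing a bounded number of mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from exaptscan import _aligner
from exaptscan.records import SEGMENT_SCORING, ScoringScheme, revcomp


@dataclass
class HomologyBlock:
    label: str
    locus_interval: tuple[int, int]
    reference_interval: tuple[int, int]
    identity: float
    length: int  # locus bp covered
    low_identity: bool = False  # identity below the configured threshold


@dataclass
class TIRResult:
    length: int
    five_prime_interval: tuple[int, int]
    three_prime_interval: tuple[int, int]
    mismatches: int


def _column_annotation(ga: str, gb: str):
    """Per-column match flags plus cumulative locus/reference positions."""
    n = len(ga)
    match = np.zeros(n, dtype=bool)
    apos = np.zeros(n + 1, dtype=int)
    bpos = np.zeros(n + 1, dtype=int)
    for i in range(n):
        apos[i + 1] = apos[i] + (ga[i] != "-")
        bpos[i + 1] = bpos[i] + (gb[i] != "-")
        match[i] = ga[i] != "-" and gb[i] != "-" and ga[i] == gb[i]
    return match, apos, bpos


def _windowed_identity(match: np.ndarray, w: int) -> np.ndarray:
    """Centered rolling mean with shrinking windows at the edges."""
    n = len(match)
    cum = np.concatenate([[0.0], np.cumsum(match)])
    half = w // 2
    lo = np.maximum(0, np.arange(n) - half)
    hi = np.minimum(n, np.arange(n) + half + 1)
    return (cum[hi] - cum[lo]) / (hi - lo)


def _two_state_path(match: np.ndarray, p_low: float, p_high: float,
                    switch_penalty: float) -> np.ndarray:
    """Most probable high/low state path under Bernoulli emissions."""
    n = len(match)
    em = np.empty((n, 2))
    for s, p in enumerate((p_low, p_high)):
        em[:, s] = np.where(match, np.log(p), np.log(1 - p))
    score = em[0].copy()
    back = np.zeros((n, 2), dtype=np.int8)
    for i in range(1, n):
        for s in (0, 1):
            stay = score[s]
            move = score[1 - s] - switch_penalty
            if stay >= move:
                back[i, s] = s
                best = stay
            else:
                back[i, s] = 1 - s
                best = move
            em[i, s] += best
        score = em[i]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def segment_blocks(
    locus: str,
    reference: str,
    window: int = 30,
    min_block: int = 40,
    low_id_threshold: float = 0.65,
    merge_gap: int = 30,
    switch_penalty: float = 6.0,
    scoring: ScoringScheme = SEGMENT_SCORING,
) -> list[HomologyBlock]:
    """Partition a locus-vs-reference alignment into identity blocks.

    Windowed identity (step 1) seeds a two-level model: a 2-means split
    of the windowed values estimates the high- and low-identity match
    rates, and the most probable two-state path under Bernoulli column
    emissions with a state-switch penalty segments the alignment (the
    penalty suppresses excursions that a bare threshold would turn into
    spurious blocks).  ``low_id_threshold`` decides whether the two
    levels are genuinely distinct; runs shorter than ``min_block`` (or
    ``merge_gap``) are absorbed into their neighbors.  Per-block identity
    is recomputed exactly from the alignment columns, not from windows.
    Blocks are labeled alphabetically 5'->3' and never overlap.
    """
    if len(locus) < window:
        raise ValueError("locus shorter than the identity window")
    score, ai, bi, ga, gb = _aligner.local_align(locus, reference, scoring)
    match, apos, bpos = _column_annotation(ga, gb)
    n = len(match)
    if n == 0:
        return []
    wid = _windowed_identity(match.astype(float), min(window, n))

    # 2-means on windowed identity -> candidate low/high match rates
    lo_c, hi_c = float(wid.min()), float(wid.max())
    for _ in range(50):
        mid = (lo_c + hi_c) / 2
        high_mask = wid > mid
        if not high_mask.any() or high_mask.all():
            break
        new_lo = float(wid[~high_mask].mean())
        new_hi = float(wid[high_mask].mean())
        if abs(new_lo - lo_c) < 1e-9 and abs(new_hi - hi_c) < 1e-9:
            break
        lo_c, hi_c = new_lo, new_hi
    p_low = float(np.clip(lo_c, 0.02, 0.98))
    p_high = float(np.clip(hi_c, 0.02, 0.98))

    if p_high - p_low < 0.05:
        # homogeneous locus: one block
        state = np.ones(n, dtype=np.int8)
    else:
        state = _two_state_path(match, p_low, p_high, switch_penalty)

    # run-length encode, then absorb residual short runs
    runs: list[list] = []
    for i, s in enumerate(state):
        if runs and runs[-1][0] == s:
            runs[-1][2] = i + 1
        else:
            runs.append([int(s), i, i + 1])
    min_run = max(min_block, merge_gap)
    while len(runs) > 1:
        lengths = [r[2] - r[1] for r in runs]
        k = int(np.argmin(lengths))
        if lengths[k] >= min_run:
            break
        runs[k][0] = 1 - runs[k][0]
        merged: list[list] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged

    # merge adjacent runs whose exact identities are indistinguishable
    # (collapses spurious state splits in near-homogeneous stretches)
    def _exact_identity(c0: int, c1: int) -> float:
        nongap = sum(1 for i in range(c0, c1) if ga[i] != "-" and gb[i] != "-")
        return float(match[c0:c1].sum() / nongap) if nongap else 0.0

    min_contrast = 0.08
    merged_runs: list[list] = []
    for s, c0, c1 in runs:
        if merged_runs and abs(
            _exact_identity(merged_runs[-1][1], merged_runs[-1][2])
            - _exact_identity(c0, c1)
        ) < min_contrast:
            merged_runs[-1][2] = c1
        else:
            merged_runs.append([s, c0, c1])
    runs = merged_runs

    blocks = []
    for idx, (s, c0, c1) in enumerate(runs):
        cols = match[c0:c1]
        nongap = sum(
            1 for i in range(c0, c1) if ga[i] != "-" and gb[i] != "-"
        )
        ident = float(cols.sum() / nongap) if nongap else 0.0
        label = chr(ord("A") + idx) if idx < 26 else f"B{idx}"
        li = (ai[0] + int(apos[c0]), ai[0] + int(apos[c1]))
        ri = (bi[0] + int(bpos[c0]), bi[0] + int(bpos[c1]))
        blocks.append(
            HomologyBlock(
                label=label,
                locus_interval=li,
                reference_interval=ri,
                identity=ident,
                length=li[1] - li[0],
                low_identity=ident < low_id_threshold,
            )
        )
    return blocks


def total_span(blocks: list[HomologyBlock]) -> int:
    """Summed locus length of a block list."""
    return sum(b.length for b in blocks)


def find_tir(
    element: str,
    min_len: int = 10,
    max_len: int = 30,
    max_mismatch: int = 0,
) -> Optional[TIRResult]:
    """Longest terminal inverted repeat in [min_len, max_len].

    Returns the largest L such that the 5' prefix of length L equals the
    reverse complement of the 3' suffix of length L with at most
    ``max_mismatch`` mismatches, or None if no L qualifies.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    n = len(element)
    if n < 2 * min_len:
        raise ValueError("element shorter than twice min_len")
    hi = min(max_len, n // 2)
    for L in range(hi, min_len - 1, -1):
        prefix = element[:L]
        tail_rc = revcomp(element[n - L :])
        mm = sum(1 for x, y in zip(prefix, tail_rc) if x != y)
        if mm <= max_mismatch:
            return TIRResult(
                length=L,
                five_prime_interval=(0, L),
                three_prime_interval=(n - L, n),
                mismatches=mm,
            )
    return None


def blocks_to_tsv(blocks: list[HomologyBlock], path) -> None:
    lines = ["label\tlocus_start\tlocus_end\tref_start\tref_end\tlength\tidentity"]
    for b in blocks:
        lines.append(
            f"{b.label}\t{b.locus_interval[0]}\t{b.locus_interval[1]}"
            f"\t{b.reference_interval[0]}\t{b.reference_interval[1]}"
            f"\t{b.length}\t{b.identity:.4f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
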