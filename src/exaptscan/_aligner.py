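"""Affine-gap pairwise alignment kernels (numba-compiled).

Local (Smith-Waterman) and global (Needleman-Wunsch) dynamic programs
with affine gap costs: a gap of length k costs gap_open + k*gap_extend.
Sequences are int8 arrays (A=0 C=1 G=2 T=3, anything else 4); code 4
always scores as a mismatch.

Tracebacks are reconstructed by re-deriving each cell's provenance from
the stored score matrices, which keeps memory at three int32 matrices.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from exaptscan.records import ScoringScheme, encode

NEG = -(10**9)


@njit(cache=True)
def _fill_local(a, b, match, mismatch, go, ge):
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in a (move along b)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in b (move along a)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i, j - 1] + ge
            eo = H[i, j - 1] + go + ge
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] + ge
            fo = H[i - 1, j] + go + ge
            if fo > f:
                f = fo
            F[i, j] = f
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if h < 0:
                h = 0
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _trace_local(a, b, H, E, F, bi, bj, match, mismatch, go, ge):
    # returns list of ops walked back from (bi,bj): 0=diag 1=gap in a 2=gap in b
    ops = []
    i, j = bi, bj
    state = 0  # 0=H 1=E 2=F
    while i > 0 or j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                s = match
            else:
                s = mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                ops.append(0)
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops.append(1)
            if E[i, j] == E[i, j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = 0
        else:
            ops.append(2)
            if F[i, j] == F[i - 1, j] + ge:
                i -= 1
            else:
                i -= 1
                state = 0
    return ops, i, j


@njit(cache=True)
def _fill_global(a, b, match, mismatch, go, ge):
    m, n = len(a), len(b)
    H = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    for j in range(1, n + 1):
        E[0, j] = go + j * ge
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = go + i * ge
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i, j - 1] + ge
            eo = H[i, j - 1] + go + ge
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] + ge
            fo = H[i - 1, j] + go + ge
            if fo > f:
                f = fo
            F[i, j] = f
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _trace_global(a, b, H, E, F, match, mismatch, go, ge):
    ops = []
    i, j = len(a), len(b)
    # pick terminal state
    state = 0
    if E[i, j] == H[i, j]:
        state = 1
    elif F[i, j] == H[i, j]:
        state = 2
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0:
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    s = match
                else:
                    s = mismatch
                if H[i, j] == H[i - 1, j - 1] + s:
                    ops.append(0)
                    i -= 1
                    j -= 1
                    continue
            if H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops.append(1)
            if j > 1 and E[i, j] == E[i, j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = 0
        else:
            ops.append(2)
            if i > 1 and F[i, j] == F[i - 1, j] + ge:
                i -= 1
            else:
                i -= 1
                state = 0
    return ops


def _ops_to_strings(a: str, b: str, ops, ai: int, bj: int):
    """Expand traceback ops (reversed order) into gapped strings."""
    ga = []
    gb = []
    i, j = ai, bj
    for op in reversed(ops):
        if op == 0:
            ga.append(a[i])
            gb.append(b[j])
            i += 1
            j += 1
        elif op == 1:  # gap in a, consume b
            ga.append("-")
            gb.append(b[j])
            j += 1
        else:  # gap in b, consume a
            ga.append(a[i])
            gb.append("-")
            i += 1
    return "".join(ga), "".join(gb), i, j


def local_align(a: str, b: str, scoring: ScoringScheme):
    """Best local alignment of a vs b.

    Returns (score, (a_start, a_end), (b_start, b_end), gapped_a, gapped_b),
    intervals 0-based half-open on the input strings.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = encode(a), encode(b)
    H, E, F, best, bi, bj = _fill_local(
        ea, eb, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    ops, i0, j0 = _trace_local(
        ea, eb, H, E, F, bi, bj,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    ga, gb, i1, j1 = _ops_to_strings(a, b, ops, i0, j0)
    return int(best), (i0, i1), (j0, j1), ga, gb


def global_align(a: str, b: str, scoring: ScoringScheme):
    """Global alignment; returns (score, gapped_a, gapped_b)."""
    if not a and not b:
        return 0, "", ""
    if not a:
        return (
            scoring.gap_open + len(b) * scoring.gap_extend,
            "-" * len(b),
            b,
        )
    if not b:
        return (
            scoring.gap_open + len(a) * scoring.gap_extend,
            a,
            "-" * len(a),
        )
    ea, eb = encode(a), encode(b)
    H, E, F = _fill_global(
        ea, eb, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    ops = _trace_global(
        ea, eb, H, E, F,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    ga, gb, _, _ = _ops_to_strings(a, b, ops, 0, 0)
    score = int(H[len(a), len(b)])
    return score, ga, gb
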