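"""Consensus-to-genome homology search and copy census.

A seed-and-extend scan: exact k-mer seed matches nominate candidate
windows, each window is realigned with the affine-gap Smith-Waterman
kernel, and retained hits carry percent identity and query coverage.
The census applies the identity/coverage thresholds and then removes
duplicate fragments whose start positions fall within a fixed window of
a better-scoring kept hit — the scheme used to count transposase-like,
exon-like and exon-CDS-like copies at 10 kb / 1 kb / 150 bp windows.

An E-value cutoff is not reproducible without database-wide statistics,
so retention is governed by a raw-score minimum instead (default 60
under match=2, mismatch=-3, gap open -5, extend -2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from exaptscan import _aligner
from exaptscan.records import ScoringScheme, SequenceRecord, revcomp
from exaptscan.simulate import TEConsensus

DEFAULT_SCORING = ScoringScheme(match=2, mismatch=-3, gap_open=-5, gap_extend=-2)
DEFAULT_MIN_SCORE = 60
SEED_K = 11


@dataclass
class HomologyHit:
    """One local-alignment match of a consensus to a genomic interval."""

    query_name: str
    target_contig: str
    target_interval: tuple[int, int]  # 0-based half-open on the + strand
    strand: str
    score: int
    identity: float          # matching fraction of aligned non-gap columns
    identity_with_gaps: float  # same numerator over all aligned columns
    query_coverage: float    # aligned query fraction
    alignment: tuple[str, str] = field(default=("", ""), repr=False)

    @property
    def start(self) -> int:
        return self.target_interval[0]

    @property
    def end(self) -> int:
        return self.target_interval[1]


def alignment_identity(ga: str, gb: str) -> tuple[float, float, int]:
    """(identity over non-gap columns, identity over all columns, n columns)."""
    if len(ga) != len(gb):
        raise ValueError("gapped strings differ in length")
    matches = 0
    nongap = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            nongap += 1
            if x == y:
                matches += 1
    ident = matches / nongap if nongap else 0.0
    ident_all = matches / len(ga) if ga else 0.0
    return ident, ident_all, len(ga)


def smith_waterman(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING):
    """Best local alignment under affine gaps.

    Returns (score, a_interval, b_interval, gapped_a, gapped_b); N (or any
    non-ACGT symbol) scores as a mismatch.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return _aligner.local_align(a, b, scoring)


def _seed_windows(query: str, target: str, k: int, pad: int) -> list[tuple[int, int]]:
    """Candidate target windows from exact k-mer seed matches."""
    if len(query) < k or len(target) < k:
        return [(0, len(target))] if target else []
    index = {}
    for i in range(len(query) - k + 1):
        index.setdefault(query[i : i + k], []).append(i)
    positions = []
    for j in range(len(target) - k + 1):
        qs = index.get(target[j : j + k])
        if qs:
            positions.append(j)
    if not positions:
        return []
    windows = []
    start = positions[0]
    prev = positions[0]
    for p in positions[1:]:
        if p - prev > len(query):
            windows.append((start, prev + k))
            start = p
        prev = p
    windows.append((start, prev + k))
    return [
        (max(0, s - pad), min(len(target), e + pad))
        for s, e in windows
    ]


def scan_genome(
    genome: SequenceRecord | Iterable[SequenceRecord],
    consensus_library: Iterable[TEConsensus | SequenceRecord],
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_score: int = DEFAULT_MIN_SCORE,
    both_strands: bool = True,
    seed_k: int = SEED_K,
) -> list[HomologyHit]:
    """Find consensus-derived fragments on one or more contigs.

    Hits are sorted by contig then start; every hit's interval, when
    extracted and realigned against its query, reproduces the score.
    """
    contigs = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    library = list(consensus_library)
    if not library:
        raise ValueError("consensus library is empty")
    hits: list[HomologyHit] = []
    for contig in contigs:
        tseq = contig.sequence
        for cons in library:
            qname = cons.name
            for strand in ("+", "-") if both_strands else ("+",):
                qseq = cons.sequence if strand == "+" else revcomp(cons.sequence)
                pad = len(qseq) // 2 + 50
                stack = list(_seed_windows(qseq, tseq, seed_k, pad))
                while stack:
                    ws, we = stack.pop()
                    if we - ws < seed_k:
                        continue
                    window = tseq[ws:we]
                    score, qi, ti, ga, gb = _aligner.local_align(qseq, window, scoring)
                    if score < min_score:
                        continue
                    # a window may hold several copies: recurse on the flanks
                    if ti[0] > 0:
                        stack.append((ws, ws + ti[0]))
                    if ws + ti[1] < we:
                        stack.append((ws + ti[1], we))
                    ident, ident_all, _ = alignment_identity(ga, gb)
                    cov = (qi[1] - qi[0]) / len(qseq)
                    hits.append(
                        HomologyHit(
                            query_name=qname,
                            target_contig=contig.name,
                            target_interval=(ws + ti[0], ws + ti[1]),
                            strand=strand,
                            score=score,
                            identity=ident,
                            identity_with_gaps=ident_all,
                            query_coverage=cov,
                            alignment=(ga, gb),
                        )
                    )
    # seed windows can overlap; keep the best hit per (query, strand, locus)
    hits.sort(key=lambda h: (h.target_contig, h.start, -h.score))
    dedup: list[HomologyHit] = []
    for h in hits:
        if dedup:
            last = dedup[-1]
            if (
                last.target_contig == h.target_contig
                and last.query_name == h.query_name
                and last.strand == h.strand
                and h.start < last.end
            ):
                if h.score > last.score:
                    dedup[-1] = h
                continue
        dedup.append(h)
    dedup.sort(key=lambda h: (h.target_contig, h.start))
    return dedup


def census(
    hits: Iterable[HomologyHit],
    min_identity: float = 0.65,
    min_coverage: float = 0.60,
    dedup_window: int = 150,
) -> tuple[int, list[HomologyHit]]:
    """Copy count under identity/coverage thresholds and start-window dedup.

    Thresholds are exclusive bounds (identity > min_identity, coverage >
    min_coverage).  After filtering, hits are taken best-score-first and
    any other hit whose start lies within ``dedup_window`` bp of a kept
    hit's start on the same contig is discarded.  Idempotent.
    """
    if not 0 <= min_identity <= 1 or not 0 <= min_coverage <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    if dedup_window < 0:
        raise ValueError("dedup_window must be >= 0")
    kept: list[HomologyHit] = []
    pool = [
        h for h in hits
        if h.identity > min_identity and h.query_coverage > min_coverage
    ]
    # best score first; ties to the leftmost start
    pool.sort(key=lambda h: (-h.score, h.target_contig, h.start))
    for h in pool:
        clash = any(
            k.target_contig == h.target_contig
            and abs(k.start - h.start) <= dedup_window
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.target_contig, h.start))
    return len(kept), kept


def hits_to_tsv(hits: Iterable[HomologyHit], path) -> None:
    cols = "query\tcontig\tstart\tend\tstrand\tscore\tidentity\tcoverage"
    lines = [cols]
    for h in hits:
        lines.append(
            f"{h.query_name}\t{h.target_contig}\t{h.start}\t{h.end}\t{h.strand}"
            f"\t{h.score}\t{h.identity:.4f}\t{h.query_coverage:.4f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def hits_to_bed(hits: Iterable[HomologyHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.target_contig}\t{h.start}\t{h.end}\t{h.query_name}"
                f"\t{h.score}\t{h.strand}\n"
            )
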