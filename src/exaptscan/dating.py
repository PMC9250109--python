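"""Consensus building, corrected distances, repeat landscapes, insertion age.

Transposon copies decay independently from the ancestral (consensus-like)
state, so divergence-to-consensus converts directly to an insertion age
T = d / r without a factor of two, where r is the per-site yearly neutral
substitution rate.  Distances use pairwise gap deletion; Jukes-Cantor
corrects the p-distance assuming equal exchange rates, and the Kimura
two-parameter correction separates transitions from transversions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from exaptscan import _aligner
from exaptscan.records import BASES, SequenceRecord, ScoringScheme

#: per-site yearly substitution rates bracketing the lineage estimate
RATE_LOW = 3.0e-9
RATE_HIGH = 3.2e-9

_ALIGN_SCORING = ScoringScheme(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class UndefinedDistanceError(ValueError):
    """Raised when a distance is saturated or has no comparable sites."""


@dataclass
class MultipleAlignment:
    """Equal-length gapped sequences; '-' is the only gap character."""

    members: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.members:
            L = len(self.members[0][1])
            if any(len(s) != L for _, s in self.members):
                raise ValueError("gapped sequences differ in length")

    @property
    def length(self) -> int:
        return len(self.members[0][1]) if self.members else 0

    def names(self) -> list[str]:
        return [n for n, _ in self.members]

    def sequences(self) -> list[str]:
        return [s for _, s in self.members]


@dataclass
class DivergenceRecord:
    copy_name: str
    p: float
    d: float
    model: str = "JC"
    sites_compared: int = 0
    family: str = "TE"


@dataclass
class Landscape:
    bin_width: float
    families: list[str]
    #: list of (bin_low, bin_high, {family: genome_fraction})
    bins: list[tuple[float, float, dict]]
    n_saturated: int = 0

    def family_total(self, family: str) -> float:
        return sum(b[2].get(family, 0.0) for b in self.bins)


@dataclass
class AgeEstimate:
    d_median: float
    rate_low: float
    rate_high: float
    age_low_Ma: float
    age_high_Ma: float


# ---------------------------------------------------------------------------


def majority_consensus(msa: MultipleAlignment) -> SequenceRecord:
    """Per-column most frequent base; alphabetic tie-break.

    Columns where gaps hold a strict majority are omitted.
    """
    if len(msa.members) < 2:
        raise ValueError("need at least two aligned members")
    seqs = msa.sequences()
    n = len(seqs)
    out = []
    for col in zip(*seqs):
        gaps = sum(1 for c in col if c == "-")
        if 2 * gaps > n:
            continue
        counts = {b: 0 for b in BASES}
        for c in col:
            if c in counts:
                counts[c] += 1
        # max count, ties broken alphabetically by iteration order of BASES
        best = max(BASES, key=lambda b: counts[b])
        out.append(best)
    return SequenceRecord("consensus", "".join(out))


def p_distance(a_gapped: str, b_gapped: str) -> tuple[float, int]:
    """Proportion of differing sites under pairwise gap deletion."""
    if len(a_gapped) != len(b_gapped):
        raise ValueError("gapped sequences differ in length")
    sites = 0
    diffs = 0
    for x, y in zip(a_gapped, b_gapped):
        if x == "-" or y == "-":
            continue
        sites += 1
        if x != y:
            diffs += 1
    if sites == 0:
        raise UndefinedDistanceError("no comparable sites")
    return diffs / sites, sites


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3); defined for p < 0.75."""
    if p < 0:
        raise ValueError("p must be non-negative")
    if p >= 0.75:
        raise UndefinedDistanceError("p-distance saturated (p >= 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def k2p_distance(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition (P) and transversion (Q) fractions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise UndefinedDistanceError("K2P distance undefined for these fractions")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def ts_tv_fractions(a_gapped: str, b_gapped: str) -> tuple[float, float, int]:
    """Transition and transversion fractions under pairwise gap deletion."""
    if len(a_gapped) != len(b_gapped):
        raise ValueError("gapped sequences differ in length")
    sites = ts = tv = 0
    for x, y in zip(a_gapped, b_gapped):
        if x == "-" or y == "-" or x not in BASES or y not in BASES:
            continue
        sites += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if sites == 0:
        raise UndefinedDistanceError("no comparable sites")
    return ts / sites, tv / sites, sites


def divergence_to_consensus(
    copies: Iterable[SequenceRecord],
    consensus: SequenceRecord,
    model: str = "JC",
    family: str = "TE",
) -> tuple[list[DivergenceRecord], int]:
    """Per-copy corrected distance to the consensus (pairwise alignment).

    Saturated copies are excluded from the returned records and counted.
    """
    records = []
    n_saturated = 0
    for copy in copies:
        _, ga, gb = _aligner.global_align(copy.sequence, consensus.sequence, _ALIGN_SCORING)
        try:
            if model == "JC":
                p, sites = p_distance(ga, gb)
                d = jc_distance(p)
            elif model == "K2P":
                P, Q, sites = ts_tv_fractions(ga, gb)
                p = P + Q
                d = k2p_distance(P, Q)
            else:
                raise ValueError(f"unknown model {model!r}")
        except UndefinedDistanceError:
            n_saturated += 1
            continue
        records.append(
            DivergenceRecord(copy.name, p=p, d=d, model=model,
                             sites_compared=sites, family=family)
        )
    return records, n_saturated


def landscape(
    records: Sequence[DivergenceRecord],
    copy_lengths: Sequence[int],
    genome_size: int,
    bin_width: float = 0.01,
) -> Landscape:
    """Genome-fraction histogram of copies binned by corrected divergence."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(records) != len(copy_lengths):
        raise ValueError("records and copy_lengths differ in length")
    families = sorted({r.family for r in records})
    if not records:
        return Landscape(bin_width=bin_width, families=[], bins=[])
    n_bins = int(max(r.d for r in records) // bin_width) + 1
    bins = [
        (i * bin_width, (i + 1) * bin_width, {f: 0.0 for f in families})
        for i in range(n_bins)
    ]
    for rec, length in zip(records, copy_lengths):
        i = min(int(rec.d // bin_width), n_bins - 1)
        bins[i][2][rec.family] += length / genome_size
    return Landscape(bin_width=bin_width, families=families, bins=bins)


def estimate_age(
    d_median: float,
    rate_low: float = RATE_LOW,
    rate_high: float = RATE_HIGH,
) -> AgeEstimate:
    """Insertion-age interval T = d/r in Ma from a median divergence."""
    if rate_low <= 0 or rate_high <= 0:
        raise ValueError("rates must be positive")
    if rate_low > rate_high:
        raise ValueError("rate_low must not exceed rate_high")
    if d_median < 0:
        raise ValueError("median divergence must be non-negative")
    return AgeEstimate(
        d_median=d_median,
        rate_low=rate_low,
        rate_high=rate_high,
        age_low_Ma=d_median / rate_high / 1e6,
        age_high_Ma=d_median / rate_low / 1e6,
    )


def median_divergence(records: Sequence[DivergenceRecord],
                      weights: Optional[Sequence[float]] = None) -> float:
    """Median corrected distance (unweighted by default; lengths optional)."""
    if not records:
        raise ValueError("no divergence records")
    d = np.array([r.d for r in records])
    if weights is None:
        return float(np.median(d))
    order = np.argsort(d)
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w) / w.sum()
    return float(d[order][np.searchsorted(cum, 0.5)])


# ---------------------------------------------------------------------------
# small-set multiple alignment (center-star)


def _merge_into_master(master: str, rows: list[str], cg: str, sg: str):
    """Merge a (center, other) pairwise alignment into the running MSA.

    ``master`` is the center sequence as currently gapped in the MSA; both
    master and cg contain the center residues in order ("once a gap,
    always a gap").
    """
    i = j = 0
    new_master = []
    new_rows = [[] for _ in rows]
    new_s = []
    while i < len(master) or j < len(cg):
        mi = master[i] if i < len(master) else None
        cj = cg[j] if j < len(cg) else None
        if mi is not None and cj is not None and mi != "-" and cj != "-":
            new_master.append(mi)
            for r, row in zip(new_rows, rows):
                r.append(row[i])
            new_s.append(sg[j])
            i += 1
            j += 1
        elif mi == "-" and cj == "-":
            new_master.append("-")
            for r, row in zip(new_rows, rows):
                r.append(row[i])
            new_s.append(sg[j])
            i += 1
            j += 1
        elif mi == "-":
            new_master.append("-")
            for r, row in zip(new_rows, rows):
                r.append(row[i])
            new_s.append("-")
            i += 1
        else:  # cj == "-" (insertion in the new sequence) or master exhausted
            new_master.append("-")
            for r in new_rows:
                r.append("-")
            new_s.append(sg[j])
            j += 1
    return (
        "".join(new_master),
        ["".join(r) for r in new_rows],
        "".join(new_s),
    )


def center_star_align(
    seqs: Sequence[str] | Sequence[SequenceRecord],
    names: Optional[Sequence[str]] = None,
) -> MultipleAlignment:
    """Progressive star alignment around the best-scoring center.

    Intended for small sets (2-50 sequences); larger sets should come in
    pre-aligned.  Degapping any member recovers its input exactly.
    """
    if seqs and hasattr(seqs[0], "sequence"):
        if names is None:
            names = [s.name for s in seqs]
        seqs = [s.sequence for s in seqs]
    seqs = list(seqs)
    if names is None:
        names = [f"seq{i}" for i in range(len(seqs))]
    if not 2 <= len(seqs) <= 50:
        raise ValueError(
            "center-star alignment accepts 2-50 sequences; align larger "
            "sets externally and load the aligned FASTA"
        )
    k = len(seqs)
    scores = np.zeros((k, k))
    pair = {}
    for i in range(k):
        for j in range(i + 1, k):
            s, ga, gb = _aligner.global_align(seqs[i], seqs[j], _ALIGN_SCORING)
            scores[i, j] = scores[j, i] = s
            pair[(i, j)] = (ga, gb)
    center = int(np.argmax(scores.sum(axis=1)))
    master = seqs[center]
    rows: list[str] = []
    order: list[int] = []
    for idx in range(k):
        if idx == center:
            continue
        if (center, idx) in pair:
            cg, sg = pair[(center, idx)]
        else:
            gb, ga = pair[(idx, center)]
            cg, sg = ga, gb
        master, rows, aligned = _merge_into_master(master, rows, cg, sg)
        rows.append(aligned)
        order.append(idx)
    members = [(names[center], master)]
    members += [(names[i], row) for i, row in zip(order, rows)]
    # restore input order
    want = {n: i for i, n in enumerate(names)}
    members.sort(key=lambda m: want[m[0]])
    return MultipleAlignment(members=members)


def landscape_to_tsv(ls: Landscape, path) -> None:
    lines = ["bin_low\tbin_high\tfamily\tfraction"]
    for lo, hi, fr in ls.bins:
        for fam in ls.families:
            lines.append(f"{lo:.4f}\t{hi:.4f}\t{fam}\t{fr.get(fam, 0.0):.6g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def plot_landscape(ls: Landscape, path) -> None:
    """Stacked-bar divergence histogram (genome fraction per family)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    lows = [b[0] for b in ls.bins]
    bottom = np.zeros(len(ls.bins))
    for fam in ls.families:
        vals = np.array([b[2].get(fam, 0.0) for b in ls.bins]) * 100
        ax.bar(lows, vals, width=ls.bin_width * 0.9, bottom=bottom,
               align="edge", label=fam)
        bottom += vals
    ax.set_xlabel("corrected divergence to consensus")
    ax.set_ylabel("% of genome")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
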