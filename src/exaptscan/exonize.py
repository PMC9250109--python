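"""Reconstruction of how a non-coding transposon region became coding.

Given a candidate exon (read in the frame continuing from the upstream
exon, not from an ATG — the encoded peptide is a C-terminal continuation)
and a set of transposon-derived homologs that retain the ancestral
state, the module:

* locates the exon ORF up to and including its first in-frame stop;
* calls ancestral->derived mutation events wherever the candidate
  differs from the strict majority of homologs, collapsing gap runs into
  single indels; ties among homologs are unpolarizable and excluded;
* classifies coding effects (frameshift removal/introduction, stop gain,
  premature stop, silent/missense); and
* searches for the minimal event subset that jointly opens the observed
  reading frame.

Frameshift direction is classified against a reference frame defined as
the indel subset maximizing the achievable peptide: indels in that
subset restore the reference coding frame (frameshift_remove), indels
outside it break it (frameshift_introduce).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from exaptscan.dating import center_star_align
from exaptscan.records import SequenceRecord

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class MutationEvent:
    """A typed ancestral->derived difference from a pairwise alignment."""

    position: int            # alignment column of the event start
    kind: str                # deletion | insertion | substitution
    ancestral: str
    derived: str
    anc_pos: int             # 0-based position in the ungapped ancestral
    der_pos: int             # 0-based position in the ungapped candidate
    effect: Optional[str] = None
    polarized: bool = True

    @property
    def indel_length(self) -> int:
        if self.kind == "deletion":
            return len(self.ancestral)
        if self.kind == "insertion":
            return len(self.derived)
        return 0

    @property
    def is_frameshift(self) -> bool:
        return self.kind != "substitution" and self.indel_length % 3 != 0


@dataclass
class CDSResult:
    cds_interval: tuple[int, int]  # within the exon, includes the stop codon
    peptide: str
    stop_codon: str

    @property
    def peptide_length(self) -> int:
        return len(self.peptide)


@dataclass
class ExonizationReport:
    name: str
    frame_offset: int
    cds_interval: Optional[tuple[int, int]]
    peptide_length: Optional[int]
    stop_codon: Optional[str]
    events: list[MutationEvent]
    minimal_set: list[MutationEvent]
    homolog_names: list[str]
    no_signal: bool = False
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------


def exon_cds(exon_seq: str, frame_offset: int = 0) -> Optional[CDSResult]:
    """Read codons from ``frame_offset`` up to the first in-frame stop.

    Returns the CDS interval (stop included), the peptide and the stop
    codon, or None when no in-frame stop exists (a non-coding read-through,
    the ancestral condition).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    if any(c not in "ACGT" for c in exon_seq):
        raise ValueError("exon sequence must contain only A, C, G, T")
    for i in range(frame_offset, len(exon_seq) - 2, 3):
        codon = exon_seq[i : i + 3]
        if codon in _STOPS:
            peptide = str(Seq(exon_seq[frame_offset:i]).translate())
            return CDSResult(
                cds_interval=(frame_offset, i + 3),
                peptide=peptide,
                stop_codon=codon,
            )
    return None


def diff_events(anc_gapped: str, der_gapped: str) -> list[MutationEvent]:
    """Typed differences between two rows of one alignment.

    Maximal gap runs collapse into single indel events; substitutions are
    one event per column.  Positions project onto both ungapped sequences.
    """
    if len(anc_gapped) != len(der_gapped):
        raise ValueError("gapped sequences differ in length")
    events: list[MutationEvent] = []
    ap = dp = 0
    i = 0
    n = len(anc_gapped)
    while i < n:
        a, d = anc_gapped[i], der_gapped[i]
        if a != "-" and d == "-":  # deletion run
            j = i
            run = []
            a0 = ap
            while j < n and anc_gapped[j] != "-" and der_gapped[j] == "-":
                run.append(anc_gapped[j])
                ap += 1
                j += 1
            events.append(
                MutationEvent(i, "deletion", "".join(run), "", a0, dp)
            )
            i = j
        elif a == "-" and d != "-":  # insertion run
            j = i
            run = []
            d0 = dp
            while j < n and anc_gapped[j] == "-" and der_gapped[j] != "-":
                run.append(der_gapped[j])
                dp += 1
                j += 1
            events.append(
                MutationEvent(i, "insertion", "", "".join(run), ap, d0)
            )
            i = j
        else:
            if a != "-" and d != "-" and a != d:
                events.append(MutationEvent(i, "substitution", a, d, ap, dp))
            ap += a != "-"
            dp += d != "-"
            i += 1
    return events


def apply_events(ancestral: str, events: Iterable[MutationEvent]) -> str:
    """Apply ancestral->derived events to an ungapped ancestral sequence."""
    seq = ancestral
    ordered = sorted(
        events, key=lambda e: (-e.anc_pos, 0 if e.kind != "insertion" else 1)
    )
    for e in ordered:
        p = e.anc_pos
        if e.kind == "deletion":
            seq = seq[:p] + seq[p + len(e.ancestral):]
        elif e.kind == "insertion":
            seq = seq[:p] + e.derived + seq[p:]
        else:
            seq = seq[:p] + e.derived + seq[p + len(e.ancestral):]
    return seq


def _shift(e: MutationEvent) -> int:
    """Derived-length change of an event."""
    return len(e.derived) - len(e.ancestral)


def _reference_indel_set(
    ancestral: str,
    events: Sequence[MutationEvent],
    frame_offset: int,
) -> list[int]:
    """Indices of the indel subset maximizing the achievable peptide.

    This subset defines the reference coding frame used to orient
    frameshift effects.
    """
    subs = [e for e in events if e.kind == "substitution"]
    indel_idx = [i for i, e in enumerate(events) if e.kind != "substitution"]
    best: tuple[int, int, tuple] = (-1, 10**9, ())
    for r in range(len(indel_idx) + 1):
        for combo in itertools.combinations(indel_idx, r):
            chosen = [events[i] for i in combo] + subs
            try:
                orf = exon_cds(apply_events(ancestral, chosen), frame_offset)
            except ValueError:
                orf = None
            if orf is None:
                continue
            key = (orf.peptide_length, len(combo), combo)
            if key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
                best = key
    return list(best[2])


def classify_effects(
    events: Sequence[MutationEvent],
    ancestral: str,
    frame_offset: int = 0,
    reference_indels: Optional[Sequence[int]] = None,
) -> list[MutationEvent]:
    """Annotate events with coding effects (in place; returns the list).

    Indels with length not a multiple of three are frameshifts, oriented
    against the reference frame (see module docstring).  Substitutions
    creating an in-frame stop on the reference sequence are stop gains;
    a stop-creating substitution upstream of the terminal one is a
    premature stop.
    """
    events = list(events)
    if reference_indels is None:
        reference_indels = _reference_indel_set(ancestral, events, frame_offset)
    ref_set = set(reference_indels)

    for i, e in enumerate(events):
        if e.kind != "substitution":
            if e.indel_length % 3 == 0:
                e.effect = "inframe_indel"
            elif i in ref_set:
                e.effect = "frameshift_remove"
            else:
                e.effect = "frameshift_introduce"

    # evaluate substitutions on the reference-frame sequence
    ref_events = [events[i] for i in ref_set] + [
        e for e in events if e.kind == "substitution"
    ]
    ref_seq = apply_events(ancestral, ref_events)
    stop_makers: list[tuple[int, MutationEvent]] = []
    for e in events:
        if e.kind != "substitution":
            continue
        shift = sum(
            _shift(events[i]) for i in ref_set if events[i].anc_pos <= e.anc_pos
        )
        rp = e.anc_pos + shift
        cs = rp - ((rp - frame_offset) % 3)
        if cs < 0 or cs + 3 > len(ref_seq):
            e.effect = "silent"
            continue
        der_codon = ref_seq[cs : cs + 3]
        off = rp - cs
        anc_codon = der_codon[:off] + e.ancestral + der_codon[off + 1:]
        if der_codon in _STOPS and anc_codon not in _STOPS:
            stop_makers.append((cs, e))
        elif anc_codon in _STOPS and der_codon not in _STOPS:
            e.effect = "stop_loss"
        else:
            try:
                same = str(Seq(der_codon).translate()) == str(Seq(anc_codon).translate())
            except Exception:
                same = False
            e.effect = "silent" if same else "missense"
    if stop_makers:
        stop_makers.sort(key=lambda t: t[0])
        for _, e in stop_makers[:-1]:
            e.effect = "premature_stop"
        stop_makers[-1][1].effect = "stop_gain"
    return events


def reconstruct_path(
    candidate: SequenceRecord | str,
    homologs: Sequence[SequenceRecord],
    frame_offset: int = 0,
    max_exhaustive: int = 6,
) -> ExonizationReport:
    """Call events against homolog majority and find the minimal ORF-opening set.

    Events where the candidate differs from the strict majority of
    homologs are polarized ancestral->derived changes; columns where no
    strict homolog majority exists are reported unpolarized and excluded
    from the minimal set.  The minimal set is the smallest event subset
    whose application to the ancestral reconstruction reproduces the
    candidate's peptide length (exhaustive to ``max_exhaustive`` events).
    """
    if isinstance(candidate, str):
        candidate = SequenceRecord("candidate", candidate)
    homologs = list(homologs)
    if not homologs:
        raise ValueError("need at least one homolog")
    warnings: list[str] = []
    if len(homologs) < 2:
        warnings.append(
            "single homolog: events cannot be polarized by majority"
        )

    msa = center_star_align([candidate] + homologs)
    rows = dict(msa.members)
    cand_g = rows[candidate.name]
    hom_g = [rows[h.name] for h in homologs]
    n_hom = len(hom_g)

    anc_cols: list[str] = []
    unpolarized_cols: list[int] = []
    for col in range(msa.length):
        chars = [g[col] for g in hom_g]
        counts: dict[str, int] = {}
        for c in chars:
            counts[c] = counts.get(c, 0) + 1
        top = max(counts.values())
        winners = [c for c, k in counts.items() if k == top]
        if len(winners) == 1 and 2 * top > n_hom:
            anc_cols.append(winners[0])
        else:
            anc_cols.append(cand_g[col])  # no call: treat as candidate state
            if cand_g[col] not in winners:
                unpolarized_cols.append(col)
    anc_gapped = "".join(anc_cols)
    ancestral = anc_gapped.replace("-", "")

    events = diff_events(anc_gapped, cand_g)
    unpolarized = []
    for col in unpolarized_cols:
        unpolarized.append(
            MutationEvent(
                col, "substitution", "?", cand_g[col], -1, -1,
                effect=None, polarized=False,
            )
        )
    classify_effects(events, ancestral, frame_offset)

    orf = exon_cds(candidate.sequence, frame_offset)
    minimal: list[MutationEvent] = []
    no_signal = False
    if not events:
        no_signal = True
        warnings.append("no exonization signal: candidate matches the homolog consensus")
    elif orf is None:
        warnings.append("candidate has no in-frame stop: no open reading frame to explain")
    else:
        found = False
        n = len(events)
        if n <= max_exhaustive:
            for r in range(1, n + 1):
                for combo in itertools.combinations(range(n), r):
                    chosen = [events[i] for i in combo]
                    try:
                        o = exon_cds(apply_events(ancestral, chosen), frame_offset)
                    except ValueError:
                        o = None
                    if o is not None and o.peptide_length == orf.peptide_length:
                        minimal = chosen
                        found = True
                        break
                if found:
                    break
        if not found:
            # greedy fallback: drop events whose removal keeps the ORF
            chosen = list(events)
            for e in sorted(events, key=lambda e: e.anc_pos):
                trial = [x for x in chosen if x is not e]
                try:
                    o = exon_cds(apply_events(ancestral, trial), frame_offset)
                except ValueError:
                    o = None
                if o is not None and o.peptide_length == orf.peptide_length:
                    chosen = trial
            minimal = chosen

    return ExonizationReport(
        name=candidate.name,
        frame_offset=frame_offset,
        cds_interval=orf.cds_interval if orf else None,
        peptide_length=orf.peptide_length if orf else None,
        stop_codon=orf.stop_codon if orf else None,
        events=list(events) + unpolarized,
        minimal_set=list(minimal),
        homolog_names=[h.name for h in homologs],
        no_signal=no_signal,
        warnings=warnings,
    )


def variant_table(reports: Sequence[ExonizationReport]) -> pd.DataFrame:
    """Comparative table of per-species exon reports (order-invariant)."""
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for r in sorted(reports, key=lambda r: r.name):
        effects = sorted(e.effect for e in r.events if e.effect)
        rows.append(
            {
                "species": r.name,
                "peptide_length": r.peptide_length,
                "stop_codon": r.stop_codon,
                "n_events": len(r.events),
                "minimal_set_size": len(r.minimal_set),
                "effects": ",".join(effects),
            }
        )
    return pd.DataFrame(rows).set_index("species")


def events_to_tsv(report: ExonizationReport, path) -> None:
    """VCF-like TSV: positions are 1-based on the candidate exon."""
    lines = ["#CHROM\tPOS\tREF\tALT\tINFO"]
    for e in report.events:
        pos = e.der_pos + 1
        ref = e.ancestral or "-"
        alt = e.derived or "-"
        info = f"effect={e.effect};kind={e.kind};polarized={int(e.polarized)}"
        lines.append(f"{report.name}\t{pos}\t{ref}\t{alt}\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
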