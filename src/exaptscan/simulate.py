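"""Synthetic genomes with transposon copies of known age and a chimeric locus.

The simulator emulates the study system end to end so every downstream
stage can be validated against machine-readable truth:

* a DNA-transposon consensus with terminal inverted repeats (TIRs) and an
  embedded non-coding "exon source" fragment;
* copies decayed to a target Jukes-Cantor divergence d = r*T (rate r per
  site per year, age T in Ma) and implanted at known loci;
* a four-exon chimeric gene whose last exon derives from the element's
  non-coding fragment via a scripted mutation path: the ancestral state
  carries a 1-nt frameshifting insertion and no in-frame stop, and one
  1-nt deletion plus one TAG-creating substitution open a reading frame.
  Variant scripts add a premature TAG (shorter peptide) or a 16-nt
  frameshifting deletion (different stop), mirroring species variants.

Coordinates are 0-based half-open throughout; GFF3 output converts to
1-based inclusive.  Every operation takes a single integer seed and is
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from exaptscan.records import BASES, SequenceRecord, encode, revcomp

_STOPS = ("TAA", "TAG", "TGA")

# geometry of the derived exon-4 fragment (see _build_exon_core)
N_CODONS = 71          # residues of the full-length peptide
_CAG_CODON = 43        # 0-based codon index forced to CAG (premature-TAG site)
_STOP_NT = 213         # nt offset of the scripted TAG
_INS_NT = 90           # derived-coordinate site of the ancestral extra base
_DEL16_NT = 60         # start of the 16-nt frameshifting deletion variant
_UTR_LEN = 30
FRAGMENT_LEN = 3 * (N_CODONS + 1) + 4 + _UTR_LEN  # 250 nt derived


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ExonSource:
    """Where and how the exon-4 fragment lives inside the consensus.

    ``fragment_interval`` is the ancestral fragment's interval in the
    consensus.  Scripts are ordered (position, type, payload) lists in
    ancestral-fragment coordinates; the default script is the minimal
    ORF-opening pair (1-nt deletion + TAG-creating substitution).
    """

    fragment_interval: tuple[int, int]
    default_script: list[tuple]
    premature_stop_script: list[tuple]
    frameshift16_script: list[tuple]
    derived_fragment: str
    n_codons: int = N_CODONS


@dataclass
class TEConsensus:
    """A transposon consensus: named sequence with TIRs of known length."""

    name: str
    family: str
    sequence: str
    tir_length: int
    exon_source: Optional[ExonSource] = None

    def __post_init__(self) -> None:
        t = self.tir_length
        if t < 0:
            raise ValueError("tir_length must be >= 0")
        if len(self.sequence) < 2 * t:
            raise ValueError("sequence shorter than twice the TIR length")
        if t and self.sequence[:t] != revcomp(self.sequence[-t:]):
            raise ValueError("termini are not inverted repeats")


@dataclass
class CopyTruth:
    name: str
    contig: str
    start: int
    end: int
    strand: str
    d_true: float
    age_ma: float


@dataclass
class ChimericTruth:
    contig: str
    gene_interval: tuple[int, int]
    exon_intervals: list[tuple[int, int]]
    acceptor_pos: int            # position of the A of the intron-terminal AG
    cds_interval: tuple[int, int]
    peptide_length: int
    stop_codon: str
    script: list[tuple]
    homolog_names: list[str] = field(default_factory=list)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated genome."""

    copies: list[CopyTruth] = field(default_factory=list)
    chimeric: Optional[ChimericTruth] = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "copies": [vars(c).copy() for c in self.copies],
            "chimeric": None,
        }
        if self.chimeric is not None:
            c = vars(self.chimeric).copy()
            c["gene_interval"] = list(c["gene_interval"])
            c["exon_intervals"] = [list(x) for x in c["exon_intervals"]]
            c["cds_interval"] = list(c["cds_interval"])
            c["script"] = [list(e) for e in c["script"]]
            d["chimeric"] = c
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        copies = [CopyTruth(**c) for c in d.get("copies", [])]
        chim = None
        if d.get("chimeric"):
            c = dict(d["chimeric"])
            c["gene_interval"] = tuple(c["gene_interval"])
            c["exon_intervals"] = [tuple(x) for x in c["exon_intervals"]]
            c["cds_interval"] = tuple(c["cds_interval"])
            c["script"] = [tuple(e) for e in c["script"]]
            chim = ChimericTruth(**c)
        return cls(copies=copies, chimeric=chim, seed=d.get("seed", 0))


# ---------------------------------------------------------------------------
# divergence arithmetic (kept local so the simulator is self-contained)


def substitution_probability(d: float) -> float:
    """Per-site substitution probability p implied by a JC distance d."""
    if d < 0:
        raise ValueError("divergence must be non-negative")
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    if p >= 0.75:
        raise ValueError("divergence implies substitution probability >= 0.75")
    return p


def _jc(p: float) -> float:
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# operations


def _random_seq(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    probs = [
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ]
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def generate_te_consensus(
    length: int,
    tir_length: int = 14,
    gc_fraction: float = 0.4,
    seed: int = 0,
    name: str = "hAT-10-like",
    family: str = "hAT-10-like",
) -> TEConsensus:
    """A random element whose termini are perfect inverted repeats.

    ``tir_length=0`` yields an unconstrained random sequence.
    """
    if tir_length < 0:
        raise ValueError("tir_length must be >= 0")
    if length < 2 * tir_length + 1:
        raise ValueError("length must be at least 2*tir_length + 1")
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length, gc_fraction))
    if tir_length:
        t = tir_length
        head = "".join(seq[:t])
        seq[-t:] = revcomp(head)
        # break any chance extension so the implanted TIR length is exact
        partner = revcomp(seq[length - 1 - t])
        if seq[t] == partner:
            seq[t] = BASES[(BASES.index(partner) + 1) % 4]
    return TEConsensus(name=name, family=family, sequence="".join(seq), tir_length=tir_length)


def evolve_copy(
    consensus: TEConsensus | SequenceRecord | str,
    target_d: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    name: str = "copy",
) -> tuple[SequenceRecord, float]:
    """Decay one copy of the consensus to a target JC divergence.

    Each site is substituted independently with probability
    p = (3/4)(1 - exp(-4d/3)) to a uniformly chosen different base; indels
    occur at ``indel_rate`` per site with geometric lengths (mean 2).
    Returns the copy and the realized JC divergence (from the realized
    substituted-site fraction, before indels).
    """
    seq = consensus.sequence if hasattr(consensus, "sequence") else consensus
    p = substitution_probability(target_d)
    rng = np.random.default_rng(seed)
    codes = encode(seq).copy()
    mask = rng.random(len(codes)) < p
    n_sub = int(mask.sum())
    if n_sub:
        codes[mask] = (codes[mask] + rng.integers(1, 4, n_sub).astype(np.int8)) % 4
    out = "".join(BASES[c] for c in codes)
    d_true = _jc(n_sub / len(codes)) if len(codes) else 0.0
    if indel_rate > 0:
        pieces = []
        prev = 0
        sites = np.flatnonzero(rng.random(len(out)) < indel_rate)
        for s in sites:
            if s < prev:  # swallowed by a previous deletion
                continue
            pieces.append(out[prev:s])
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # insertion
                pieces.append(out[s])
                pieces.append(_random_seq(rng, length, 0.5))
                prev = s + 1
            else:  # deletion
                prev = min(len(out), s + length)
        pieces.append(out[prev:])
        out = "".join(pieces)
    return SequenceRecord(name=name, sequence=out), d_true


def implant_copies(
    genome: SequenceRecord,
    consensus: TEConsensus,
    ages_Ma: list[float],
    rate: float = 3.1e-9,
    seed: int = 0,
    min_spacing: int = 300,
    max_offset: Optional[int] = None,
    name_prefix: str = "copy",
) -> tuple[SequenceRecord, SimTruth]:
    """Insert decayed copies at collision-free loci; truth has d = r*T.

    Insertion offsets are sampled in the original genome (below
    ``max_offset`` if given) and resampled until pairwise separation is at
    least ``min_spacing``; copies therefore never overlap in the output.
    """
    n = len(ages_Ma)
    truth = SimTruth(seed=seed)
    if n == 0:
        return SequenceRecord(genome.name, genome.sequence), truth
    rng = np.random.default_rng(seed)
    hi = len(genome.sequence) if max_offset is None else max_offset
    if hi <= 0 or n * min_spacing >= hi:
        raise ValueError("genome too short for the requested copies")
    # sorted uniforms on the spacing-reduced interval plus a cumulative
    # offset guarantee pairwise separation >= min_spacing in one draw
    slack = hi - (n - 1) * min_spacing
    offsets = np.sort(rng.integers(0, slack, n)) + np.arange(n) * min_spacing
    pieces = []
    prev = 0
    shift = 0
    for k, off in enumerate(offsets):
        d_true = rate * ages_Ma[k] * 1e6
        copy, _ = evolve_copy(
            consensus, d_true, seed=int(rng.integers(0, 2**31 - 1)),
            name=f"{name_prefix}{k}",
        )
        strand = "+" if rng.random() < 0.5 else "-"
        ins = copy.sequence if strand == "+" else revcomp(copy.sequence)
        pieces.append(genome.sequence[prev:off])
        pieces.append(ins)
        truth.copies.append(
            CopyTruth(
                name=f"{name_prefix}{k}",
                contig=genome.name,
                start=int(off) + shift,
                end=int(off) + shift + len(ins),
                strand=strand,
                d_true=float(d_true),
                age_ma=float(ages_Ma[k]),
            )
        )
        shift += len(ins)
        prev = off
    pieces.append(genome.sequence[prev:])
    return SequenceRecord(genome.name, "".join(pieces)), truth


# ---------------------------------------------------------------------------
# the exon-source fragment and the chimeric locus


def _first_orf(seq: str, frame: int = 0):
    """(cds_length, peptide_length, stop_codon) of the first in-frame stop."""
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            return i + 3 - frame, (i - frame) // 3, codon
    return None


def _frame_constraints_ok(s: str) -> bool:
    # no stop in the +16-deletion shifted frame up to the scripted tail stop
    for i in range(_DEL16_NT + 16, _STOP_NT + 2, 3):
        if s[i : i + 3] in _STOPS:
            return False
    # no stop in the frame read through the ancestral 1-nt insertion
    for i in range(_INS_NT + 2, len(s) - 2, 3):
        if s[i : i + 3] in _STOPS:
            return False
    return True


def _build_exon_core(rng: np.random.Generator) -> str:
    """Derived exon-4 fragment: 71 codons, TAG, then a short tail.

    Construction guarantees (i) no in-frame stop before the TAG, (ii) a
    CAG at codon 44 one substitution away from TAG, (iii) a TAA in the
    frame reached after a 16-nt deletion at nt 60 (peptide 67), and
    (iv) no stop in the frame the ancestral 1-nt insertion produces, so
    the ancestral state is non-coding (translation runs off the end).
    """
    bases = list(BASES)
    while True:
        codons = []
        for k in range(N_CODONS):
            if k == _CAG_CODON:
                codons.append("CAG")
                continue
            while True:
                c = "".join(rng.choice(bases, 3))
                if c not in _STOPS:
                    break
            codons.append(c)
        utr = "".join(rng.choice(list("ACG"), _UTR_LEN))
        s = "".join(codons) + "TAG" + "T" + "TAA" + utr
        if _frame_constraints_ok(s):
            return s


def apply_script(fragment: str, script: list[tuple]) -> str:
    """Apply an ordered mutation script (ancestral-fragment coordinates).

    Events are (position, type, payload): deletion payload is a length,
    insertion/substitution payloads are replacement strings.  Events are
    applied from 3' to 5' so positions stay valid.
    """
    seq = fragment
    for pos, kind, payload in sorted(script, key=lambda e: -e[0]):
        if not 0 <= pos < len(fragment):
            raise ValueError(f"script position {pos} outside the fragment")
        if kind == "deletion":
            seq = seq[:pos] + seq[pos + int(payload):]
        elif kind == "insertion":
            seq = seq[:pos] + str(payload) + seq[pos:]
        elif kind == "substitution":
            pl = str(payload)
            seq = seq[:pos] + pl + seq[pos + len(pl):]
        else:
            raise ValueError(f"unknown event type {kind!r}")
    return seq


def add_exon_source(te: TEConsensus, seed: int = 0, offset: int = 300) -> TEConsensus:
    """Embed the ancestral exon-4 source fragment into a consensus.

    The fragment is placed at ``offset`` (clear of both TIRs); the
    returned element carries the fragment interval and the mutation
    scripts that generate the derived exon and its species variants.
    """
    rng = np.random.default_rng(seed)
    derived = _build_exon_core(rng)
    anc = derived[:_INS_NT] + "C" + derived[_INS_NT:]
    anc = anc[: _STOP_NT + 1] + "C" + anc[_STOP_NT + 2 :]
    default = [(_INS_NT, "deletion", 1), (_STOP_NT + 1, "substitution", "T")]
    premature = default + [(_CAG_CODON * 3 + 1, "substitution", "T")]
    fs16 = default + [(_DEL16_NT, "deletion", 16)]
    f0, f1 = offset, offset + len(anc)
    if f0 <= te.tir_length or f1 >= len(te.sequence) - te.tir_length:
        raise ValueError("fragment would overlap a terminal inverted repeat")
    if apply_script(anc, default) != derived:
        raise AssertionError("script does not regenerate the derived fragment")
    seq = te.sequence[:f0] + anc + te.sequence[f1:]
    return TEConsensus(
        name=te.name,
        family=te.family,
        sequence=seq,
        tir_length=te.tir_length,
        exon_source=ExonSource(
            fragment_interval=(f0, f1),
            default_script=default,
            premature_stop_script=premature,
            frameshift16_script=fs16,
            derived_fragment=derived,
        ),
    )


def implant_chimeric_locus(
    genome: SequenceRecord,
    te: TEConsensus,
    script: Optional[list[tuple]] = None,
    seed: int = 0,
    insert_at: Optional[int] = None,
) -> tuple[SequenceRecord, SimTruth]:
    """Insert a four-exon gene whose exon 4 is the scripted TE fragment.

    The intron 3 tail carries 133 bp of consensus homology and ends with
    the splice-acceptor AG immediately before exon 4.  Truth records the
    exon intervals, acceptor, CDS interval and expected peptide length.
    """
    if te.exon_source is None:
        raise ValueError("consensus carries no exon-source fragment; see add_exon_source")
    src = te.exon_source
    f0, f1 = src.fragment_interval
    anc = te.sequence[f0:f1]
    exon4 = apply_script(anc, script if script is not None else src.default_script)
    orf = _first_orf(exon4, 0)
    if orf is None:
        raise ValueError("scripted exon 4 has no in-frame stop codon")
    cds_len, pep_len, stop = orf

    rng = np.random.default_rng(seed)
    ex1 = _random_seq(rng, 80, 0.45)
    in1 = _random_seq(rng, 150, 0.4)
    ex2 = _random_seq(rng, 120, 0.5)
    in2 = _random_seq(rng, 140, 0.4)
    ex3 = _random_seq(rng, 111, 0.5)
    in3 = _random_seq(rng, 120, 0.4) + te.sequence[max(0, f0 - 133) : f0] + "AG"
    down = te.sequence[f1 : f1 + 207]
    gene = ex1 + in1 + ex2 + in2 + ex3 + in3 + exon4 + down

    pos = len(genome.sequence) // 2 if insert_at is None else insert_at
    if not 0 <= pos <= len(genome.sequence):
        raise ValueError("insertion point outside the genome")
    out = genome.sequence[:pos] + gene + genome.sequence[pos:]

    starts = [0]
    for part in (ex1, in1, ex2, in2, ex3, in3, exon4):
        starts.append(starts[-1] + len(part))
    g = pos
    exons = [
        (g + starts[0], g + starts[1]),
        (g + starts[2], g + starts[3]),
        (g + starts[4], g + starts[5]),
        (g + starts[6], g + starts[7]),
    ]
    ex4_start = exons[3][0]
    truth = SimTruth(
        seed=seed,
        chimeric=ChimericTruth(
            contig=genome.name,
            gene_interval=(pos, pos + len(gene)),
            exon_intervals=exons,
            acceptor_pos=ex4_start - 2,
            cds_interval=(ex4_start, ex4_start + cds_len),
            peptide_length=pep_len,
            stop_codon=stop,
            script=list(script if script is not None else src.default_script),
        ),
    )
    return SequenceRecord(genome.name, out), truth


# ---------------------------------------------------------------------------
# whole-study fixture


@dataclass
class StudyFixture:
    genome: SequenceRecord
    truth: SimTruth
    te: TEConsensus


def extract_copy(genome: SequenceRecord, copy: CopyTruth) -> str:
    seq = genome.sequence[copy.start : copy.end]
    return seq if copy.strand == "+" else revcomp(seq)


def extract_homolog_fragments(fixture: StudyFixture) -> list[SequenceRecord]:
    """Exon-source fragments of the truth homolog copies, consensus-oriented."""
    src = fixture.te.exon_source
    f0, f1 = src.fragment_interval
    names = set(fixture.truth.chimeric.homolog_names)
    out = []
    for c in fixture.truth.copies:
        if c.name in names:
            out.append(SequenceRecord(c.name, extract_copy(fixture.genome, c)[f0:f1]))
    return out


def simulate_study(
    seed: int = 0,
    genome_length: int = 60_000,
    n_copies: int = 20,
    age_ma: float = 17.5,
    rate: float = 3.1e-9,
    n_homologs: int = 4,
    homolog_age_ma: float = 3.0,
    script: Optional[list[tuple]] = None,
    te_length: int = 1000,
    tir_length: int = 14,
) -> StudyFixture:
    """Background genome + dated copies + near-ancestral homologs + locus.

    Defaults reflect the study conditions: copies decayed to d = r*T with
    T = 17.5 Ma and r = 3.1e-9 per site per year (median JC divergence
    ~0.054), a 1 kb element with 14-bp TIRs, and the two-mutation
    ORF-gain script for the chimeric locus.
    """
    rng = np.random.default_rng(seed)
    te = generate_te_consensus(te_length, tir_length, seed=int(rng.integers(2**31 - 1)))
    te = add_exon_source(te, seed=int(rng.integers(2**31 - 1)))
    genome = SequenceRecord("chr_sim", _random_seq(rng, genome_length, 0.42))
    ages = [age_ma] * n_copies + [homolog_age_ma] * n_homologs
    genome, truth = implant_copies(
        genome, te, ages, rate=rate, seed=int(rng.integers(2**31 - 1)),
        max_offset=genome_length - 2000,
    )
    # homologs are the youngest copies; rename for clarity
    by_age = sorted(truth.copies, key=lambda c: c.age_ma)
    homologs = [c.name for c in by_age[:n_homologs]] if n_homologs else []
    genome, chim_truth = implant_chimeric_locus(
        genome, te, script=script, seed=int(rng.integers(2**31 - 1)),
        insert_at=len(genome.sequence) - 1000,
    )
    chim_truth.chimeric.homolog_names = homologs
    truth.chimeric = chim_truth.chimeric
    truth.seed = seed
    return StudyFixture(genome=genome, truth=truth, te=te)
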