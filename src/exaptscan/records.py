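"""Shared primitive types: sequences, coordinate conventions.

All intervals inside the package are 0-based half-open.  GFF3 output is
the only place 1-based inclusive coordinates appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"

# integer encoding shared with the alignment kernels: A=0 C=1 G=2 T=3, other=4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class SequenceRecord:
    """A named nucleotide (or peptide) sequence with an alphabet tag."""

    name: str
    sequence: str
    alphabet: str = "dna"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ScoringScheme:
    """Affine-gap scoring for local/global alignment.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")


#: mild scoring that stays positive in expectation down to ~55% identity,
#: used where an alignment must span a low-identity region
SEGMENT_SCORING = ScoringScheme(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)
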