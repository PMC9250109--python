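"""Readers and writers for the package's on-disk formats.

FASTA goes through Biopython (wrapped at 60 columns).  Truth annotations
are written both as GFF3 (1-based inclusive, source ``exaptscan-sim``)
and as JSON (the lossless form used for round-trips).
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from exaptscan.records import SequenceRecord
from exaptscan.simulate import SimTruth

GFF_SOURCE = "exaptscan-sim"


def write_fasta(records: list[SequenceRecord] | SequenceRecord, path) -> None:
    if isinstance(records, SequenceRecord):
        records = [records]
    bio = [BioSeqRecord(Seq(r.sequence), id=r.name, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_fasta(path) -> list[SequenceRecord]:
    return [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def _gff_line(contig, ftype, start0, end0, strand, attrs) -> str:
    # internal 0-based half-open -> GFF3 1-based inclusive
    attr = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{contig}\t{GFF_SOURCE}\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attr}"


def write_truth_gff3(truth: SimTruth, path) -> None:
    lines = ["##gff-version 3"]
    for c in truth.copies:
        lines.append(
            _gff_line(
                c.contig, "mobile_element", c.start, c.end, c.strand,
                {"ID": c.name, "d_true": f"{c.d_true:.6g}", "age_ma": f"{c.age_ma:g}"},
            )
        )
    ch = truth.chimeric
    if ch is not None:
        g0, g1 = ch.gene_interval
        lines.append(_gff_line(ch.contig, "gene", g0, g1, "+", {"ID": "chimeric_gene"}))
        for i, (s, e) in enumerate(ch.exon_intervals, 1):
            lines.append(
                _gff_line(ch.contig, "exon", s, e, "+",
                          {"ID": f"exon{i}", "Parent": "chimeric_gene"})
            )
        s, e = ch.cds_interval
        lines.append(
            _gff_line(ch.contig, "CDS", s, e, "+",
                      {"ID": "exon4_cds", "Parent": "chimeric_gene"})
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_json(truth: SimTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True) + "\n")


def read_truth_json(path) -> SimTruth:
    return SimTruth.from_dict(json.loads(Path(path).read_text()))


def write_fixture(genome: SequenceRecord, truth: SimTruth, out_dir) -> dict:
    """Write genome FASTA + GFF3 + JSON truth; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "gff3": out / "truth.gff3",
        "json": out / "truth.json",
    }
    write_fasta(genome, paths["genome"])
    write_truth_gff3(truth, paths["gff3"])
    write_truth_json(truth, paths["json"])
    return paths


def read_fixture(out_dir) -> tuple[SequenceRecord, SimTruth]:
    out = Path(out_dir)
    genome = read_fasta(out / "genome.fa")[0]
    truth = read_truth_json(out / "truth.json")
    return genome, truth
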