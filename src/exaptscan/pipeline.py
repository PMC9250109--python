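"""End-to-end orchestration: simulate -> scan -> blocks/TIR -> date -> exonize -> tree.

One configured run writes every stage's outputs plus a machine-readable
summary.  A single seed fans out to per-stage seeds (seed + stage index)
so stages are independently reproducible; rerunning with the same config
and seed reproduces every output byte for byte (no timestamps in
outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from exaptscan import __version__, dating, exonize, homology, io, phylo, regions, simulate
from exaptscan.records import SequenceRecord

log = logging.getLogger("exaptscan")


@dataclass
class RunConfig:
    """All thresholds and rates of one pipeline run."""

    seed: int = 0
    # simulation
    genome_length: int = 60_000
    n_copies: int = 20
    age_ma: float = 17.5
    sim_rate: float = 3.1e-9
    n_homologs: int = 4
    homolog_age_ma: float = 3.0
    te_length: int = 1000
    tir_length: int = 14
    # homology search / census
    min_score: int = 60
    min_identity: float = 0.65
    min_coverage: float = 0.60
    dedup_window: int = 150
    # dating
    rate_low: float = 3.0e-9
    rate_high: float = 3.2e-9
    bin_width: float = 0.01
    # TIR scan
    tir_min: int = 10
    tir_max: int = 30
    tir_max_mismatch: int = 0
    # phylogeny
    bootstrap_reps: int = 1000
    tree_model: str = "K2P"

    def validate(self) -> None:
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dedup_window < 0 or self.min_score <= 0:
            raise ValueError("dedup_window must be >= 0 and min_score positive")
        if self.rate_low <= 0 or self.rate_low > self.rate_high:
            raise ValueError("rates must be positive with rate_low <= rate_high")
        if self.bin_width <= 0 or self.bootstrap_reps < 1:
            raise ValueError("bin_width must be positive, bootstrap_reps >= 1")
        if self.tir_min > self.tir_max or self.tir_min < 1:
            raise ValueError("TIR length range invalid")
        if self.tree_model not in ("JC", "K2P"):
            raise ValueError("tree_model must be JC or K2P")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _setup_logging(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log", mode="w")
    fmt = logging.Formatter("%(levelname)s %(message)s")
    handler.setFormatter(fmt)
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(fmt)
        log.addHandler(stream)
    log.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages in dependency order; returns the summary dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    cfg_hash = config.digest()
    seed = config.seed
    summary: dict = {
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": seed,
    }
    try:
        config.to_yaml(out / "config.yaml")

        log.info("stage=simulate seed=%d", seed + 1)
        fx = simulate.simulate_study(
            seed=seed + 1,
            genome_length=config.genome_length,
            n_copies=config.n_copies,
            age_ma=config.age_ma,
            rate=config.sim_rate,
            n_homologs=config.n_homologs,
            homolog_age_ma=config.homolog_age_ma,
            te_length=config.te_length,
            tir_length=config.tir_length,
        )
        io.write_fixture(fx.genome, fx.truth, out / "fixture")
        io.write_fasta(
            SequenceRecord(fx.te.name, fx.te.sequence), out / "consensus.fa"
        )

        log.info("stage=scan contigs=1 library=1")
        hits = homology.scan_genome(
            fx.genome, [fx.te], min_score=config.min_score
        )
        homology.hits_to_tsv(hits, out / "hits.tsv")
        homology.hits_to_bed(hits, out / "hits.bed")
        count, retained = homology.census(
            hits, config.min_identity, config.min_coverage, config.dedup_window
        )
        log.info("stage=census hits=%d retained=%d", len(hits), count)

        log.info("stage=blocks")
        src = fx.te.exon_source
        f0, f1 = src.fragment_interval
        ex4 = fx.truth.chimeric.exon_intervals[3]
        locus = fx.genome.sequence[ex4[0] - 135 : ex4[1] + 207]
        reference = fx.te.sequence[max(0, f0 - 133) : f1 + 207]
        blocks = regions.segment_blocks(locus, reference)
        regions.blocks_to_tsv(blocks, out / "blocks.tsv")
        tir = regions.find_tir(
            fx.te.sequence, config.tir_min, config.tir_max, config.tir_max_mismatch
        )
        (out / "tir.json").write_text(
            json.dumps(None if tir is None else vars(tir), default=list) + "\n"
        )

        log.info("stage=date copies=%d", len(retained))
        records = []
        lengths = []
        for h in retained:
            p = 1.0 - h.identity
            try:
                d = dating.jc_distance(p)
            except dating.UndefinedDistanceError:
                continue
            records.append(
                dating.DivergenceRecord(
                    f"{h.target_contig}:{h.start}", p=p, d=d,
                    sites_compared=h.end - h.start, family=fx.te.family,
                )
            )
            lengths.append(h.end - h.start)
        ls = dating.landscape(
            records, lengths, len(fx.genome.sequence), config.bin_width
        )
        dating.landscape_to_tsv(ls, out / "landscape.tsv")
        d_med = dating.median_divergence(records)
        age = dating.estimate_age(d_med, config.rate_low, config.rate_high)
        # the reported interval folds the sampling uncertainty of the
        # median (bootstrap 95% CI over copies) into the rate bracket;
        # with few copies the rate bracket alone is far narrower than
        # the median's noise
        d_vals = np.array([r.d for r in records])
        brng = np.random.default_rng(seed + 4)
        boots = np.median(
            d_vals[brng.integers(0, len(d_vals), (500, len(d_vals)))], axis=1
        )
        d_lo, d_hi = np.quantile(boots, [0.025, 0.975])
        age_low = float(d_lo) / config.rate_high / 1e6
        age_high = float(d_hi) / config.rate_low / 1e6
        (out / "age.json").write_text(
            json.dumps(
                {**vars(age), "age_ci_low_Ma": age_low,
                 "age_ci_high_Ma": age_high},
                indent=1,
            )
            + "\n"
        )

        log.info("stage=exonize homologs=%d", config.n_homologs)
        candidate = SequenceRecord(
            "candidate_exon4", fx.genome.sequence[ex4[0] : ex4[1]]
        )
        homolog_frags = simulate.extract_homolog_fragments(fx)
        report = exonize.reconstruct_path(candidate, homolog_frags, frame_offset=0)
        exonize.events_to_tsv(report, out / "events.tsv")
        (out / "exonization.json").write_text(
            json.dumps(
                {
                    "peptide_length": report.peptide_length,
                    "stop_codon": report.stop_codon,
                    "cds_interval": report.cds_interval,
                    "minimal_set": [
                        {"kind": e.kind, "effect": e.effect, "der_pos": e.der_pos}
                        for e in report.minimal_set
                    ],
                    "n_events": len(report.events),
                    "warnings": report.warnings,
                },
                indent=1,
            )
            + "\n"
        )

        log.info("stage=tree reps=%d model=%s", config.bootstrap_reps, config.tree_model)
        msa = dating.center_star_align(homolog_frags + [candidate])
        tree = phylo.bootstrap(
            msa, n_reps=config.bootstrap_reps, model=config.tree_model,
            seed=seed + 6,
        )
        (out / "tree.nwk").write_text(tree.newick() + "\n")

        summary.update(
            {
                "census_count": count,
                "n_hits": len(hits),
                "blocks": [
                    {"label": b.label, "length": b.length,
                     "identity": round(b.identity, 4)}
                    for b in blocks
                ],
                "tir_length": None if tir is None else tir.length,
                "median_divergence": round(d_med, 6),
                "age_low_Ma": round(age_low, 3),
                "age_high_Ma": round(age_high, 3),
                "age_rate_bracket_Ma": [
                    round(age.age_low_Ma, 3), round(age.age_high_Ma, 3)
                ],
                "true_age_Ma": config.age_ma,
                "exonization": {
                    "peptide_length": report.peptide_length,
                    "stop_codon": report.stop_codon,
                    "minimal_set_size": len(report.minimal_set),
                    "minimal_set_effects": sorted(
                        e.effect for e in report.minimal_set
                    ),
                },
                "tree_file": "tree.nwk",
            }
        )
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
        log.info("stage=done census=%d age=[%.2f, %.2f] Ma", count,
                 age.age_low_Ma, age.age_high_Ma)
        return summary
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
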