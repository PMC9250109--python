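"""Synthetic-data generator: TIR construction, decay arithmetic, locus truth."""

import math

import numpy as np
import pytest

from exaptscan import io, simulate
from exaptscan.records import SequenceRecord, revcomp


class TestConsensusGeneration:
    def test_termini_are_inverted_repeats(self):
        te = simulate.generate_te_consensus(1000, 14, seed=1)
        assert te.sequence[:14] == revcomp(te.sequence[-14:])
        assert len(te.sequence) == 1000

    def test_zero_tir_is_unconstrained(self):
        te = simulate.generate_te_consensus(200, 0, seed=3)
        assert len(te.sequence) == 200

    def test_deterministic_for_fixed_seed(self):
        a = simulate.generate_te_consensus(500, 14, seed=9)
        b = simulate.generate_te_consensus(500, 14, seed=9)
        assert a.sequence == b.sequence

    def test_incompatible_length_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_te_consensus(20, 14, seed=0)


class TestEvolveCopy:
    def test_zero_divergence_is_identity(self):
        te = simulate.generate_te_consensus(300, 0, seed=4)
        copy, d = simulate.evolve_copy(te, 0.0, seed=1)
        assert copy.sequence == te.sequence
        assert d == 0.0

    def test_realized_p_matches_jc_inversion(self):
        """At d=0.054 the substitution probability is p=0.0521 (inverted JC)."""
        p_expected = 0.75 * (1 - math.exp(-4 * 0.054 / 3))
        assert abs(p_expected - 0.0521) < 1e-4
        te = simulate.generate_te_consensus(10_000, 0, seed=7)
        copy, _ = simulate.evolve_copy(te, 0.054, seed=11)
        hamming = sum(x != y for x, y in zip(te.sequence, copy.sequence))
        p_hat = hamming / 10_000
        sd = math.sqrt(p_expected * (1 - p_expected) / 10_000)
        assert abs(p_hat - p_expected) < 3 * sd

    def test_median_reestimated_divergence(self):
        """1000 copies at target d=0.054 re-estimate to a median near 0.054."""
        te = simulate.generate_te_consensus(1000, 0, seed=2)
        ds = []
        for k in range(1000):
            copy, _ = simulate.evolve_copy(te, 0.054, seed=k)
            p = sum(x != y for x, y in zip(te.sequence, copy.sequence)) / 1000
            ds.append(-0.75 * math.log(1 - 4 * p / 3))
        assert abs(float(np.median(ds)) - 0.054) < 0.003

    def test_substitution_count_conservation(self):
        """Without indels, Hamming distance equals the drawn substitutions."""
        te = simulate.generate_te_consensus(2000, 0, seed=5)
        copy, d = simulate.evolve_copy(te, 0.1, seed=3)
        hamming = sum(x != y for x, y in zip(te.sequence, copy.sequence))
        p_back = 0.75 * (1 - math.exp(-4 * d / 3))
        assert round(p_back * 2000) == hamming

    def test_saturating_divergence_rejected(self):
        te = simulate.generate_te_consensus(100, 0, seed=1)
        with pytest.raises(ValueError):
            simulate.evolve_copy(te, math.inf, seed=0)

    def test_d_rt_error_shrinks_with_length(self):
        """|realized d - r*T| shrinks as copy length grows (1 kb vs 10 kb)."""
        target = 3.1e-9 * 17.5e6
        errs = {}
        for L in (1000, 10_000):
            te = simulate.generate_te_consensus(L, 0, seed=L)
            devs = [
                abs(simulate.evolve_copy(te, target, seed=k)[1] - target)
                for k in range(30)
            ]
            errs[L] = np.mean(devs)
        assert errs[10_000] < errs[1000]


class TestImplantCopies:
    def test_truth_d_equals_rate_times_age(self):
        genome = SequenceRecord("g", simulate._random_seq(
            np.random.default_rng(0), 30_000, 0.4))
        te = simulate.generate_te_consensus(500, 14, seed=1)
        out, truth = simulate.implant_copies(
            genome, te, [17.5] * 10, rate=3.1e-9, seed=2
        )
        assert all(abs(c.d_true - 0.05425) < 1e-12 for c in truth.copies)
        assert len(out.sequence) == 30_000 + 10 * 500

    def test_truth_intervals_recover_copies(self, study):
        for c in study.truth.copies:
            extracted = simulate.extract_copy(study.genome, c)
            assert len(extracted) == len(study.te.sequence)

    def test_empty_ages_is_identity(self):
        genome = SequenceRecord("g", "ACGT" * 100)
        te = simulate.generate_te_consensus(100, 0, seed=0)
        out, truth = simulate.implant_copies(genome, te, [], seed=1)
        assert out.sequence == genome.sequence and truth.copies == []

    def test_deterministic(self):
        genome = SequenceRecord("g", simulate._random_seq(
            np.random.default_rng(1), 20_000, 0.4))
        te = simulate.generate_te_consensus(400, 14, seed=1)
        a, _ = simulate.implant_copies(genome, te, [5.0] * 5, seed=7)
        b, _ = simulate.implant_copies(genome, te, [5.0] * 5, seed=7)
        assert a.sequence == b.sequence

    def test_capacity_error(self):
        genome = SequenceRecord("g", "ACGT" * 100)
        te = simulate.generate_te_consensus(100, 0, seed=0)
        with pytest.raises(ValueError):
            simulate.implant_copies(genome, te, [1.0] * 50, seed=1)


class TestChimericLocus:
    def test_default_script_gives_71_residues(self, te_with_source):
        genome = SequenceRecord("g", "A" * 5000)
        _, truth = simulate.implant_chimeric_locus(genome, te_with_source, seed=1)
        assert truth.chimeric.peptide_length == 71
        assert truth.chimeric.stop_codon == "TAG"

    def test_premature_stop_variant_gives_43(self, te_with_source):
        genome = SequenceRecord("g", "A" * 5000)
        script = te_with_source.exon_source.premature_stop_script
        _, truth = simulate.implant_chimeric_locus(
            genome, te_with_source, script=script, seed=1
        )
        assert truth.chimeric.peptide_length == 43

    def test_16nt_deletion_variant_gives_67(self, te_with_source):
        genome = SequenceRecord("g", "A" * 5000)
        script = te_with_source.exon_source.frameshift16_script
        _, truth = simulate.implant_chimeric_locus(
            genome, te_with_source, script=script, seed=1
        )
        assert truth.chimeric.peptide_length == 67

    def test_acceptor_ag_precedes_exon4(self, study):
        ch = study.truth.chimeric
        g = study.genome.sequence
        assert g[ch.acceptor_pos : ch.acceptor_pos + 2] == "AG"
        assert ch.acceptor_pos + 2 == ch.exon_intervals[3][0]

    def test_truth_cds_translates_cleanly(self, study):
        """Fixture ORF truth: the truth CDS yields a stop-free peptide."""
        from Bio.Seq import Seq

        ch = study.truth.chimeric
        s, e = ch.cds_interval
        cds = study.genome.sequence[s:e]
        assert len(cds) % 3 == 0
        pep = str(Seq(cds[:-3]).translate())
        assert "*" not in pep
        assert len(pep) == ch.peptide_length

    def test_ancestral_fragment_is_noncoding(self, te_with_source):
        """The unedited fragment has no in-frame stop: translation runs off."""
        f0, f1 = te_with_source.exon_source.fragment_interval
        anc = te_with_source.sequence[f0:f1]
        assert simulate._first_orf(anc, 0) is None

    def test_script_outside_fragment_rejected(self, te_with_source):
        genome = SequenceRecord("g", "A" * 5000)
        with pytest.raises(ValueError):
            simulate.implant_chimeric_locus(
                genome, te_with_source,
                script=[(10_000, "deletion", 1)], seed=1,
            )


class TestFixtureIO:
    def test_round_trip(self, study, tmp_path):
        io.write_fixture(study.genome, study.truth, tmp_path)
        genome, truth = io.read_fixture(tmp_path)
        assert genome.sequence == study.genome.sequence
        assert truth.to_dict() == study.truth.to_dict()

    def test_gff3_is_one_based_inclusive(self, study, tmp_path):
        io.write_fixture(study.genome, study.truth, tmp_path)
        lines = (tmp_path / "truth.gff3").read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        first = next(l for l in lines if "\tmobile_element\t" in l)
        fields = first.split("\t")
        start_1, end_1 = int(fields[3]), int(fields[4])
        c = study.truth.copies[0]
        assert (start_1, end_1) == (c.start + 1, c.end)

    def test_empty_truth_still_valid(self, tmp_path):
        genome = SequenceRecord("g", "ACGT" * 30)
        truth = simulate.SimTruth(seed=1)
        io.write_fixture(genome, truth, tmp_path)
        g2, t2 = io.read_fixture(tmp_path)
        assert g2.sequence == genome.sequence
        assert t2.copies == [] and t2.chimeric is None
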