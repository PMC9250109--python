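"""ORF location, event calling, effect classification, minimal-set search."""

import numpy as np
import pytest

from exaptscan import exonize, simulate
from exaptscan.exonize import MutationEvent
from exaptscan.records import SequenceRecord


class TestExonCds:
    def test_213nt_plus_tag_gives_71_residues(self, te_with_source):
        derived = te_with_source.exon_source.derived_fragment
        res = exonize.exon_cds(derived, 0)
        assert res is not None
        assert res.peptide_length == 71
        assert res.stop_codon == "TAG"
        assert res.cds_interval == (0, 216)

    def test_minimal_orf(self):
        res = exonize.exon_cds("ATGTAA", 0)
        assert res.peptide_length == 1 and res.stop_codon == "TAA"

    def test_no_stop_returns_none(self):
        assert exonize.exon_cds("ATGGCCGCA", 0) is None

    def test_frame_offset_respected(self):
        # TAA in frame 1 only
        assert exonize.exon_cds("ATAACCC", 1).stop_codon == "TAA"
        assert exonize.exon_cds("ATAACCC", 0) is None

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            exonize.exon_cds("ATGNNN", 0)


class TestDiffEvents:
    def test_identical_empty(self):
        assert exonize.diff_events("ACGTA", "ACGTA") == []

    def test_single_deletion(self):
        events = exonize.diff_events("ACGTA", "AC-TA")
        assert len(events) == 1
        e = events[0]
        assert e.kind == "deletion" and e.ancestral == "G" and e.position == 2
        assert e.anc_pos == 2 and e.der_pos == 2

    def test_gap_run_collapses(self):
        events = exonize.diff_events("ACGGGTA", "AC---TA")
        assert len(events) == 1 and events[0].ancestral == "GGG"

    def test_round_trip_on_random_pairs(self):
        """Applying called events to the ancestral rebuilds the candidate."""
        rng = np.random.default_rng(21)
        from exaptscan.dating import center_star_align

        for _ in range(200):
            anc = "".join(rng.choice(list("ACGT"), int(rng.integers(10, 60))))
            der = list(anc)
            for _ in range(int(rng.integers(0, 5))):
                op = rng.integers(0, 3)
                if not der:
                    break
                pos = int(rng.integers(0, len(der)))
                if op == 0:
                    der[pos] = "ACGT"[int(rng.integers(0, 4))]
                elif op == 1:
                    del der[pos]
                else:
                    der.insert(pos, "ACGT"[int(rng.integers(0, 4))])
            der = "".join(der)
            msa = center_star_align([anc, der])
            ga, gb = msa.sequences()
            events = exonize.diff_events(ga, gb)
            assert exonize.apply_events(anc, events) == der


class TestClassifyEffects:
    def _sub(self, anc_pos, anc, der):
        return MutationEvent(anc_pos, "substitution", anc, der, anc_pos, anc_pos)

    def test_16nt_deletion_is_frameshift(self):
        e = MutationEvent(0, "deletion", "A" * 16, "", 0, 0)
        assert e.is_frameshift  # 16 mod 3 == 1

    def test_3nt_deletion_not_frameshift(self):
        anc = "ATGAAACCCGGGTTTTAG"
        e = MutationEvent(3, "deletion", "AAA", "", 3, 3)
        out = exonize.classify_effects([e], anc, 0)
        assert out[0].effect == "inframe_indel"

    def test_cag_to_tag_is_stop_gain(self):
        anc = "ATGCAGGGG"
        e = self._sub(3, "C", "T")
        out = exonize.classify_effects([e], anc, 0)
        assert out[0].effect == "stop_gain"

    def test_upstream_stop_is_premature(self):
        # two stop-creating substitutions; the upstream one is premature
        anc = "ATGCAGAAACAGGGG"
        events = [self._sub(3, "C", "T"), self._sub(9, "C", "T")]
        out = exonize.classify_effects(events, anc, 0)
        assert out[0].effect == "premature_stop"
        assert out[1].effect == "stop_gain"

    def test_frameshift_consistency(self):
        """Frameshift flag <=> indel length not divisible by three."""
        anc = "ATG" + "GCA" * 30 + "TAG"
        rng = np.random.default_rng(3)
        for L in range(1, 10):
            pos = int(rng.integers(3, 60))
            e = MutationEvent(pos, "deletion", anc[pos : pos + L], "", pos, pos)
            out = exonize.classify_effects([e], anc, 0)
            if L % 3 == 0:
                assert out[0].effect == "inframe_indel"
            else:
                assert out[0].effect in (
                    "frameshift_remove", "frameshift_introduce"
                )


class TestReconstructPath:
    def test_two_event_minimal_set(self, candidate_and_homologs):
        """Fixture path: one 1-nt deletion + one TAG-creating substitution."""
        candidate, homologs = candidate_and_homologs
        report = exonize.reconstruct_path(candidate, homologs, 0)
        assert report.peptide_length == 71
        assert len(report.minimal_set) == 2
        kinds = sorted(e.kind for e in report.minimal_set)
        assert kinds == ["deletion", "substitution"]
        effects = sorted(e.effect for e in report.minimal_set)
        assert effects == ["frameshift_remove", "stop_gain"]
        dele = next(e for e in report.minimal_set if e.kind == "deletion")
        assert len(dele.ancestral) == 1

    def test_minimal_set_reproduces_peptide(self, candidate_and_homologs):
        """Frame arithmetic: replaying the minimal set re-opens the same ORF."""
        candidate, homologs = candidate_and_homologs
        report = exonize.reconstruct_path(candidate, homologs, 0)
        # rebuild the ancestral state by reverting every polarized event
        anc = candidate.sequence
        for e in sorted(
            (e for e in report.events if e.polarized),
            key=lambda e: -e.der_pos,
        ):
            p = e.der_pos
            if e.kind == "deletion":
                anc = anc[:p] + e.ancestral + anc[p:]
            elif e.kind == "insertion":
                anc = anc[:p] + anc[p + len(e.derived):]
            else:
                anc = anc[:p] + e.ancestral + anc[p + len(e.derived):]
        replay = exonize.apply_events(anc, report.minimal_set)
        res = exonize.exon_cds(replay, 0)
        assert res is not None and res.peptide_length == report.peptide_length

    def test_premature_variant_reports_43_and_premature_stop(self, study):
        src = study.te.exon_source
        f0, f1 = src.fragment_interval
        anc_frag = study.te.sequence[f0:f1]
        cand = SequenceRecord(
            "variant43",
            simulate.apply_script(anc_frag, src.premature_stop_script),
        )
        homologs = simulate.extract_homolog_fragments(study)
        report = exonize.reconstruct_path(cand, homologs, 0)
        assert report.peptide_length == 43
        assert any(e.effect == "premature_stop" for e in report.events)

    def test_identical_candidate_flags_no_signal(self, study):
        homologs = simulate.extract_homolog_fragments(study)
        src = study.te.exon_source
        f0, f1 = src.fragment_interval
        anc_frag = study.te.sequence[f0:f1]
        # candidate equal to the homolog consensus (ancestral state)
        report = exonize.reconstruct_path(
            SequenceRecord("anc", anc_frag), homologs, 0
        )
        assert report.no_signal
        assert report.minimal_set == []

    def test_requires_homologs(self):
        with pytest.raises(ValueError):
            exonize.reconstruct_path("ACGTACGTTAG", [], 0)


class TestVariantTable:
    def test_species_variant_lengths(self, study):
        """Four species-analog scripts yield peptides {71, 67, 43, 43}."""
        src = study.te.exon_source
        f0, f1 = src.fragment_interval
        anc_frag = study.te.sequence[f0:f1]
        homologs = simulate.extract_homolog_fragments(study)
        scripts = {
            "laevis_like": src.default_script,
            "petersii_like": src.frameshift16_script,
            "itombwensis_like": src.premature_stop_script,
            "largeni_like": src.premature_stop_script,
        }
        reports = [
            exonize.reconstruct_path(
                SequenceRecord(name, simulate.apply_script(anc_frag, sc)),
                homologs, 0,
            )
            for name, sc in scripts.items()
        ]
        table = exonize.variant_table(reports)
        assert sorted(table["peptide_length"]) == [43, 43, 67, 71]

    def test_order_invariance(self, study):
        src = study.te.exon_source
        f0, f1 = src.fragment_interval
        anc_frag = study.te.sequence[f0:f1]
        homologs = simulate.extract_homolog_fragments(study)
        reports = [
            exonize.reconstruct_path(
                SequenceRecord(n, simulate.apply_script(anc_frag, sc)),
                homologs, 0,
            )
            for n, sc in [
                ("x", src.default_script),
                ("y", src.premature_stop_script),
            ]
        ]
        a = exonize.variant_table(reports)
        b = exonize.variant_table(reports[::-1])
        assert a.equals(b)

    def test_single_report(self, candidate_and_homologs):
        candidate, homologs = candidate_and_homologs
        rep = exonize.reconstruct_path(candidate, homologs, 0)
        assert len(exonize.variant_table([rep])) == 1
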