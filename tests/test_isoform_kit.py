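"""Splicing arithmetic, in-silico PCR, band inference and probe QC."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from laminaquant.isoform_kit import (
    BandObservation,
    PrimerPair,
    TranscriptModel,
    append_t3,
    infer_transcript_support,
    predict_products,
    probe_qc,
    probe_tm,
    read_bed12,
    read_gff3,
    splice,
    with_spliced,
    write_bed12,
    T3_PROMOTER,
)
from laminaquant.synthgen import clcc1_like_panel, pnkd_like_panel
from laminaquant.workbench import load_fixture


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSplice:
    def test_single_exon_covering_genome_is_identity(self):
        genome = "ACGTACGTAA"
        m = TranscriptModel("t", exons=((0, 10),))
        assert splice(m, genome) == genome

    def test_two_exons_concatenate(self):
        genome = "A" * 10 + "C" * 20 + "G" * 10
        m = TranscriptModel("t", exons=((0, 10), (30, 40)))
        assert splice(m, genome) == "A" * 10 + "G" * 10

    def test_minus_strand_reverse_complements(self):
        rng = np.random.default_rng(0)
        genome = _random_seq(rng, 100)
        m = TranscriptModel("t", strand="-", exons=((10, 30), (50, 80)))
        expected = str(Seq(genome[10:30] + genome[50:80]).reverse_complement())
        assert splice(m, genome) == expected

    def test_length_equals_sum_of_exon_lengths(self):
        rng = np.random.default_rng(1)
        genome = _random_seq(rng, 500)
        for _ in range(200):
            n_exons = rng.integers(1, 6)
            cuts = np.sort(rng.choice(500, size=2 * n_exons, replace=False))
            exons = tuple((int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_exons))
            m = TranscriptModel("t", exons=exons)
            assert len(splice(m, genome)) == m.spliced_length

    def test_out_of_bounds_exon_rejected(self):
        with pytest.raises(ValueError, match="outside genome"):
            splice(TranscriptModel("t", exons=((0, 50),)), "ACGT")

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TranscriptModel("t", exons=((0, 10), (5, 20)))


class TestModelIO:
    def test_gff3_reader_agrees_with_bed12(self, tmp_path):
        models = [
            TranscriptModel("tx1", "+", ((10, 50), (80, 120), (150, 200)), chrom="chr1"),
            TranscriptModel("tx2", "-", ((20, 60), (90, 130)), chrom="chr1"),
        ]
        bed = tmp_path / "m.bed"
        write_bed12(models, bed)
        gff = tmp_path / "m.gff3"
        lines = ["##gff-version 3"]
        for m in models:
            lines.append(
                f"chr1\tsrc\tmRNA\t{m.exons[0][0] + 1}\t{m.exons[-1][1]}\t.\t{m.strand}\t.\tID={m.id}"
            )
            for s, e in m.exons:
                lines.append(
                    f"chr1\tsrc\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\tParent={m.id}"
                )
        gff.write_text("\n".join(lines) + "\n")
        from_bed = {m.id: m.exons for m in read_bed12(bed)}
        from_gff = {m.id: m.exons for m in read_gff3(gff)}
        assert from_bed == from_gff


class TestPredictProducts:
    def test_product_length_is_forward_start_through_reverse_end(self):
        rng = np.random.default_rng(2)
        fwd = _random_seq(rng, 20)
        rev = _random_seq(rng, 20)
        middle = _random_seq(rng, 110)
        template = fwd + middle + str(Seq(rev).reverse_complement()) + _random_seq(rng, 30)
        m = TranscriptModel("t", exons=((0, len(template)),), spliced=template)
        preds = predict_products(PrimerPair("p", fwd, rev), [m])
        assert [p.product_length for p in preds] == [150]

    def test_no_product_when_forward_exon_is_skipped(self):
        genome, models, pairs, _ = pnkd_like_panel(seed=3)
        p3p4 = next(p for p in pairs if p.name == "p3+p4")
        hits = {p.transcript_id for p in predict_products(p3p4, models)}
        assert hits == {"short"}  # e4 is absent from long and medium

    def test_junctions_spanned_are_reported(self):
        genome, models, pairs, _ = pnkd_like_panel(seed=3)
        p1p2 = next(p for p in pairs if p.name == "p1+p2")
        preds = predict_products(p1p2, models)
        assert all(p.product_length == 246 for p in preds)
        assert all(p.junctions == ("e2_e3",) for p in preds)
        assert {p.transcript_id for p in preds} == {"long", "short"}

    def test_ambiguous_primer_base_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            PrimerPair("p", "ACGTN", "ACGT")

    def test_matches_naive_double_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            seq = _random_seq(rng, 300)
            fwd = seq[10:18]  # short primers so multiple hits are likely
            rev = str(Seq(seq[150:158]).reverse_complement())
            m = TranscriptModel("t", exons=((0, 300),), spliced=seq)
            got = sorted(
                p.product_length for p in predict_products(PrimerPair("p", fwd, rev), [m])
            )
            rc = str(Seq(rev).reverse_complement())
            expected = sorted(
                (j + len(rc)) - i
                for i in range(300) if seq.startswith(fwd, i)
                for j in range(300) if seq.startswith(rc, j)
                if i + len(fwd) <= j
            )
            assert got == expected

    def test_alt_first_exon_pairs_downstream_of_common_exon_are_isoform_blind(self):
        genome, models, pairs, _ = clcc1_like_panel(seed=6)
        rng = np.random.default_rng(5)
        # a primer pair fully inside the shared e3..e6 chain
        m = models[0]
        i3 = m.exon_names.index("e3")
        skip = sum(e - s for s, e in m.exons[:i3])
        tail = m.spliced[skip:]
        pair = PrimerPair("common", tail[5:25], str(Seq(tail[180:200]).reverse_complement()))
        preds = predict_products(pair, models)
        assert len({p.product_length for p in preds}) == 1
        assert {p.transcript_id for p in preds} == {m.id for m in models}


class TestInference:
    def test_single_transcript_all_positive_is_supported(self):
        genome, models, pairs, _ = pnkd_like_panel(seed=1)
        medium = [m for m in models if m.id == "medium"]
        preds = [p for pair in pairs for p in predict_products(pair, medium)]
        obs = [BandObservation("p5+p6", (167,)), BandObservation("p5+p7", (282,))]
        res = infer_transcript_support(preds, obs, transcripts=["medium"])
        assert res.status == {"medium": "supported"}
        assert res.novel_junctions == []

    def test_negative_diagnostic_pair_excludes_short_isoform(self):
        genome, models, pairs, obs = pnkd_like_panel(seed=1)
        preds = [p for pair in pairs for p in predict_products(pair, models)]
        res = infer_transcript_support(
            preds, obs, transcripts=[m.id for m in models],
            primer_pairs=pairs, models=models, genome=genome,
        )
        assert res.status == {
            "long": "supported", "medium": "supported", "short": "excluded",
        }
        assert res.minimal_subsets == [frozenset({"long", "medium"})]

    def test_orphan_band_yields_novel_junction_hypothesis(self):
        genome, models, pairs, obs = clcc1_like_panel(seed=2)
        preds = [p for pair in pairs for p in predict_products(pair, models)]
        res = infer_transcript_support(
            preds, obs, transcripts=[m.id for m in models],
            primer_pairs=pairs, models=models, genome=genome,
        )
        assert res.status["iso_c"] == "excluded"
        assert [h.junction for h in res.novel_junctions] == ["e2_e3"]

    def test_unknown_pair_in_observation_rejected(self):
        genome, models, pairs, obs = pnkd_like_panel(seed=1)
        preds = [p for pair in pairs for p in predict_products(pair, models)]
        with pytest.raises(ValueError, match="unknown primer pair"):
            infer_transcript_support(preds, [BandObservation("p9+p9", (100,))])


class TestProbeQc:
    def test_short_template_fails_on_length(self):
        rng = np.random.default_rng(6)
        report = probe_qc(_random_seq(rng, 150))
        assert not report.passed and report.reasons == ("length",)

    def test_tm_matches_hand_evaluated_formula(self):
        seq = ("AC" * 100) + ("GT" * 100)  # 400 nt, 50% GC
        expected = 81.5 + 16.6 * math.log10(0.195) + 0.41 * 50.0 - 675.0 / 400
        assert probe_tm(seq) == pytest.approx(expected, abs=1e-9)

    def test_homopolymer_is_low_complexity(self):
        report = probe_qc("A" * 300)
        assert report.low_complexity and not report.passed
        assert "low_complexity" in report.reasons

    def test_internal_repeat_is_flagged(self):
        rng = np.random.default_rng(7)
        block = _random_seq(rng, 60)
        report = probe_qc(_random_seq(rng, 100) + block + _random_seq(rng, 80) + block)
        assert report.repeat_flag

    def test_typical_random_template_passes(self):
        rng = np.random.default_rng(8)
        report = probe_qc(_random_seq(rng, 450))
        assert report.passed, report.reasons
        assert 77 <= report.tm <= 94

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            probe_qc("ACGU" * 50)


class TestT3:
    def test_extension_adds_exactly_26(self):
        primer = "GATCGGATTACCA" + "TACGATCG"  # 21 nt
        out = append_t3(primer)
        assert len(out) == len(primer) + 26 == 47
        assert out.startswith("GGAGCAAATTAACCCTCACTAAAGGG")
        assert out.endswith(primer)

    def test_fixture_reverse_primers_follow_the_plus_26_convention(self):
        table1 = load_fixture("table1")
        for _, row in table1.iterrows():
            extended = append_t3(row["reverse"])
            assert len(extended) == len(row["reverse"]) + len(T3_PROMOTER)
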