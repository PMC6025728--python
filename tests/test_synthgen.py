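"""Generator contracts: determinism, polarity, planted ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laminaquant.isoform_kit import read_bed12, splice, write_bed12
from laminaquant.synthgen import (
    AGE_PROFILES,
    AGES,
    ExpressionScenario,
    flat_scenario,
    generate_isoform_panel,
    generate_quant_table,
    generate_section_image,
    layer_bands,
    read_section_image,
    write_section_image,
)


class TestSectionImages:
    @pytest.mark.parametrize("age", AGES)
    def test_no_stain_gives_constant_background(self, age):
        img = generate_section_image(flat_scenario(noise_sd=0.0), age, "WT", seed=1)
        assert np.all(img.pixels == 200)
        assert tuple(img.layer_rows) == AGE_PROFILES[age].layers

    def test_layer_maps_partition_the_section(self):
        for age in AGES:
            bands = layer_bands(age, 200)
            spans = sorted(bands.values())
            assert spans[0][0] == 0 and spans[-1][1] == 200
            for (_, e), (s, _) in zip(spans, spans[1:]):
                assert e == s  # contiguous, non-overlapping

    def test_bit_identical_for_identical_inputs(self):
        sc = ExpressionScenario(
            "g", {("P14", "GCL"): 40.0}, {("P14", "GCL"): 0.05},
            sparse_amplitude=120.0, noise_sd=4.0,
        )
        a = generate_section_image(sc, "P14", "WT", replicate=2, seed=7)
        b = generate_section_image(sc, "P14", "WT", replicate=2, seed=7)
        assert np.array_equal(a.pixels, b.pixels)
        c = generate_section_image(sc, "P14", "WT", replicate=3, seed=7)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_gcl_mean_tracks_planted_amplitude_under_noise(self):
        # Monte-Carlo check: amplitude 80 on background 200 with sd-5 noise
        # leaves the empirical band mean within 3 gray levels of 120.
        sc = ExpressionScenario("g", {("P14", "GCL"): 80.0}, noise_sd=5.0)
        img = generate_section_image(sc, "P14", "WT", seed=3)
        gcl = img.layer_pixels("GCL").astype(float)
        assert gcl.size >= 64 * 64
        assert abs(gcl.mean() - 120.0) < 3.0

    def test_unsupported_age_is_rejected(self):
        with pytest.raises(ValueError, match="unsupported age"):
            generate_section_image(flat_scenario(), "P10", "WT")

    def test_amplitude_above_background_clips_with_warning(self, caplog):
        sc = ExpressionScenario("g", {("P14", "GCL"): 250.0}, noise_sd=0.0)
        with caplog.at_level("WARNING"):
            img = generate_section_image(sc, "P14", "WT", seed=0)
        assert np.all(img.layer_pixels("GCL") == 0)
        assert any("clipping" in r.message for r in caplog.records)

    @given(amp=st.floats(min_value=0, max_value=150))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_more_stain_means_darker_layer(self, amp):
        sc = ExpressionScenario("g", {("P7", "GCL"): amp}, noise_sd=0.0)
        img = generate_section_image(sc, "P7", "WT", seed=0)
        assert img.layer_pixels("GCL").mean() == pytest.approx(
            200.0 - amp, abs=0.5
        )

    def test_genotype_effect_scales_gcl_only(self):
        sc = ExpressionScenario(
            "g", {("P7", "GCL"): 80.0, ("P7", "INL"): 30.0},
            noise_sd=0.0, genotype_effect=0.25,
        )
        ko = generate_section_image(sc, "P7", "KO", seed=0)
        assert ko.layer_pixels("GCL").mean() == pytest.approx(180.0, abs=0.5)
        assert ko.layer_pixels("INL").mean() == pytest.approx(170.0, abs=0.5)

    @pytest.mark.parametrize("suffix", [".png", ".tif"])
    def test_image_round_trip(self, tmp_path, suffix):
        sc = ExpressionScenario("g", {("P3", "GCL"): 30.0}, noise_sd=2.0)
        img = generate_section_image(sc, "P3", "KO", replicate=1, seed=5)
        path = write_section_image(img, tmp_path / f"img{suffix}")
        back = read_section_image(path)
        assert np.array_equal(back.pixels, img.pixels)
        assert back.layer_rows == img.layer_rows
        assert (back.gene, back.age, back.genotype, back.replicate) == (
            "g", "P3", "KO", 1,
        )


class TestQuantTables:
    def test_planted_candidates_pass_all_criteria_with_margin(self):
        df = generate_quant_table(n_genes=100, planted_fraction=0.2, seed=4)
        planted = df[df.planted]
        assert len(planted) == round(0.2 * len(df))
        assert (planted.fpkm_brn3a_wt_rgc > 2).all()
        assert (planted.fpkm_brn3a_wt_rgc / planted.fpkm_brn3a_ko_rgc >= 2.5).all()
        b = planted.fpkm_brn3b_wt_rgc / planted.fpkm_brn3b_ko_rgc
        assert (np.maximum(b, 1 / b) < 1.3).all()

    def test_zero_planted_fraction(self):
        df = generate_quant_table(n_genes=50, planted_fraction=0.0, seed=1)
        assert not df.planted.any()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_quant_table(fold=1.0)
        with pytest.raises(ValueError):
            generate_quant_table(planted_fraction=1.5)

    def test_deterministic(self):
        a = generate_quant_table(n_genes=20, seed=9)
        b = generate_quant_table(n_genes=20, seed=9)
        assert a.equals(b)


class TestIsoformPanels:
    def test_cassette_skipping_arithmetic(self):
        _, models = generate_isoform_panel("cassette", seed=0)
        by_id = {m.id: m for m in models}
        skipped = set(by_id["iso_full"].exon_names) - set(by_id["iso_skip"].exon_names)
        lost = sum(
            e - s
            for name, (s, e) in zip(by_id["iso_full"].exon_names, by_id["iso_full"].exons)
            if name in skipped
        )
        assert by_id["iso_skip"].spliced_length == by_id["iso_full"].spliced_length - lost
        assert len(by_id["iso_skip"].spliced) == by_id["iso_skip"].spliced_length

    def test_alt_first_exon_isoforms_share_downstream_sequence(self):
        genome, models = generate_isoform_panel("alt_first_exon", seed=2)
        tails = []
        for m in models:
            i = m.exon_names.index("e3")
            skip = sum(e - s for s, e in m.exons[:i])
            tails.append(m.spliced[skip:])
        assert len(set(tails)) == 1
        assert len({m.exons[0] for m in models}) == len(models)  # distinct exon 1

    def test_bed12_round_trip_preserves_exon_structure(self, tmp_path):
        for kind in ("alt_first_exon", "cassette"):
            genome, models = generate_isoform_panel(kind, seed=5)
            path = tmp_path / f"{kind}.bed"
            write_bed12(models, path)
            back = {m.id: m for m in read_bed12(path)}
            for m in models:
                assert back[m.id].exons == m.exons
                assert back[m.id].strand == m.strand
                assert splice(back[m.id], genome) == m.spliced

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown panel kind"):
            generate_isoform_panel("nonsense")
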