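import numpy as np
import pandas as pd
import pytest

from riboshift import (
    SimulationConfig,
    PanelConfig,
    simulate_abundances,
    simulate_annotation,
    simulate_counts,
    simulate_mrna_reads,
    simulate_panel,
    simulate_rpf_reads,
)
from riboshift.qc import read_frames


def small_config(**kw):
    defaults = dict(seed=7, n_genes=50, depth_rpf=20_000, depth_mrna=20_000)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestAnnotationSim:
    def test_top_count_rounds(self):
        ann = simulate_annotation(SimulationConfig(seed=0, n_genes=10, top_fraction=0.2))
        assert len(ann.top_gene_ids) == 2

    def test_no_top_when_fraction_zero(self):
        ann = simulate_annotation(SimulationConfig(seed=0, n_genes=10, top_fraction=0.0))
        assert ann.top_gene_ids == []

    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = small_config()
        p1, p2 = tmp_path / "a1.tsv", tmp_path / "a2.tsv"
        simulate_annotation(cfg).to_tsv(p1)
        simulate_annotation(cfg).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_cds_lengths_are_codon_multiples_in_range(self):
        cfg = small_config(cds_length_range=(200, 900))
        for g in simulate_annotation(cfg):
            assert g.cds_length % 3 == 0
            assert 198 <= g.cds_length <= 900


class TestAbundances:
    def test_zero_mouse_cv_is_exact(self):
        cfg = small_config(mouse_cv=0.0)
        ann = simulate_annotation(cfg)
        ab = simulate_abundances(cfg, ann, "control")
        assert (ab.rna["rep1"] == ab.rna["rep2"]).all()

    def test_transcription_times_translation_fold(self):
        # 4-fold transcription x 4.5-fold translation = 18-fold ribosome loading
        cfg = small_config(mouse_cv=0.0, effects={"g01": (4.0, 4.5)}, top_fraction=0.0)
        ann = simulate_annotation(cfg)
        ctrl = simulate_abundances(cfg, ann, "control")
        exer = simulate_abundances(cfg, ann, "exercise")
        assert exer.rna.loc["g01", "rep1"] == pytest.approx(
            4.0 * ctrl.rna.loc["g01", "rep1"]
        )
        assert exer.loading.loc["g01", "rep1"] == pytest.approx(
            18.0 * ctrl.loading.loc["g01", "rep1"]
        )

    def test_neutral_top_fold_means_top_behaves_as_nontop(self):
        cfg = small_config(mouse_cv=0.0, top_te_fold=1.0, top_fraction=0.3)
        ann = simulate_annotation(cfg)
        ctrl = simulate_abundances(cfg, ann, "control")
        exer = simulate_abundances(cfg, ann, "exercise")
        pd.testing.assert_frame_equal(ctrl.loading, exer.loading)

    def test_top_suppression_only_under_exercise(self):
        cfg = small_config(mouse_cv=0.0, top_te_fold=0.5, top_fraction=0.3)
        ann = simulate_annotation(cfg)
        ctrl = simulate_abundances(cfg, ann, "control")
        exer = simulate_abundances(cfg, ann, "exercise")
        top = ann.top_gene_ids
        ratio = exer.loading.loc[top, "rep1"] / ctrl.loading.loc[top, "rep1"]
        assert np.allclose(ratio, 0.5)


class TestRpfReads:
    def test_degenerate_bias_puts_all_ends_on_frame0(self):
        cfg = small_config(frame0_bias=1.0, start_peak_fold=1.0)
        ann = simulate_annotation(cfg)
        ab = simulate_abundances(cfg, ann, "control")
        reads = simulate_rpf_reads(cfg, ann, ab, "s1")
        body = reads[reads["five_prime_pos"] != cfg.peak_offset_nt]
        assert (read_frames(body) == 0).all()

    def test_total_reads_equals_depth(self):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        ab = simulate_abundances(cfg, ann, "control")
        assert len(simulate_rpf_reads(cfg, ann, ab, "s1")) == cfg.depth_rpf

    def test_seeded_determinism(self):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        ab = simulate_abundances(cfg, ann, "control")
        r1 = simulate_rpf_reads(cfg, ann, ab, "s1")
        r2 = simulate_rpf_reads(cfg, ann, ab, "s1")
        pd.testing.assert_frame_equal(r1, r2)

    def test_reads_respect_reference_bounds(self):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        ab = simulate_abundances(cfg, ann, "control")
        for sim in (simulate_rpf_reads, simulate_mrna_reads):
            reads = sim(cfg, ann, ab, "s1")
            cds = reads["gene_id"].map(lambda g: ann[g].cds_length)
            assert (reads["five_prime_pos"] >= -25).all()
            assert (reads["five_prime_pos"] + reads["length"] <= cds).all()

    def test_frame_fraction_matches_binomial_oracle(self):
        # q=0.7 at 1e5 reads: global frame-0 fraction within 3 binomial SEs
        cfg = SimulationConfig(
            seed=11, n_genes=200, frame0_bias=0.7, start_peak_fold=1.0,
            depth_rpf=100_000,
        )
        ann = simulate_annotation(cfg)
        ab = simulate_abundances(cfg, ann, "control")
        reads = simulate_rpf_reads(cfg, ann, ab, "s1")
        frac0 = (read_frames(reads) == 0).mean()
        se = np.sqrt(0.7 * 0.3 / len(reads))
        assert abs(frac0 - 0.7) < 3 * se


class TestMrnaReads:
    def test_uniform_null_frame_fractions(self):
        cfg = small_config(depth_mrna=60_000)
        ann = simulate_annotation(cfg)
        ab = simulate_abundances(cfg, ann, "control")
        reads = simulate_mrna_reads(cfg, ann, ab, "m1")
        fracs = np.bincount(read_frames(reads), minlength=3) / len(reads)
        se = np.sqrt((1 / 3) * (2 / 3) / len(reads))
        assert np.all(np.abs(fracs - 1 / 3) < 4 * se)

    def test_zero_depth_is_empty(self):
        cfg = small_config(depth_mrna=0)
        ann = simulate_annotation(cfg)
        ab = simulate_abundances(cfg, ann, "control")
        assert len(simulate_mrna_reads(cfg, ann, ab, "m1")) == 0

    def test_read_ratio_tracks_abundance_ratio(self):
        # One gene at 2x RNA abundance of another receives ~2x the reads.
        cfg = small_config(mouse_cv=0.0, depth_mrna=100_000)
        ann = simulate_annotation(cfg)
        ab = simulate_abundances(cfg, ann, "control")
        counts = simulate_mrna_reads(cfg, ann, ab, "m1")["gene_id"].value_counts()
        rna = ab.rna["rep1"]
        pairs = 0
        for ga in rna.index[:10]:
            for gb in rna.index[:10]:
                r = rna[ga] / rna[gb]
                if not 1.9 < r < 2.1 or counts.get(gb, 0) < 200:
                    continue
                obs = counts.get(ga, 0) / counts.get(gb, 0)
                se = r * np.sqrt(1 / counts[ga] + 1 / counts[gb])
                assert abs(obs - r) < 4 * se
                pairs += 1
        # fall back: compare top-abundance gene against the multinomial law
        expected = rna / rna.sum() * 100_000
        g = rna.idxmax()
        assert abs(counts[g] - expected[g]) < 4 * np.sqrt(expected[g])


class TestCountsSim:
    def test_library_size_exact_and_deterministic(self):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        ab = simulate_abundances(cfg, ann, "control")
        c1 = simulate_counts(cfg, ab.loading["rep1"], 50_000, "x")
        c2 = simulate_counts(cfg, ab.loading["rep1"], 50_000, "x")
        assert c1.sum() == 50_000
        assert c1.equals(c2)


class TestPanelSim:
    def test_shape_and_groups(self):
        panel = simulate_panel(PanelConfig(seed=1))
        assert len(panel) == 30
        assert set(panel["group"]) == {"NoEx", "0h", "1h", "2h", "4h"}
        assert panel["mouse_id"].is_unique

    def test_deterministic(self):
        p1 = simulate_panel(PanelConfig(seed=5))
        p2 = simulate_panel(PanelConfig(seed=5))
        pd.testing.assert_frame_equal(p1, p2)

    def test_zero_noise_response_is_exact_linear_combination(self):
        cfg = PanelConfig(seed=3, noise_sd=0.0, coefficients={"Pmpca": 2.0}, intercept=0.5)
        panel = simulate_panel(cfg)
        expected = 0.5 + 2.0 * panel["Pmpca"]
        assert np.allclose(panel["Slc25a25_protein"], expected)
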