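import numpy as np
import pandas as pd
import pytest

from riboshift import (
    SimulationConfig,
    ks_two_sample,
    make_count_table,
    pca_profiles,
    rpm_normalize,
    simulate_abundances,
    simulate_annotation,
    simulate_counts,
    te_shift,
    top_shift_test,
    translational_efficiency,
)


def brute_force_ks_d(x, y):
    """Exhaustive ECDF max-gap scan over all observed points."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        gap = abs((x <= t).mean() - (y <= t).mean())
        best = max(best, gap)
    return best


def rpm_frame(values, samples=("r1",)):
    idx = [f"g{i}" for i in range(len(values))]
    return pd.DataFrame({s: values for s in samples}, index=idx)


class TestTranslationalEfficiency:
    def test_ratio_closed_form(self):
        te = translational_efficiency(rpm_frame([200.0]), rpm_frame([100.0]), ["g0"])
        assert te["g0"] == pytest.approx(2.0)

    def test_identity_gives_unit_te(self):
        vals = [10.0, 250.0, 4000.0]
        te = translational_efficiency(rpm_frame(vals), rpm_frame(vals), [f"g{i}" for i in range(3)])
        assert np.allclose(te, 1.0)

    def test_zero_mrna_excluded(self):
        te = translational_efficiency(
            rpm_frame([100.0, 100.0]), rpm_frame([50.0, 0.0]), ["g0", "g1"]
        )
        assert list(te.index) == ["g0"]

    def test_empty_gene_set_is_error(self):
        with pytest.raises(ValueError):
            translational_efficiency(rpm_frame([1.0]), rpm_frame([1.0]), [])

    def test_te_invariant_to_library_scaling(self):
        counts_rpf = pd.DataFrame({"s": [20, 80]}, index=["g0", "g1"])
        counts_mrna = pd.DataFrame({"s": [40, 60]}, index=["g0", "g1"])
        te1 = translational_efficiency(
            rpm_normalize(counts_rpf), rpm_normalize(counts_mrna), ["g0", "g1"]
        )
        te2 = translational_efficiency(
            rpm_normalize(counts_rpf * 7), rpm_normalize(counts_mrna), ["g0", "g1"]
        )
        assert np.allclose(te1, te2)


def _condition_tables(cfg, ann, condition, depth=1_000_000):
    ab = simulate_abundances(cfg, ann, condition)
    rpf = make_count_table(
        [simulate_counts(cfg, ab.loading[r], depth, f"rpf_{condition}_{r}") for r in ab.loading]
    )
    mrna = make_count_table(
        [simulate_counts(cfg, ab.rna[r], depth, f"mrna_{condition}_{r}") for r in ab.rna]
    )
    return rpm_normalize(rpf), rpm_normalize(mrna)


class TestTeShiftSimulator:
    def test_translation_fold_recovered_for_high_count_gene(self):
        cfg = SimulationConfig(seed=31, top_fraction=0.0)
        ann = simulate_annotation(cfg)
        base = simulate_abundances(cfg, ann, "control")
        # a well-expressed gene (~0.2% of the library): tight sampling error
        # without compositionally distorting the RPM normalisation
        share = base.rna["rep1"] / base.rna["rep1"].sum()
        target = (share - 0.002).abs().idxmin()
        cfg = SimulationConfig(seed=31, top_fraction=0.0, effects={target: (4.0, 4.5)})
        rpf_c, mrna_c = _condition_tables(cfg, ann, "control")
        rpf_e, mrna_e = _condition_tables(cfg, ann, "exercise")
        te = te_shift(rpf_c, rpf_e, mrna_c, mrna_e, ann.gene_ids)
        assert np.exp(te.loc[target, "log_ratio"]) == pytest.approx(4.5, rel=0.15)

    def test_top_suppression_detected_with_direction(self):
        cfg = SimulationConfig(seed=32, top_te_fold=0.5)
        ann = simulate_annotation(cfg)
        rpf_c, mrna_c = _condition_tables(cfg, ann, "control")
        rpf_e, mrna_e = _condition_tables(cfg, ann, "exercise")
        te = te_shift(rpf_c, rpf_e, mrna_c, mrna_e, ann.gene_ids)
        res = top_shift_test(te, ann)
        assert res.ks.p_value < 0.01
        assert res.top_shifted_down

    def test_all_nontop_is_error(self):
        cfg = SimulationConfig(seed=33, n_genes=50, top_fraction=0.0, depth_rpf=50_000)
        ann = simulate_annotation(cfg)
        rpf_c, mrna_c = _condition_tables(cfg, ann, "control", depth=50_000)
        rpf_e, mrna_e = _condition_tables(cfg, ann, "exercise", depth=50_000)
        te = te_shift(rpf_c, rpf_e, mrna_c, mrna_e, ann.gene_ids)
        with pytest.raises(ValueError):
            top_shift_test(te, ann)


class TestKsTwoSample:
    def test_identical_samples(self):
        res = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.D == 0.0 and res.p_value == 1.0

    def test_disjoint_supports(self):
        res = ks_two_sample([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert res.D == 1.0

    def test_symmetric(self, rng):
        x, y = rng.normal(size=9), rng.normal(1, 2, size=7)
        a, b = ks_two_sample(x, y), ks_two_sample(y, x)
        assert a.D == b.D and a.p_value == b.p_value

    def test_matches_exhaustive_ecdf_scan(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(2, 11, size=2)
            x = np.round(rng.normal(size=n1), 1)  # rounding forces ties
            y = np.round(rng.normal(0.5, 1, size=n2), 1)
            assert ks_two_sample(x, y).D == pytest.approx(
                brute_force_ks_d(x, y), abs=1e-12
            )

    def test_degenerate_equal_samples(self):
        res = ks_two_sample([2.0, 2.0], [2.0, 2.0])
        assert res.D == 0.0 and res.p_value == 1.0

    def test_tiny_sample_is_error(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [1.0, 2.0])


class TestPca:
    def _toy(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(10, 2000, size=(30, 4)),
            index=[f"g{i:02d}" for i in range(30)],
            columns=["s1", "s2", "s3", "s4"],
        )
        return rpm_normalize(counts)

    def test_identical_samples_have_identical_scores(self):
        rpm = self._toy()
        rpm["s2"] = rpm["s1"]
        scores = pca_profiles(rpm).to_frame()
        assert np.allclose(scores.loc["s1"], scores.loc["s2"], atol=1e-8)

    def test_variance_fractions_sum_below_one(self):
        scores = pca_profiles(self._toy())
        assert 0 < scores.variance_explained.sum() <= 1 + 1e-12

    def test_matches_covariance_eigendecomposition(self):
        rpm = self._toy()
        scores = pca_profiles(rpm, n_components=3)
        X = np.log2(rpm.sort_index().to_numpy().T + 0.5)
        X = X - X.mean(axis=0)
        cov = X @ X.T  # sample-space Gram matrix shares eigenvalues with the covariance
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        expect = v[:, order[:3]] * np.sqrt(w[order[:3]])
        for j in range(3):
            got = scores.scores[:, j]
            assert np.allclose(got, expect[:, j], atol=1e-8) or np.allclose(
                got, -expect[:, j], atol=1e-8
            )

    def test_gene_order_invariance(self):
        rpm = self._toy()
        shuffled = rpm.sample(frac=1, random_state=3)
        s1 = pca_profiles(rpm)
        s2 = pca_profiles(shuffled)
        assert np.allclose(s1.scores, s2.scores, atol=1e-8)

    def test_too_few_samples_is_error(self):
        rpm = self._toy()[["s1", "s2"]]
        with pytest.raises(ValueError):
            pca_profiles(rpm)
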