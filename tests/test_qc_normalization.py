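"""QC stages against exhaustive / hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mechamethyl as mm
from mechamethyl.qc_normalization import run_qc

from conftest import make_dataset


class TestDetectionFilter:
    def test_clean_input_removes_nothing(self):
        ds = make_dataset(np.full((5, 6), 0.5))
        out, removed = mm.detection_filter(ds)
        assert len(removed) == 0 and out.n_probes == 5

    def test_single_failing_cell_removes_exactly_that_probe(self):
        detp = np.zeros((4, 6))
        detp[2, 3] = 0.02
        ds = make_dataset(np.full((4, 6), 0.5), detp=detp)
        out, removed = mm.detection_filter(ds, p_thresh=0.01)
        assert list(removed) == ["p2"]
        assert "p2" not in out.beta.index

    def test_random_matrix_matches_per_cell_scan(self):
        rng = np.random.default_rng(0)
        detp = rng.uniform(0, 0.05, (60, 10))
        ds = make_dataset(rng.uniform(0.1, 0.9, (60, 10)), detp=detp)
        out, removed = mm.detection_filter(ds, p_thresh=0.01)
        expected = {
            f"p{i}"
            for i in range(60)
            if any(detp[i, j] > 0.01 for j in range(10))
        }
        assert set(removed) == expected
        assert set(out.beta.index) == {f"p{i}" for i in range(60)} - expected

    def test_empty_dataset_raises(self):
        ds = make_dataset(np.full((2, 6), 0.5))
        empty = ds.subset_probes(ds.beta.index[:0])
        with pytest.raises(mm.EmptyInputError):
            mm.detection_filter(empty)


class TestQuantileNormalize:
    def test_identical_columns_are_fixed_point(self):
        col = np.array([0.1, 0.5, 0.9, 0.3])
        mat = pd.DataFrame({"a": col, "b": col, "c": col})
        out = mm.quantile_normalize(mat)
        np.testing.assert_allclose(out.to_numpy(), mat.to_numpy())

    def test_hand_computed_order_statistic_means(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = mm.quantile_normalize(mat)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_columns_share_sorted_vector_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(rng.uniform(0, 1, (15, 4)))
        out = mm.quantile_normalize(mat)
        ref = np.sort(out.to_numpy()[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out.to_numpy()[:, j]), ref)
        twice = mm.quantile_normalize(out)
        np.testing.assert_allclose(twice.to_numpy(), out.to_numpy(), atol=1e-12)

    def test_ties_get_average_reference(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
        out = mm.quantile_normalize(mat)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_single_column_is_noop(self):
        mat = pd.DataFrame({"a": [3.0, 1.0, 2.0]})
        out = mm.quantile_normalize(mat)
        np.testing.assert_allclose(out["a"], mat["a"])


class TestControlProbeNormalize:
    def test_constant_controls_identity(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(0, 1, (10, 8)))
        controls = pd.DataFrame(np.ones((4, 8)), columns=vals.columns)
        out = mm.control_probe_normalize(vals, controls, k=2)
        np.testing.assert_allclose(out.to_numpy(), vals.to_numpy())

    def test_constructed_pc1_signal_removed(self):
        rng = np.random.default_rng(2)
        n_samp = 12
        pc = rng.normal(0, 1, n_samp)
        pc -= pc.mean()
        controls = pd.DataFrame(np.outer(rng.normal(1, 0.2, 6), pc))
        probe_mean = rng.normal(0.5, 0.1, 20)
        coeff = rng.normal(0, 2, 20)
        vals = pd.DataFrame(
            probe_mean[:, None] + np.outer(coeff, pc), columns=controls.columns
        )
        out = mm.control_probe_normalize(vals, controls, k=1)
        np.testing.assert_allclose(
            out.to_numpy(), np.tile(probe_mean[:, None], (1, n_samp)), atol=1e-8
        )

    def test_k_zero_identity_and_k_too_large(self):
        vals = pd.DataFrame(np.random.default_rng(3).normal(0, 1, (5, 4)))
        controls = pd.DataFrame(np.random.default_rng(4).normal(0, 1, (3, 4)))
        out = mm.control_probe_normalize(vals, controls, k=0)
        np.testing.assert_allclose(out.to_numpy(), vals.to_numpy())
        with pytest.raises(mm.DomainError):
            mm.control_probe_normalize(vals, controls, k=4)


class TestSnpLikeFlagging:
    def test_unimodal_probe_not_flagged(self):
        rng = np.random.default_rng(5)
        ds = make_dataset(rng.normal(0.5, 0.03, (1, 30)).clip(0, 1))
        flags, conf = mm.flag_snp_like_probes(ds)
        assert len(flags) == 0

    def test_planted_trimodal_probe_flagged_with_confidence(self):
        rng = np.random.default_rng(6)
        centers = rng.choice([0.05, 0.5, 0.95], size=30, p=[0.3, 0.4, 0.3])
        beta = (centers + rng.normal(0, 0.02, 30)).clip(0.001, 0.999)
        ds = make_dataset(beta[None, :])
        flags, conf = mm.flag_snp_like_probes(ds)
        assert list(flags) == ["p0"]
        assert conf["p0"] > 0.5

    def test_sensitivity_and_specificity_on_planted_set(self):
        d = mm.StudyDesign(n_probes=1000, n_genes=100, seed=21)
        ann = mm.generate_probe_annotation(d)
        spec = mm.EffectSpec(frac_snp_like=0.05, frac_dm=0.0, frac_fail=0.0)
        datasets, truth = mm.generate_methylation_experiment(d, spec, ann)
        ds = datasets["spherical"]
        flags, _ = mm.flag_snp_like_probes(ds)
        flagged = set(flags)
        planted = truth.snp_like_probes
        sens = len(flagged & planted) / len(planted)
        spec_rate = 1 - len(flagged - planted) / (d.n_probes - len(planted))
        assert sens >= 0.9
        assert spec_rate >= 0.95


class TestBlacklistAndTransforms:
    def test_blacklist_set_difference(self, tmp_path):
        ds = make_dataset(np.full((6, 6), 0.5))
        bl = tmp_path / "bl.txt"
        bl.write_text("p1\np3\np5\nabsent1\nabsent2\n")
        out = mm.remove_blacklisted(ds, str(bl))
        assert set(out.beta.index) == {"p0", "p2", "p4"}

    def test_empty_blacklist_identity(self):
        ds = make_dataset(np.full((3, 6), 0.5))
        out = mm.remove_blacklisted(ds, [])
        assert list(out.beta.index) == list(ds.beta.index)

    def test_beta_m_round_trip_and_anchors(self):
        assert mm.beta_to_m(0.5) == pytest.approx(0.0)
        assert mm.beta_to_m(0.8) == pytest.approx(2.0)
        rng = np.random.default_rng(7)
        x = rng.uniform(0.01, 0.99, 100)
        np.testing.assert_allclose(mm.m_to_beta(mm.beta_to_m(x)), x, atol=1e-9)


class TestFilterAlgebraAndReport:
    def test_filters_commute_on_retained_set(self):
        rng = np.random.default_rng(8)
        detp = np.where(rng.random((40, 12)) < 0.1, 0.5, 0.001)
        ds = make_dataset(rng.uniform(0.1, 0.9, (40, 12)), detp=detp)
        bl = ["p3", "p7", "p11"]
        a = mm.remove_blacklisted(mm.detection_filter(ds)[0], bl)
        b = mm.detection_filter(mm.remove_blacklisted(ds, bl))[0]
        assert set(a.beta.index) == set(b.beta.index)

    def test_qc_report_counts_reconcile(self, experiment):
        datasets, _ = experiment
        ds = datasets["spherical"]
        out, report = run_qc(ds)
        assert report.n_retained == out.n_probes
        assert (
            report.n_input_probes
            - report.n_failed_detection
            - report.n_snp_like
            - report.n_blacklisted
            == report.n_retained
        )
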