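import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheroprot import differential as diff
from spheroprot import ingest as ing
from spheroprot import normalize as norm
from spheroprot.quant import LogMatrix

from conftest import make_matrix, simple_rows


def one_batch(values, n_refs=0, dims=None):
    n_samples = np.asarray(values).shape[1] - n_refs
    rows = simple_rows(n_samples_per_batch=n_samples, n_refs=n_refs, n_batches=1, dims=dims)
    return make_matrix(values, rows)


class TestReplaceZeros:
    def test_zero_becomes_floor(self):
        q = one_batch([[0.0, 4.0]])
        out = norm.replace_zeros(q)
        np.testing.assert_allclose(out.values.to_numpy(), [[0.1, 4.0]])

    def test_no_zero_identity(self):
        q = one_batch([[2.0, 4.0]])
        out = norm.replace_zeros(q)
        pd.testing.assert_frame_equal(out.values, q.values)

    def test_count_of_changed_cells(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 10, size=(20, 5))
        idx = rng.choice(100, 5, replace=False)
        vals.flat[idx] = 0.0
        q = one_batch(vals)
        out = norm.replace_zeros(q)
        assert int((out.values.to_numpy() != vals).sum()) == 5

    def test_na_untouched(self):
        q = one_batch([[0.0, np.nan]])
        out = norm.replace_zeros(q)
        assert np.isnan(out.values.iloc[0, 1])

    def test_bad_floor(self):
        with pytest.raises(ValueError):
            norm.replace_zeros(one_batch([[1.0, 2.0]]), floor=0)


class TestMedianNormalize:
    def test_two_channel_oracle(self):
        q = one_batch(np.array([[2.0, 1.0], [4.0, 2.0], [6.0, 3.0]]).tolist())
        out = norm.median_normalize(q)
        np.testing.assert_allclose(out.values.to_numpy(), [[1.5, 1.5], [3, 3], [4.5, 4.5]])

    def test_shared_median_identity(self):
        q = one_batch([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        out = norm.median_normalize(q)
        pd.testing.assert_frame_equal(out.values, q.values)

    def test_single_channel_identity(self):
        rows = simple_rows(n_samples_per_batch=1, n_refs=0)
        q = make_matrix([[2.0], [5.0], [9.0]], rows)
        out = norm.median_normalize(q)
        pd.testing.assert_frame_equal(out.values, q.values)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_postcondition_equal_medians(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(3, 1, size=(15, 6))
        out = norm.median_normalize(one_batch(vals.tolist()))
        med = out.values.median(axis=0)
        assert np.allclose(med, med.iloc[0], atol=1e-9)


class TestLog2:
    def test_examples(self):
        q = one_batch([[8.0, 1.0]])
        m = norm.log2_transform(q)
        np.testing.assert_allclose(m.values.to_numpy(), [[3.0, 0.0]])
        assert m.stage == "raw-log2"

    def test_floor_value(self):
        q = one_batch([[0.1, 0.1]])
        m = norm.log2_transform(q)
        np.testing.assert_allclose(m.values.to_numpy(), np.log2(0.1), rtol=1e-12)

    def test_na_propagates(self):
        m = norm.log2_transform(one_batch([[np.nan, 2.0]]))
        assert np.isnan(m.values.iloc[0, 0])

    def test_nonpositive_error(self):
        with pytest.raises(ValueError):
            norm.log2_transform(one_batch([[0.0, 1.0]]))


class TestReferenceScale:
    def test_constant_refs_subtracted(self):
        # refs (6,6,6), samples (5,7) -> samples (-1,+1), refs (0,0,0)
        rows = simple_rows(n_samples_per_batch=2, n_refs=3, n_batches=1)
        m = make_matrix([[5.0, 7.0, 6.0, 6.0, 6.0]], rows, log=True, stage="raw-log2")
        out = norm.reference_scale(m)
        np.testing.assert_allclose(out.values.to_numpy(), [[-1, 1, 0, 0, 0]])
        assert out.stage == "reference-scaled"

    def test_batch_offset_cancels(self):
        rows = simple_rows(n_samples_per_batch=2, n_refs=1, n_batches=2)
        base = np.array([[5.0, 7.0, 6.0]])
        shifted = np.hstack([base + 1.0, base - 1.0])
        m = make_matrix(shifted, rows, log=True, stage="raw-log2")
        out = norm.reference_scale(m)
        b1 = out.values.iloc[0, :3].to_numpy()
        b2 = out.values.iloc[0, 3:].to_numpy()
        np.testing.assert_allclose(b1, b2, atol=1e-12)

    def test_missing_refs_error(self):
        rows = simple_rows(n_samples_per_batch=2, n_refs=0, n_batches=1)
        m = make_matrix([[1.0, 2.0]], rows, log=True, stage="raw-log2")
        with pytest.raises(ValueError, match="batch 1"):
            norm.reference_scale(m)

    def test_removability_cross_batch_replicates(self, noisefree_dataset, design4x4):
        _, truth, q = noisefree_dataset
        m = norm.normalize_pipeline(q)
        samples = design4x4.sample_table
        for _, grp in samples.groupby(["cell_line", "dimension"]):
            keys = [f"{b}:{c}" for b, c in zip(grp["batch"], grp["channel"])]
            block = m.values[keys].to_numpy()
            assert np.abs(block - block[:, [0]]).max() < 1e-9


class TestCenterRows:
    def test_simple(self):
        m = one_batch([[1.0, 2.0, 3.0]])
        lm = LogMatrix(values=m.values, design=m.design, stage="raw-log2")
        out = norm.center_rows(lm)
        np.testing.assert_allclose(out.values.to_numpy(), [[-1, 0, 1]])
        assert out.stage == "centered"

    def test_already_centered_identity(self):
        m = one_batch([[-1.0, 0.0, 1.0]])
        lm = LogMatrix(values=m.values, design=m.design, stage="raw-log2")
        out = norm.center_rows(lm)
        pd.testing.assert_frame_equal(out.values, lm.values)

    def test_na_row_mean_over_finite(self):
        m = one_batch([[1.0, 3.0, np.nan]])
        lm = LogMatrix(values=m.values, design=m.design, stage="raw-log2")
        out = norm.center_rows(lm)
        np.testing.assert_allclose(out.values.to_numpy()[0, :2], [-1, 1])
        assert np.isnan(out.values.iloc[0, 2])

    def test_preserves_pairwise_differences(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(10, 5))
        m = one_batch(vals.tolist())
        lm = LogMatrix(values=m.values, design=m.design, stage="raw-log2")
        out = norm.center_rows(lm)
        np.testing.assert_allclose(
            np.diff(out.values.to_numpy(), axis=1), np.diff(vals, axis=1), atol=1e-12
        )


class TestPipelineInvariants:
    def test_centered_row_means_zero(self, noisy_dataset):
        _, truth, q = noisy_dataset
        q2 = ing.filter_master_proteins(ing.remove_contaminants(q, set(truth.contaminant_accessions))[0])
        m = norm.normalize_pipeline(q2)
        means = m.values[m.sample_keys].mean(axis=1, skipna=True)
        assert means.abs().max() < 1e-9

    def test_batch_scale_equivariance(self, noisefree_dataset):
        # zero-free input: the absolute zero floor breaks strict
        # equivariance on cells that were literal zeros
        _, truth, q = noisefree_dataset
        q2 = ing.filter_master_proteins(q)
        m1 = norm.normalize_pipeline(q2)
        scaled = q2.values.copy()
        scaled[q2.batch_keys(2)] *= 7.5  # whole-batch multiplicative factor
        m2 = norm.normalize_pipeline(q2.with_values(scaled))
        pd.testing.assert_frame_equal(m1.values, m2.values, atol=1e-9, rtol=0)


class TestPca:
    def test_single_axis_explains_all(self):
        t = np.linspace(-1, 1, 6)
        vals = np.outer(np.arange(1, 5), t)  # rank-1 after row centering
        m = one_batch(vals.tolist())
        lm = LogMatrix(values=m.values, design=m.design, stage="centered")
        res = norm.run_pca(lm, k=2)
        assert res.variance_fraction[0] > 0.999999

    def test_rotation_invariance_of_variance(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(30, 6))
        m1 = one_batch(vals.tolist())
        lm1 = LogMatrix(values=m1.values, design=m1.design, stage="centered")
        r1 = norm.run_pca(lm1, k=3)
        Q, _ = np.linalg.qr(rng.normal(size=(30, 30)))
        m2 = one_batch((Q @ vals).tolist())
        lm2 = LogMatrix(values=m2.values, design=m2.design, stage="centered")
        r2 = norm.run_pca(lm2, k=3)
        np.testing.assert_allclose(r1.variance_fraction, r2.variance_fraction, atol=1e-9)

    def test_separates_dimension_groups(self, noisefree_dataset, design4x4):
        _, truth, q = noisefree_dataset
        m = norm.normalize_pipeline(q)
        res = norm.run_pca(m, k=2, include_references=False)
        d = design4x4.sample_table
        keys = [f"{b}:{c}" for b, c in zip(d["batch"], d["channel"])]
        labels = d["dimension"].to_numpy()
        best = 0.0
        for pc in ("PC1", "PC2"):
            s = res.scores.loc[keys, pc].to_numpy()
            gap = abs(s[labels == "3D"].mean() - s[labels == "2D"].mean())
            spread = s[labels == "3D"].std() + s[labels == "2D"].std()
            best = max(best, gap / (spread + 1e-12))
        assert best > 1.0  # one component cleanly separates 2D from 3D

    def test_degenerate_error(self):
        m = one_batch([[1.0, 1.0], [2.0, 2.0]])
        lm = LogMatrix(values=m.values, design=m.design, stage="centered")
        with pytest.raises(ValueError):
            norm.run_pca(lm, k=1)


class TestCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        cols = pd.DataFrame({"a": x, "b": -x})
        corr = norm.correlation_matrix(cols)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_constant_column_warns_na(self):
        cols = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            corr = norm.correlation_matrix(cols)
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["b", "b"] == 1.0

    def test_shared_effects_drive_ratio_correlation(self, design4x4):
        # lines sharing common effects correlate more than independent pairs
        from spheroprot.simulate import SyntheticParams, generate_quant, generate_truth

        params = SyntheticParams(
            n_proteins=500, frac_de=0.3, frac_common=0.6, noise_sd=0.1,
            cellline_effect_sd=0.3, zero_rate=0.0, seed=21,
        )
        truth = generate_truth(params, design4x4)
        q = generate_quant(params, design4x4, truth)
        m = norm.normalize_pipeline(q)
        table = diff.compute_differential(m)
        lfc = table[[c for c in table.columns if c.startswith("lfc_")]]
        corr = norm.ratio_correlation(lfc)
        off_diag = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
        assert off_diag.min() > 0.3  # common effects induce positive coupling


def test_log_matrix_tsv_roundtrip(noisefree_dataset, tmp_path, design4x4):
    _, _, q = noisefree_dataset
    m = norm.normalize_pipeline(q)
    vpath, dpath = tmp_path / "norm.tsv", tmp_path / "design.tsv"
    m.to_tsv(vpath)
    design4x4.to_tsv(dpath)
    assert vpath.read_text().startswith("#stage=centered")
    back = LogMatrix.from_tsv(vpath, dpath)
    assert back.stage == "centered"
    pd.testing.assert_frame_equal(back.values, m.values, atol=1e-9, rtol=0)
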