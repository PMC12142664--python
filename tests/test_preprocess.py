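"""Cleaning/normalization contracts: strict thresholds, blank rule,
single-linkage merging, QC drift correction, IS normalization and the
train-fitted transform."""

import numpy as np
import pandas as pd
import pytest

from shockpanel import (
    FeatureFilterParams,
    FeatureTable,
    apply_transform,
    filter_features,
    fit_transform,
    internal_standard_normalize,
    merge_coeluting_features,
    qc_normalize,
    simulate_cohort,
    subtract_blank,
)
from shockpanel.cohortsim import ROLE_QC, ROLE_STUDY

from conftest import small_config


def _table(inten: dict, mz, rt, snr=None, index=None):
    df = pd.DataFrame(inten, index=index or [f"s{i}" for i in range(len(next(iter(inten.values()))))])
    feats = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(df.columns, name="feature_id"))
    if snr is not None:
        feats["snr"] = snr
    return FeatureTable(df, feats)


class TestFilterFeatures:
    def test_threshold_boundaries_are_strict(self):
        """120k/snr12 retained; exactly 100k removed despite snr 50."""
        t = _table({"hi": [120_000.0, 90_000.0], "edge": [100_000.0, 99_000.0]},
                   mz=[200, 210], rt=[1, 2], snr=[12.0, 50.0])
        out = filter_features(t)
        assert out.feature_ids == ["hi"]

    def test_snr_threshold_strict(self):
        t = _table({"a": [2e5, 2e5], "b": [2e5, 2e5]}, mz=[200, 210], rt=[1, 2],
                   snr=[10.0, 10.0001])
        assert filter_features(t).feature_ids == ["b"]

    def test_empty_feature_set_ok(self):
        t = _table({"a": [1.0, 2.0]}, mz=[100], rt=[1], snr=[50.0])
        out = filter_features(filter_features(t))
        assert out.feature_ids == []

    def test_missing_snr_entry_names_feature(self, toy_table):
        snr = pd.Series({"A": 20.0, "B": 20.0})  # C missing
        with pytest.raises(ValueError, match="C"):
            filter_features(toy_table, snr=snr)

    def test_idempotent(self, small_cohort):
        table, _, _ = small_cohort
        once = filter_features(table)
        twice = filter_features(once)
        assert once.feature_ids == twice.feature_ids


class TestSubtractBlank:
    def test_blank_only_feature_removed_and_10x_retained(self):
        t = _table({"bg": [10.0, 12.0, 1000.0], "real": [5000.0, 6000.0, 500.0]},
                   mz=[150, 160], rt=[1, 2], index=["s1", "s2", "blank"])
        out = subtract_blank(t, ["blank"])
        assert out.feature_ids == ["real"]
        assert "blank" not in out.intensities.index

    def test_matches_bruteforce_rule(self, small_cohort):
        """Exhaustive per-feature re-check of the blank rule."""
        table, samples, _ = small_cohort
        blanks = list(samples.index[samples["role"] == "blank"])
        params = FeatureFilterParams()
        out = subtract_blank(table, blanks, params)
        study = table.intensities.drop(index=blanks)
        expected = [
            f for f in table.feature_ids
            if np.nan_to_num(study[f].mean())
            > params.blank_fold * np.nan_to_num(table.intensities.loc[blanks, f].mean())
        ]
        assert out.feature_ids == expected
        assert len(expected) < len(table.feature_ids)  # some background removed

    def test_absent_blank_id_errors(self, toy_table):
        with pytest.raises(KeyError):
            subtract_blank(toy_table, ["nope"])


class TestMergeCoeluting:
    def test_close_pair_merged_far_pair_not(self):
        t = _table({"a": [10.0, 20.0], "b": [30.0, 5.0], "c": [7.0, 7.0]},
                   mz=[200.0, 200.0008, 200.02], rt=[1.0, 1.3, 1.1])
        out = merge_coeluting_features(t)  # a-b 4 ppm apart, c 100 ppm away
        assert len(out.feature_ids) == 2
        merged = out.intensities.iloc[:, 0]
        assert list(merged) == [30.0, 20.0]  # per-sample max of a,b

    def test_rt_window_blocks_merge(self):
        t = _table({"a": [1.0, 1.0], "b": [1.0, 1.0]},
                   mz=[300.0, 300.0009], rt=[1.0, 1.6])
        assert len(merge_coeluting_features(t).feature_ids) == 2

    def test_chain_merges_by_single_linkage(self):
        """A-B and B-C within tolerance, A-C not: one group regardless."""
        t = _table({"a": [3.0, 1.0], "b": [2.0, 2.0], "c": [1.0, 3.0]},
                   mz=[500.0, 500.002, 500.004], rt=[2.0, 2.0, 2.0])
        out = merge_coeluting_features(t)
        assert len(out.feature_ids) == 1
        assert list(out.intensities.iloc[:, 0]) == [3.0, 3.0]

    def test_agrees_with_bruteforce_components(self, small_cohort):
        """Oracle: O(n^2) connected components over the pairwise relation."""
        table, _, _ = small_cohort
        params = FeatureFilterParams()
        out = merge_coeluting_features(table, params)
        mz = table.features["mz"].to_numpy()
        rt = table.features["rt"].to_numpy()
        n = len(mz)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if (abs(mz[i] - mz[j]) / min(mz[i], mz[j]) < params.ppm_tol * 1e-6
                        and abs(rt[i] - rt[j]) < params.rt_tol):
                    parent[find(i)] = find(j)
        n_groups = len({find(i) for i in range(n)})
        assert len(out.feature_ids) == n_groups

    def test_idempotent(self, small_cohort):
        table, _, _ = small_cohort
        once = merge_coeluting_features(table)
        twice = merge_coeluting_features(once)
        assert once.feature_ids == twice.feature_ids


class TestQCNormalize:
    def test_noiseless_no_drift_is_identity_up_to_constant(self):
        rng = np.random.default_rng(0)
        n = 12
        samples = pd.DataFrame({
            "role": [ROLE_QC if i % 3 == 0 else ROLE_STUDY for i in range(n)],
            "label": None, "subgroup": None, "survival28": None,
            "injection_order": np.arange(1, n + 1),
        }, index=[f"s{i}" for i in range(n)])
        vals = np.tile(rng.uniform(1e5, 1e6, 5), (n, 1))  # constant per feature
        t = _table({f"F{j}": vals[:, j] for j in range(5)},
                   mz=np.linspace(100, 500, 5), rt=np.linspace(1, 9, 5),
                   index=list(samples.index))
        out = qc_normalize(t, samples)
        ratio = out.intensities / t.intensities
        assert np.allclose(ratio, ratio.iloc[0, 0], rtol=1e-9)

    def test_qc_cv_reduced_under_linear_2x_drift(self):
        """Simulated 2x drift across the run: QC CV must not increase, and
        should drop substantially."""
        cfg = small_config(n_features=60, drift_amplitude=1.0, missing_rate=0.0,
                          seed=17)
        table, samples, _ = simulate_cohort(cfg)
        out = qc_normalize(table, samples)
        qc_ids = samples.index[samples["role"] == ROLE_QC]
        pre = (table.intensities.loc[qc_ids].std(ddof=1)
               / table.intensities.loc[qc_ids].mean())
        post = (out.intensities.loc[qc_ids].std(ddof=1)
                / out.intensities.loc[qc_ids].mean())
        assert (post <= pre + 1e-9).all()
        assert post.median() < 0.5 * pre.median()

    def test_identity_sets_preserved(self, small_cohort):
        table, samples, _ = small_cohort
        out = qc_normalize(table, samples)
        assert out.feature_ids == table.feature_ids
        assert out.sample_ids == table.sample_ids

    def test_too_few_qcs_instructs_skip(self, toy_table):
        samples = pd.DataFrame({
            "role": [ROLE_STUDY] * 4, "label": "shock", "subgroup": "shock",
            "survival28": "alive", "injection_order": [1, 2, 3, 4],
        }, index=list(toy_table.intensities.index))
        with pytest.raises(ValueError, match="skip"):
            qc_normalize(toy_table, samples)


class TestInternalStandard:
    def test_equals_elementwise_division_oracle(self):
        rng = np.random.default_rng(3)
        is_vec = rng.uniform(0.5, 2.0, 4)
        t = _table({"A": [1.0, 2.0, 3.0, 4.0], "B": [5.0, 6.0, 7.0, 8.0],
                    "IS": is_vec},
                   mz=[100, 200, 700], rt=[1, 2, 3])
        out = internal_standard_normalize(t, "IS")
        assert "IS" not in out.feature_ids
        np.testing.assert_allclose(out.intensities["A"],
                                   np.array([1.0, 2.0, 3.0, 4.0]) / is_vec)
        np.testing.assert_allclose(out.intensities["B"],
                                   np.array([5.0, 6.0, 7.0, 8.0]) / is_vec)

    def test_doubled_is_halves_that_sample(self):
        t = _table({"A": [10.0, 10.0], "IS": [1.0, 2.0]}, mz=[100, 700], rt=[1, 3])
        out = internal_standard_normalize(t, "IS")
        assert out.intensities["A"].tolist() == [10.0, 5.0]

    def test_zero_is_names_sample(self):
        t = _table({"A": [1.0, 1.0], "IS": [1.0, 0.0]}, mz=[100, 700], rt=[1, 3],
                   index=["good", "bad"])
        with pytest.raises(ValueError, match="bad"):
            internal_standard_normalize(t, "IS")


class TestTransform:
    def test_train_columns_standardized(self, small_cohort):
        table, samples, _ = small_cohort
        study = table.intensities.loc[samples["role"] == ROLE_STUDY]
        state = fit_transform(study)
        Z = apply_transform(state, study)
        assert np.allclose(Z.mean(), 0, atol=1e-9)
        assert np.allclose(Z.std(ddof=1), 1, atol=1e-9)

    def test_constant_feature_dropped(self):
        df = pd.DataFrame({"c": [5.0, 5.0, 5.0], "v": [1.0, 2.0, 4.0]})
        state = fit_transform(df)
        assert state.dropped == ["c"]
        assert list(apply_transform(state, df).columns) == ["v"]

    def test_heldout_matches_oracle_recomputation(self):
        rng = np.random.default_rng(5)
        train = pd.DataFrame(10 ** rng.normal(5, 0.5, (20, 4)),
                             columns=list("wxyz"))
        test = pd.DataFrame(10 ** rng.normal(5, 0.5, (7, 4)),
                            columns=list("wxyz"))
        test.iloc[0, 2] = np.nan
        state = fit_transform(train)
        Z = apply_transform(state, test)
        for c in "wxyz":
            floor = train[c][train[c] > 0].min() / 2
            logv = np.log10(test[c].fillna(floor))
            ltrain = np.log10(train[c])
            expect = (logv - ltrain.mean()) / ltrain.std(ddof=1)
            np.testing.assert_allclose(Z[c], expect, rtol=1e-12)

    def test_no_leakage_from_test_samples(self, small_cohort):
        """TransformState depends only on the training rows."""
        table, samples, _ = small_cohort
        study = table.intensities.loc[samples["role"] == ROLE_STUDY]
        train = study.iloc[:30]
        s1 = fit_transform(train)
        s2 = fit_transform(train)  # test rows never enter
        pd.testing.assert_series_equal(s1.mean, s2.mean)
        Z1 = apply_transform(s1, study.iloc[30:40])
        Z2 = apply_transform(s2, study.iloc[40:50] * 3.0)
        pd.testing.assert_series_equal(s1.sd, s2.sd)
        assert not Z1.index.equals(Z2.index)
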