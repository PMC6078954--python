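"""Institution-balanced splitting, LASSO path CV, refit and metrics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from gliomics.model import (
    SplitSpec,
    compute_metrics,
    fit_lasso_cv,
    idh_labels,
    institution_balanced_split,
    lasso_lambda_max,
    refit_and_evaluate,
    repeat_and_compare,
    select_feature_columns,
)

warnings.filterwarnings("ignore", category=UserWarning)


def manifest_of(n, n_inst):
    return pd.DataFrame({
        "case_id": [f"c{i:03d}" for i in range(n)],
        "institution": np.arange(n) % n_inst,
    })


class TestSplit:
    def test_study_sized_split(self):
        train, val = institution_balanced_split(manifest_of(169, 11), SplitSpec(seed=3))
        assert len(train) == 111 and len(val) == 58

    def test_largest_remainder_single_institution(self):
        train, val = institution_balanced_split(
            manifest_of(10, 1), SplitSpec(train_fraction=0.657, seed=0)
        )
        assert len(train) == 7 and len(val) == 3

    def test_partition_properties(self):
        man = manifest_of(83, 7)
        train, val = institution_balanced_split(man, SplitSpec(seed=11))
        assert set(train) | set(val) == set(man["case_id"])
        assert set(train) & set(val) == set()
        # per-institution counts stay within one of the exact quota
        man_idx = man.set_index("case_id")
        for inst, grp in man.groupby("institution"):
            quota = len(grp) * SplitSpec().train_fraction
            got = sum(man_idx.loc[t, "institution"] == inst for t in train)
            assert abs(got - quota) < 1.0

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            institution_balanced_split(manifest_of(0, 1), SplitSpec())

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="train_fraction"):
            SplitSpec(train_fraction=1.2)


def noise_table(n=120, p=100, seed=0, classes=("a", "b")):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)]
    )
    y = np.array(list(classes) * (n // len(classes)))
    rng.shuffle(y)
    return X, y


class TestLassoCV:
    def test_lambda_max_gives_empty_model(self):
        X, y = noise_table(seed=1)
        lmax = lasso_lambda_max(X.to_numpy(), y, "binomial")
        fit = fit_lasso_cv(X, y, "binomial", lambda_path=np.array([lmax]), seed=0)
        assert fit.selected == []
        assert fit.lambda_min == pytest.approx(lmax)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_feature_selected(self, seed):
        X, y = noise_table(seed=100 + seed)
        X["f0"] = np.where(y == "a", 0.0, 5.0) + np.random.default_rng(seed).normal(size=len(y))
        fit = fit_lasso_cv(X, y, "binomial", seed=seed)
        assert "f0" in fit.selected

    def test_selected_size_non_increasing_in_lambda(self):
        """Stronger penalty gives a sparser model (near-orthogonal design;
        correlated designs can legitimately drop features along the path)."""
        X, y = noise_table(n=200, p=10, seed=0)
        X["f0"] = np.where(y == "a", 0.0, 5.0) + np.random.default_rng(0).normal(size=len(y))
        from gliomics.model import _Standardizer, _make_estimator

        lmax = lasso_lambda_max(X.to_numpy(), y, "binomial")
        path = lmax * np.logspace(0, np.log10(0.05), 10)
        std = _Standardizer(X.to_numpy())
        sizes = []
        for lam in path:
            est = _make_estimator("binomial", lam, len(y))
            est.fit(std(X.to_numpy()), y)
            sizes.append(int((np.abs(est.coef_) > 1e-6).sum()))
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] == 0

    def test_single_class_rejected(self):
        X, _ = noise_table(seed=0)
        with pytest.raises(ValueError, match="single class"):
            fit_lasso_cv(X, np.repeat("a", len(X)), "binomial")

    def test_too_many_folds_rejected(self):
        X, y = noise_table(n=8, p=4, seed=0)
        with pytest.raises(ValueError, match="folds"):
            fit_lasso_cv(X, y, "binomial", n_folds=20)


class TestRefitAndMetrics:
    def test_separable_data_perfect_accuracy(self):
        X, y = noise_table(n=80, p=10, seed=3)
        X["f0"] = np.where(y == "a", -10.0, 10.0)
        fit = fit_lasso_cv(X, y, "binomial", seed=0)
        m_tr, m_va, _ = refit_and_evaluate(
            fit, X.iloc[:60], y[:60], X.iloc[60:], y[60:]
        )
        assert m_tr.accuracy == 1.0 and m_va.accuracy == 1.0

    def test_null_three_class_accuracy_near_chance(self):
        X, y = noise_table(n=169, p=109, seed=4, classes=("a", "b", "c"))
        # 169 is not divisible by 3; pad the label vector deterministically
        y = np.array((["a"] * 57 + ["b"] * 56 + ["c"] * 56))
        np.random.default_rng(4).shuffle(y)
        fit = fit_lasso_cv(X.iloc[:111], y[:111], "multinomial", seed=4,
                           task="subtype_3class")
        _, m_va, _ = refit_and_evaluate(fit, X.iloc[:111], y[:111], X.iloc[111:], y[111:])
        assert 0.23 <= m_va.accuracy <= 0.43

    def test_confusion_rows_sum_to_class_counts(self):
        y_true = np.array(["a"] * 5 + ["b"] * 3 + ["c"] * 2)
        y_pred = np.array(["a", "b", "a", "c", "a", "b", "b", "a", "c", "c"])
        m = compute_metrics(y_true, y_pred)
        for cls, count in zip(*np.unique(y_true, return_counts=True)):
            assert m.confusion.loc[cls].sum() == count

    def test_binary_metric_identities_on_hand_confusion(self):
        # TP=3 FN=1 FP=2 TN=4 with positive class "pos"
        y_true = np.array(["pos"] * 4 + ["neg"] * 6)
        y_pred = np.array(["pos", "pos", "pos", "neg",
                           "pos", "pos", "neg", "neg", "neg", "neg"])
        m = compute_metrics(y_true, y_pred, task="idh_binary", pos_label="pos")
        assert m.accuracy == pytest.approx(7 / 10)
        assert m.sensitivity == pytest.approx(3 / 4)
        assert m.specificity == pytest.approx(4 / 6)
        assert m.ppv == pytest.approx(3 / 5)
        assert m.npv == pytest.approx(4 / 5)

    def test_unseen_validation_class_rejected(self):
        X, y = noise_table(n=40, p=5, seed=5)
        fit = fit_lasso_cv(X, y, "binomial", seed=0, n_folds=4)
        y_val = np.repeat("zzz", 10)
        with pytest.raises(ValueError, match="absent at refit"):
            refit_and_evaluate(fit, X.iloc[:30], y[:30], X.iloc[30:], y_val)


def test_idh_labels_collapse():
    s = np.array(["IDHmt_astro", "IDHmt_TERTmt_oligo", "IDHwt"])
    assert list(idh_labels(s)) == ["IDHmt", "IDHmt", "IDHwt"]


def test_select_feature_columns_uses_one_atlas_only(small_table):
    on_idh = select_feature_columns(small_table, "idh_binary", True)
    on_3c = select_feature_columns(small_table, "subtype_3class", True)
    off = select_feature_columns(small_table, "idh_binary", False)
    assert sum(c.startswith("MNI_str_loc") for c in on_idh) == 10
    assert not any(c.startswith("HrvdOxf") for c in on_idh)
    assert sum(c.startswith("HrvdOxf_loc") for c in on_3c) == 49
    assert not any(c.startswith("MNI_str") for c in on_3c)
    assert len(off) == 50 and not any("loc" in c for c in off)


class TestRepeatAndCompare:
    def test_single_repetition_rejected(self, small_table):
        with pytest.raises(ValueError, match="2 repetitions"):
            repeat_and_compare(small_table, n_rep=1)

    def test_identical_arms_tie(self):
        """With no location columns both arms see the same features."""
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(60, 8)), columns=[f"T1_x{i}" for i in range(8)])
        X["T1_x0"] += np.where(np.arange(60) % 2 == 0, 4.0, 0.0)
        X["subtype"] = np.where(np.arange(60) % 2 == 0, "IDHwt", "IDHmt_astro")
        X["institution"] = np.arange(60) % 3
        X.index = pd.Index([f"c{i}" for i in range(60)], name="case_id")
        res = repeat_and_compare(X, task="idh_binary", n_rep=2, seed=0, n_folds=4,
                                 n_lambdas=10)
        on = [m.accuracy for m in res.metrics["location_on"]]
        off = [m.accuracy for m in res.metrics["location_off"]]
        assert on == off
        assert res.mcnemar_p == 1.0
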