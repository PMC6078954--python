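"""First-order texture, shape, occupancy features and cohort screens."""

import warnings

import numpy as np
import pandas as pd
import pytest

from gliomics.core import AtlasLabelMap, NormalizedVolume, VOIMask, ZScoreVolume
from gliomics.features import (
    anova_screen,
    assemble_feature_table,
    build_default_inventory,
    correlation_matrix,
    enhancement_area,
    first_order_features,
    occupancy_features,
    shape_features,
)


def region_volume(values, shape=(10, 10, 10)):
    """Channel + VOI covering exactly len(values) voxels with given values."""
    data = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    flat = data.reshape(-1)
    flat[: len(values)] = values
    mask.reshape(-1)[: len(values)] = True
    return NormalizedVolume(data=data.astype(np.uint8)), VOIMask(data=mask)


class TestFirstOrder:
    def test_constant_region_conventions(self):
        ch, voi = region_volume([42] * 50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = first_order_features(ch, voi)
        assert f["mean"] == 42 and f["sd"] == 0 and f["entropy"] == 0
        assert f["median"] == f["p10"] == f["p90"] == 42
        assert f["skewness"] == 0 and f["kurtosis"] == 0

    def test_two_level_histogram_entropy_is_one_bit(self):
        ch, voi = region_volume([0] * 32 + [255] * 32)
        f = first_order_features(ch, voi)
        assert f["entropy"] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        """All eight statistics against definition-level computations."""
        rng = np.random.default_rng(8)
        values = rng.integers(0, 256, size=1000)
        ch, voi = region_volume(values)
        f = first_order_features(ch, voi)
        x = values.astype(float)
        n = x.size
        mu = x.sum() / n
        m2 = ((x - mu) ** 2).sum() / n
        m3 = ((x - mu) ** 3).sum() / n
        m4 = ((x - mu) ** 4).sum() / n
        counts = np.bincount(values, minlength=256)
        p = counts[counts > 0] / n
        oracle = {
            "mean": mu,
            "sd": np.sqrt(m2),
            "skewness": m3 / m2 ** 1.5,
            "kurtosis": m4 / m2 ** 2 - 3.0,
            "median": np.median(x),
            "p10": np.percentile(x, 10),
            "p90": np.percentile(x, 90),
            "entropy": float(-(p * np.log2(p)).sum()),
        }
        for k, v in oracle.items():
            assert f[k] == pytest.approx(v, abs=1e-9), k

    def test_outside_voi_is_ignored(self):
        rng = np.random.default_rng(0)
        ch, voi = region_volume(rng.integers(0, 256, 200))
        f1 = first_order_features(ch, voi)
        altered = ch.data.copy()
        altered[~voi.data] = 199
        f2 = first_order_features(NormalizedVolume(data=altered), voi)
        assert f1 == f2

    def test_empty_voi_rejected(self):
        ch, _ = region_volume([1])
        with pytest.raises(ValueError, match="empty VOI"):
            first_order_features(ch, VOIMask(data=np.zeros((10, 10, 10), dtype=bool)))


def ball_mask(radius, shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0), stretch=(1, 1, 1)):
    x, y, z = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    c = (np.asarray(shape) - 1) / 2
    r2 = (((x - c[0]) / stretch[0]) ** 2 + ((y - c[1]) / stretch[1]) ** 2
          + ((z - c[2]) / stretch[2]) ** 2)
    return VOIMask(data=r2 <= radius ** 2, spacing=spacing)


class TestShape:
    def test_single_voxel_volume(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[4, 4, 4] = True
        f = shape_features(VOIMask(data=mask, spacing=(1.0, 1.0, 1.0)))
        assert f["volume_mm3"] == pytest.approx(1.0)

    def test_digital_ball_sphericity_near_one(self):
        f = shape_features(ball_mask(10))
        assert 0.90 <= f["sphericity"] <= 1.00

    def test_elongation_lowers_sphericity(self):
        ball = shape_features(ball_mask(8))
        # same-volume ellipsoid with 4:1 axis ratio
        stretched = shape_features(
            ball_mask(8 / 4 ** (1 / 3), shape=(64, 32, 32), stretch=(4, 1, 1))
        )
        assert ball["sphericity"] > stretched["sphericity"]

    def test_spacing_scales_volume(self):
        f = shape_features(ball_mask(6, spacing=(2.0, 2.0, 2.0)))
        assert f["volume_mm3"] == pytest.approx(ball_mask(6).n_voxels * 8.0)


class TestEnhancementArea:
    def test_zero_map_gives_zero(self):
        z = ZScoreVolume(data=np.zeros((6, 6, 6)))
        voi = VOIMask(data=np.ones((6, 6, 6), dtype=bool))
        assert enhancement_area(z, voi) == 0.0

    def test_half_enhancing(self):
        data = np.zeros((6, 6, 6))
        data.reshape(-1)[:108] = 5.0
        z = ZScoreVolume(data=data)
        voi = VOIMask(data=np.ones((6, 6, 6), dtype=bool))
        assert enhancement_area(z, voi, z_thresh=2.0) == pytest.approx(0.5)

    def test_counting_oracle(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(8, 8, 8))
        voi = VOIMask(data=rng.uniform(size=(8, 8, 8)) > 0.5)
        got = enhancement_area(ZScoreVolume(data=data), voi, z_thresh=1.0)
        assert got == pytest.approx((data[voi.data] > 1.0).sum() / voi.n_voxels)


class TestOccupancy:
    def test_one_hot_frontal(self, atlas10):
        voi = VOIMask(data=atlas10.data == 3)
        occ = occupancy_features(voi, atlas10)
        assert occ["loc.04"] == 1.0
        assert sum(occ.values()) == pytest.approx(1.0)
        assert all(v == 0.0 for k, v in occ.items() if k != "loc.04")

    def test_even_split_across_two_labels(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[2:] = 5
        atlas = AtlasLabelMap(data=labels, labels={0: "a", 5: "f"})
        voi = np.zeros((4, 4, 4), dtype=bool)
        voi[1] = voi[2] = True
        occ = occupancy_features(VOIMask(data=voi), atlas)
        assert occ["loc.01"] == 0.5 and occ["loc.06"] == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counting_oracle_and_unit_sum(self, atlas49, seed):
        rng = np.random.default_rng(seed)
        voi = VOIMask(data=rng.uniform(size=atlas49.shape) > 0.9)
        occ = occupancy_features(voi, atlas49)
        assert sum(occ.values()) == pytest.approx(1.0, abs=1e-9)
        vals = atlas49.data[voi.data]
        for k in range(49):
            assert occ[f"loc.{k + 1:02d}"] == pytest.approx(
                (vals == k).sum() / vals.size, abs=1e-12
            )

    def test_grid_mismatch(self, atlas10):
        voi = VOIMask(data=np.ones((8, 8, 8), dtype=bool))
        with pytest.raises(ValueError, match="grid mismatch"):
            occupancy_features(voi, atlas10)


class TestAssembleTable:
    def test_inventory_has_109_unique_names(self):
        inv = build_default_inventory()
        assert len(inv) == 109 and len(set(inv)) == 109

    def test_full_cohort_table(self, small_table):
        assert small_table.shape == (30, 111)  # 109 features + 2 metadata
        feats = small_table.drop(columns=["subtype", "institution"])
        assert list(feats.columns) == build_default_inventory()
        assert not feats.isna().any().any()

    def test_incomplete_case_excluded(self, caplog):
        inv = build_default_inventory()
        good = {k: 0.0 for k in inv}
        records = [
            ("c1", "IDHwt", 0, good),
            ("c2", "IDHwt", 0, None),  # e.g. missing Gd channel
            ("c3", "IDHmt_astro", 1, {k: 1.0 for k in inv[:50]}),
        ]
        import logging

        with caplog.at_level(logging.WARNING, logger="gliomics.features"):
            table = assemble_feature_table(records)
        assert list(table.index) == ["c1"]
        assert "2 case(s)" in caplog.text

    def test_empty_cohort_keeps_header(self):
        table = assemble_feature_table([])
        assert len(table) == 0
        assert list(table.columns) == build_default_inventory() + ["subtype", "institution"]


def make_group_table(groups, rng=None):
    rows = []
    for name, values in groups.items():
        for v in values:
            rows.append({"f": v, "subtype": name, "institution": 0})
    return pd.DataFrame(rows)


class TestAnovaScreen:
    def test_constant_feature_gets_p_one(self):
        table = make_group_table({"a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 1]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = anova_screen(table)
        assert out.loc["f", "p"] == 1.0 and out.loc["f", "bin"] == ">=0.05"

    def test_matches_textbook_f_statistic(self):
        groups = {"a": [3.0, 5.0, 4.0], "b": [6.0, 8.0, 7.0], "c": [9.0, 12.0, 10.0]}
        out = anova_screen(make_group_table(groups))
        # textbook one-way ANOVA from sums of squares
        all_vals = np.concatenate([np.asarray(v) for v in groups.values()])
        grand = all_vals.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        df_b, df_w = 2, len(all_vals) - 3
        f_oracle = (ss_between / df_b) / (ss_within / df_w)
        from scipy.stats import f as fdist

        assert out.loc["f", "F"] == pytest.approx(f_oracle, abs=1e-9)
        assert out.loc["f", "p"] == pytest.approx(fdist.sf(f_oracle, df_b, df_w), abs=1e-9)

    def test_planted_effect_lands_in_strictest_bin(self):
        rng = np.random.default_rng(0)
        groups = {
            "a": rng.normal(0, 1, 30), "b": rng.normal(5, 1, 30),
            "c": rng.normal(10, 1, 30),
        }
        out = anova_screen(make_group_table(groups))
        assert out.loc["f", "bin"] == "<0.001"

    def test_small_group_rejected(self):
        table = make_group_table({"a": [1.0, 2.0], "b": [3.0]})
        with pytest.raises(ValueError, match=">= 2 cases"):
            anova_screen(table)


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, small_table):
        corr = correlation_matrix(small_table)
        arr = corr.to_numpy()
        assert np.allclose(arr, arr.T)
        nonconst = small_table.drop(columns=["subtype", "institution"]).std() > 0
        assert np.allclose(np.diag(arr)[nonconst.to_numpy()], 1.0)
        assert np.nanmax(np.abs(arr)) <= 1.0 + 1e-12

    def test_duplicated_column_fully_correlated(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"f1": rng.normal(size=20), "subtype": "x", "institution": 0})
        t["f2"] = t["f1"]
        corr = correlation_matrix(t)
        assert corr.loc["f1", "f2"] == pytest.approx(1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        t["subtype"] = "x"
        t["institution"] = 0
        corr = correlation_matrix(t)
        X = t[list("abcd")].to_numpy()
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / len(X)
        sd = np.sqrt(np.diag(cov))
        oracle = cov / np.outer(sd, sd)
        assert np.allclose(corr.to_numpy(), oracle, atol=1e-9)

    def test_constant_column_zeroed_with_warning(self):
        t = pd.DataFrame({"f1": [1.0, 2.0, 3.0], "f2": [7.0, 7.0, 7.0],
                          "subtype": "x", "institution": 0})
        with pytest.warns(UserWarning, match="constant"):
            corr = correlation_matrix(t)
        assert (corr.loc["f2"] == 0).all()
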