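import json

import numpy as np
import pandas as pd
import pytest

import wetstage as ws
from wetstage.composite import FeatureSchema, QuarterKey
from wetstage.model import (RFParams, SplitSpec, StageModel, TwoStageRF,
                            fit_stage1, fit_stage2, importance_heatmap,
                            split_train_test)

FAST_RF = RFParams(n_estimators=80)


def toy_table(n=200, seed=0, noise=0.0, continuous_signal=True):
    """Additive toy data: target = 2*d1 + (NDVI part) + noise."""
    rng = np.random.default_rng(seed)
    d1 = rng.integers(0, 5, n).astype(float)
    d2 = rng.uniform(0, 1, n)
    ndvi = rng.uniform(-0.2, 0.8, n)
    b2 = rng.uniform(0, 1, n)
    y = 2.0 * d1 + (1.5 * ndvi if continuous_signal else 0.0) \
        + rng.normal(0, noise, n)
    return pd.DataFrame({
        "d1": d1, "d2": d2, "NDVI": ndvi, "B2": b2,
        "concentration": y, "quarter": rng.integers(1, 5, n),
        "flagged": False,
    })


SCHEMA = FeatureSchema(discrete=["d1", "d2"], continuous=["NDVI", "B2"])


class TestSplit:
    def test_counts_70_30(self):
        table = toy_table(100)
        train, test = split_train_test(table, SplitSpec(seed=4))
        assert (len(train), len(test)) == (70, 30)

    def test_deterministic_and_exhaustive(self):
        table = toy_table(123)
        a1, b1 = split_train_test(table, SplitSpec(seed=9))
        a2, b2 = split_train_test(table, SplitSpec(seed=9))
        pd.testing.assert_frame_equal(a1, a2)
        union = pd.concat([a1, b1]).sort_index()
        pd.testing.assert_frame_equal(union, table)
        assert set(a1.index).isdisjoint(b1.index)

    def test_stratified_split_respects_groups(self):
        table = toy_table(120)
        table["w"] = np.repeat(["a", "b", "c"], 40)
        train, test = split_train_test(table, SplitSpec(seed=1, strata="w"))
        for _, grp in train.groupby("w"):
            assert len(grp) == 28  # round(0.7 * 40)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(toy_table(5).iloc[0:0], SplitSpec())


class TestStage1:
    def test_recovers_linear_discrete_signal(self):
        table = toy_table(300, continuous_signal=False)
        train, test = split_train_test(table, SplitSpec(seed=0))
        model, resid = fit_stage1(train, ["d1", "d2"], rf_params=FAST_RF, seed=0)
        pred = model.predict(test)
        m = ws.evaluate(pred, test["concentration"])
        assert m.r2 > 0.95
        assert model.ranked_features()[0][0] == "d1"
        assert len(resid) == len(train)

    def test_pure_noise_target_gives_near_zero_r2(self):
        """Held-out r2 hovers around 0 when the target carries no signal."""
        r2s = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            table = toy_table(150, seed=seed, continuous_signal=False)
            table["concentration"] = rng.normal(0, 1, len(table))
            train, test = split_train_test(table, SplitSpec(seed=seed))
            model, _ = fit_stage1(train, ["d1", "d2"], rf_params=FAST_RF,
                                  seed=seed)
            r2s.append(ws.evaluate(model.predict(test),
                                   test["concentration"]).r2)
        # a forest fit to pure noise has no hold-out skill (r2 at or below 0)
        assert float(np.median(r2s)) < 0.1

    def test_oob_residuals_are_not_degenerate(self):
        table = toy_table(200, noise=0.5)
        train, _ = split_train_test(table, SplitSpec(seed=2))
        _, oob_resid = fit_stage1(train, ["d1", "d2"], rf_params=FAST_RF,
                                  seed=2, residual_source="oob")
        _, ins_resid = fit_stage1(train, ["d1", "d2"], rf_params=FAST_RF,
                                  seed=2, residual_source="insample")
        # in-sample RF residuals are shrunk; OOB residuals keep the noise scale
        assert np.std(oob_resid) > np.std(ins_resid)

    def test_single_row_train_rejected(self):
        with pytest.raises(ValueError):
            fit_stage1(toy_table(5).iloc[:1], ["d1"], rf_params=FAST_RF)

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            fit_stage1(toy_table(10), [], rf_params=FAST_RF)

    def test_constant_target_warns(self):
        table = toy_table(30)
        table["concentration"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            fit_stage1(table, ["d1"], rf_params=FAST_RF)

    def test_importances_normalized(self):
        table = toy_table(100)
        model, _ = fit_stage1(table, ["d1", "d2"], rf_params=FAST_RF)
        assert sum(model.importances.values()) == pytest.approx(1.0, abs=1e-6)


class TestStage2:
    def test_recovers_noiseless_ndvi_residual(self):
        table = toy_table(300)
        train, test = split_train_test(table, SplitSpec(seed=1))
        resid_train = 1.5 * train["NDVI"].to_numpy()
        model = fit_stage2(train, ["NDVI", "B2"], resid_train,
                           rf_params=FAST_RF, seed=1)
        pred = model.predict(test)
        m = ws.evaluate(pred, 1.5 * test["NDVI"].to_numpy())
        assert m.r2 > 0.9
        assert model.ranked_features()[0][0] == "NDVI"

    def test_noise_residuals_give_near_zero_r2(self):
        r2s = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            table = toy_table(150, seed=seed)
            train, test = split_train_test(table, SplitSpec(seed=seed))
            model = fit_stage2(train, ["NDVI", "B2"],
                               rng.normal(0, 1, len(train)),
                               rf_params=FAST_RF, seed=seed)
            r2s.append(ws.evaluate(model.predict(test),
                                   rng.normal(0, 1, len(test))).r2)
        assert float(np.median(r2s)) < 0.1

    def test_zero_residuals_predict_zero(self):
        table = toy_table(100)
        model = fit_stage2(table, ["NDVI"], np.zeros(len(table)),
                           rf_params=FAST_RF)
        np.testing.assert_allclose(model.predict(table), 0.0, atol=1e-12)

    def test_misaligned_residuals_rejected(self):
        table = toy_table(50)
        with pytest.raises(ValueError):
            fit_stage2(table, ["NDVI"], np.zeros(10), rf_params=FAST_RF)


class TestTwoStage:
    def test_additive_identity_and_clipping(self):
        table = toy_table(200, seed=3)
        table.loc[:, "concentration"] -= 4.0  # force some negative finals
        res = TwoStageRF(table, SCHEMA, rf_params=FAST_RF,
                         split=SplitSpec(seed=3)).fit()
        with pytest.warns(UserWarning, match="clipped"):
            pred = res.predict(table)
        ok = ~pred["baseline_only"]
        np.testing.assert_allclose(
            pred.loc[ok, "final_raw"],
            pred.loc[ok, "baseline"] + pred.loc[ok, "correction"], atol=1e-12)
        assert (pred["final"] >= 0).all()
        raw_neg = pred["final_raw"] < 0
        assert raw_neg.any()
        np.testing.assert_array_equal(pred.loc[raw_neg, "final"], 0.0)

    def test_flagged_rows_fall_back_to_baseline(self):
        table = toy_table(120, seed=4)
        table.loc[:10, "flagged"] = True
        res = TwoStageRF(table, SCHEMA, rf_params=FAST_RF,
                         split=SplitSpec(seed=4)).fit()
        pred = res.predict(table)
        flagged = pred["baseline_only"]
        assert flagged[:11].all()
        np.testing.assert_allclose(pred.loc[flagged, "final_raw"],
                                   pred.loc[flagged, "baseline"], atol=1e-12)
        assert pred.loc[flagged, "correction"].isna().all()

    def test_metrics_reported_for_all_three_scopes(self):
        res = TwoStageRF(toy_table(200, seed=5, noise=0.3), SCHEMA,
                         rf_params=FAST_RF, split=SplitSpec(seed=5)).fit()
        assert set(res.metrics) == {"stage1", "stage2", "final"}
        for m in res.metrics.values():
            assert m.rmse >= m.mae >= abs(m.mbe) >= 0.0

    def test_fixed_seed_gives_bit_identical_metrics(self):
        docs = []
        for _ in range(2):
            res = TwoStageRF(toy_table(150, seed=6, noise=0.2), SCHEMA,
                             rf_params=FAST_RF, split=SplitSpec(seed=6)).fit()
            docs.append(json.dumps(res.metrics_dict(), sort_keys=True))
        assert docs[0] == docs[1]

    def test_summary_mentions_stages_and_metrics(self):
        res = TwoStageRF(toy_table(150, seed=7), SCHEMA, rf_params=FAST_RF,
                         split=SplitSpec(seed=7)).fit()
        text = res.summary()
        for token in ("stage1", "stage2", "final", "Stage 1", "Stage 2"):
            assert token in text


class TestPredictMap:
    def test_layers_and_identities(self, default_study, default_fit):
        s = default_study
        comps = ws.composite_by_quarter(ws.sar_to_linear(s.scenes))
        comp = comps[QuarterKey(2021, 2)]
        pm = default_fit.pooled.predict_map(comp, s.wetlands, climate=s.climate)
        fin, base, corr = (pm.final_raw.values, pm.baseline.values,
                           pm.correction.values)
        valid = pm.final.valid
        assert valid.any()
        np.testing.assert_allclose(fin[valid], (base + corr)[valid], atol=1e-9)
        # baseline constant within each wetland
        import shapely
        g = comp.grid
        xs = g.origin_x + (np.arange(g.n_cols) + 0.5) * g.pixel_size
        ys = g.origin_y - (np.arange(g.n_rows) + 0.5) * g.pixel_size
        xx, yy = np.meshgrid(xs, ys)
        for w in s.wetlands:
            inside = shapely.contains_xy(w.polygon, xx, yy) & valid
            vals = np.unique(base[inside])
            assert len(vals) == 1
        # outside every polygon: nodata in all layers
        outside = ~valid
        assert outside.any()
        for layer in (pm.baseline, pm.correction, pm.final):
            assert np.isnan(layer.values[outside]).all()

    def test_missing_band_raises_with_name(self, default_study, default_fit):
        s = default_study
        comps = ws.composite_by_quarter(ws.sar_to_linear(s.scenes))
        comp = comps[QuarterKey(2021, 2)]
        broken = ws.QuarterComposite(
            key=comp.key,
            bands={k: v for k, v in comp.bands.items() if k != "SRVI"},
            n_scenes=comp.n_scenes)
        with pytest.raises(KeyError, match="SRVI"):
            default_fit.pooled.predict_map(broken, s.wetlands)


class TestImportanceHeatmap:
    @staticmethod
    def _stage(importances, stage=1):
        return StageModel(model_handle=None, feature_names=list(importances),
                          importances=importances, stage=stage)

    def test_single_model_per_quarter_is_identity(self):
        models = [(QuarterKey(2021, q), self._stage({"A": 0.6, "B": 0.4}))
                  for q in (1, 2, 3, 4)]
        hm = importance_heatmap(models, stage=1)
        assert hm.table.loc["A"].tolist() == [0.6] * 4
        assert hm.provenance["Q1"] == [2021]

    def test_two_years_average(self):
        models = [(QuarterKey(2021, 1), self._stage({"A": 0.2})),
                  (QuarterKey(2022, 1), self._stage({"A": 0.4}))]
        hm = importance_heatmap(models, stage=1)
        assert hm.table.loc["A", "Q1"] == pytest.approx(0.3)
        assert hm.provenance["Q1"] == [2021, 2022]

    def test_feature_missing_from_one_model_flagged(self):
        models = [(QuarterKey(2021, 1), self._stage({"A": 0.2, "B": 0.8})),
                  (QuarterKey(2022, 1), self._stage({"A": 0.4}))]
        hm = importance_heatmap(models, stage=1)
        assert hm.table.loc["B", "Q1"] == pytest.approx(0.8)
        assert ("B", "Q1") in hm.partial_cells

    def test_wrong_stage_rejected(self):
        with pytest.raises(ValueError):
            importance_heatmap([(QuarterKey(2021, 1), self._stage({"A": 1.0}))],
                               stage=2)

    def test_tie_break_is_lexicographic(self):
        sm = self._stage({"B": 0.5, "A": 0.5})
        assert [n for n, _ in sm.ranked_features()] == ["A", "B"]


class TestScoping:
    def test_small_groups_fall_back_to_pooled(self, default_study, default_fit):
        # 324 samples over 16 (year, quarter) groups -> ~14 training rows
        # per group, below the 20-row floor, so the scope falls back
        assert set(default_fit.fits) == {"pooled"}
        assert "Q1" in default_fit.pooled.stage1.feature_names

    def test_per_quarter_scope_when_counts_allow(self):
        table = toy_table(400, seed=8, noise=0.2)
        table["year"] = 2021
        table["nutrient"] = "N"
        fits = ws.fit_scoped(table, SCHEMA, scope="per_quarter",
                             min_train_rows=20, rf_params=FAST_RF,
                             split=SplitSpec(seed=8))
        assert all(isinstance(k, QuarterKey) for k in fits)
        assert len(fits) == 4
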