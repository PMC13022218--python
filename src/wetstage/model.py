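"""Two-stage hybrid random-forest model for wetland nutrient mapping.

The estimator decomposes a nutrient concentration field additively:

    y = f1(discrete site attributes) + f2(continuous satellite predictors) + eps

Stage 1 fits a random-forest regression of concentration on discrete,
per-wetland attributes (morphometrics, land-use composition, 7-day
climate means), giving a baseline that is constant within a wetland for
a given quarter. Stage 2 fits a second, independent random forest to the
stage-1 residuals (observed - baseline) using per-pixel predictors from
the quarterly satellite composites, supplying a spatial correction. The
final prediction is the elementwise sum y_hat = y1_hat + r_hat, clipped
at zero by default since concentrations are nonnegative.

The API follows the model/results convention: build a
:class:`TwoStageRF` from a feature table, call :meth:`TwoStageRF.fit`,
and read estimates, importances, hold-out metrics and ``summary()`` off
the returned :class:`TwoStageRFResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .composite import FeatureSchema, QuarterComposite, QuarterKey, trailing_climate_means
from .geoio import LANDUSE_CLASSES, WetlandUnit
from .grid import RasterBand
from .metrics import MetricsReport, evaluate

QUARTER_DUMMIES = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class SplitSpec:
    """Random 70/30 train/test partition specification."""

    train_fraction: float = 0.70
    seed: int = 0
    strata: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters shared by both stages.

    Defaults follow the regression convention: 500 trees, mtry = floor(p/3)
    candidate features per split, unlimited depth, minimum leaf size 1.
    ``importance`` selects impurity-based (normalized to sum 1) or
    permutation importances.
    """

    n_estimators: int = 500
    max_features: int | None = None  # None -> floor(p/3), at least 1
    max_depth: int | None = None
    min_samples_leaf: int = 1
    importance: str = "impurity"

    def resolve_max_features(self, p: int) -> int:
        if self.max_features is not None:
            return max(1, min(self.max_features, p))
        return max(1, p // 3)


@dataclass
class StageModel:
    """A fitted single-stage regressor with its importance scores."""

    model_handle: RandomForestRegressor
    feature_names: list[str]
    importances: dict[str, float]
    stage: int

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.feature_names].to_numpy(dtype=float)
        return self.model_handle.predict(X)

    def ranked_features(self) -> list[tuple[str, float]]:
        """Features by descending importance; ties broken lexicographically."""
        return sorted(self.importances.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class PredictionMap:
    """Per-pixel prediction layers for one quarter.

    ``final`` = ``baseline`` + ``correction`` pixelwise (before any
    clipping); ``final_raw`` retains unclipped values as a diagnostic.
    """

    key: QuarterKey
    baseline: RasterBand
    correction: RasterBand
    final: RasterBand
    final_raw: RasterBand

    def write(self, path) -> None:
        from .geoio import write_bands
        start, _ = self.key.date_range()
        write_bands(path, [self.baseline, self.correction, self.final],
                    sensor="prediction", date=start)


@dataclass
class ImportanceHeatmap:
    """Feature x quarter importance matrix averaged over years."""

    table: pd.DataFrame                       # rows: features, cols: Q1..Q4
    stage: int
    provenance: dict[str, list[int]]          # quarter label -> contributing years
    partial_cells: list[tuple[str, str]] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


# ---------------------------------------------------------------------------
# Partitioning


def split_train_test(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive random partition with |train| = round(f·n).

    With a ``strata`` column name, the split is performed independently
    inside each stratum (counts rounded per stratum).
    """
    if table.empty:
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(spec.seed)
    if spec.strata is not None:
        parts_train, parts_test = [], []
        for _, grp in table.groupby(spec.strata, sort=True):
            perm = rng.permutation(len(grp))
            k = int(round(spec.train_fraction * len(grp)))
            parts_train.append(grp.iloc[perm[:k]])
            parts_test.append(grp.iloc[perm[k:]])
        return pd.concat(parts_train), pd.concat(parts_test)
    perm = rng.permutation(len(table))
    k = int(round(spec.train_fraction * len(table)))
    return table.iloc[perm[:k]], table.iloc[perm[k:]]


# ---------------------------------------------------------------------------
# Stage fitting primitives


def _fit_rf(X: np.ndarray, y: np.ndarray, params: RFParams, seed: int,
            oob: bool) -> RandomForestRegressor:
    rf = RandomForestRegressor(
        n_estimators=params.n_estimators,
        max_features=params.resolve_max_features(X.shape[1]),
        max_depth=params.max_depth,
        min_samples_leaf=params.min_samples_leaf,
        oob_score=oob,
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def _importances(rf: RandomForestRegressor, X: np.ndarray, y: np.ndarray,
                 names: list[str], params: RFParams, seed: int) -> dict[str, float]:
    if params.importance == "permutation":
        pi = permutation_importance(rf, X, y, n_repeats=5,
                                    random_state=int(seed) % (2**31), n_jobs=1)
        scores = np.maximum(pi.importances_mean, 0.0)
    else:
        scores = rf.feature_importances_
    total = scores.sum()
    if total > 0:
        scores = scores / total
    return dict(zip(names, (float(s) for s in scores)))


def fit_stage1(train: pd.DataFrame, discrete_features: list[str],
               target: str = "concentration", rf_params: RFParams | None = None,
               seed: int = 0, residual_source: str = "oob"
               ) -> tuple[StageModel, np.ndarray]:
    """Fit the baseline forest and return it with training residuals.

    Residuals are observed minus stage-1 prediction on the training
    partition. ``residual_source`` = "oob" (default) uses out-of-bag
    predictions, which avoids the near-zero residuals an in-sample forest
    fit produces; "insample" uses the fitted prediction directly.
    """
    if rf_params is None:
        rf_params = RFParams()
    if not discrete_features:
        raise ValueError("stage 1 requires at least one discrete feature")
    if len(train) < 2:
        raise ValueError("stage 1 needs at least two training rows")
    if residual_source not in ("oob", "insample"):
        raise ValueError("residual_source must be 'oob' or 'insample'")
    X = train[discrete_features].to_numpy(dtype=float)
    y = train[target].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("stage-1 target is constant; the fit is degenerate")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        rf = _fit_rf(X, y, rf_params, seed, oob=residual_source == "oob")
    if residual_source == "oob":
        pred = np.asarray(rf.oob_prediction_, dtype=float)
        bad = ~np.isfinite(pred)
        if bad.any():  # rows never left out of bag: fall back to in-sample
            pred[bad] = rf.predict(X[bad])
    else:
        pred = rf.predict(X)
    model = StageModel(
        model_handle=rf, feature_names=list(discrete_features),
        importances=_importances(rf, X, y, list(discrete_features), rf_params, seed),
        stage=1,
    )
    return model, y - pred


def fit_stage2(train: pd.DataFrame, continuous_features: list[str],
               residuals: np.ndarray, rf_params: RFParams | None = None,
               seed: int = 0) -> StageModel:
    """Fit the residual-correction forest on continuous predictors."""
    if rf_params is None:
        rf_params = RFParams()
    if not continuous_features:
        raise ValueError("stage 2 requires at least one continuous feature")
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) != len(train):
        raise ValueError("residuals must align with the training rows")
    X = train[continuous_features].to_numpy(dtype=float)
    rf = _fit_rf(X, residuals, rf_params, seed + 1, oob=False)
    return StageModel(
        model_handle=rf, feature_names=list(continuous_features),
        importances=_importances(rf, X, residuals, list(continuous_features),
                                 rf_params, seed + 1),
        stage=2,
    )


# ---------------------------------------------------------------------------
# The model / results pair


class TwoStageRF:
    """Two-stage hybrid random-forest model built from a feature table.

    Parameters
    ----------
    table : DataFrame
        Feature table from :func:`wetstage.composite.build_feature_table`
        (one row per sample; ``concentration`` target, ``flagged`` marks
        rows with missing continuous features).
    schema : FeatureSchema
        Ordering of the discrete and continuous feature blocks.
    nutrient : str, optional
        Restrict to rows of one nutrient ("N" or "P").
    add_quarter_dummies : bool
        Append Q1..Q4 one-hot columns to the discrete block (used by the
        pooled model scope so seasonality is learnable in stage 1).
    clip_negative : bool
        Clip negative final concentrations to zero (raw values retained).
    """

    def __init__(self, table: pd.DataFrame, schema: FeatureSchema,
                 nutrient: str | None = None,
                 rf_params: RFParams | None = None,
                 split: SplitSpec | None = None,
                 residual_source: str = "oob",
                 add_quarter_dummies: bool = False,
                 clip_negative: bool = True):
        if nutrient is not None:
            table = table[table["nutrient"] == nutrient]
        if table.empty:
            raise ValueError("feature table has no rows for this model")
        table = table.reset_index(drop=True)
        self.schema = schema
        self.nutrient = nutrient
        self.rf_params = rf_params or RFParams()
        self.split = split or SplitSpec()
        self.residual_source = residual_source
        self.add_quarter_dummies = add_quarter_dummies
        self.clip_negative = clip_negative
        self.discrete_features = list(schema.discrete)
        if add_quarter_dummies:
            table = table.copy()
            for q in (1, 2, 3, 4):
                table[f"Q{q}"] = (table["quarter"] == q).astype(float)
            self.discrete_features += list(QUARTER_DUMMIES)
        self.continuous_features = list(schema.continuous)
        self.table = table

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, discrete: list[str],
                       continuous: list[str], **kwargs) -> "TwoStageRF":
        return cls(table, FeatureSchema(discrete=discrete, continuous=continuous),
                   **kwargs)

    def fit(self, holdout: bool = True) -> "TwoStageRFResults":
        """Fit both stages; with ``holdout`` (default) also evaluate on the
        30% test partition. ``holdout=False`` trains on every row (used for
        per-quarter importance models where no validation is wanted)."""
        if holdout:
            train, test = split_train_test(self.table, self.split)
            if len(train) < 2:
                raise ValueError("training partition has fewer than two rows")
        else:
            train, test = self.table, self.table.iloc[0:0]

        stage1, residuals = fit_stage1(
            train, self.discrete_features, rf_params=self.rf_params,
            seed=self.split.seed, residual_source=self.residual_source)

        ok = ~train["flagged"].to_numpy(dtype=bool)
        stage2 = fit_stage2(
            train.loc[ok], self.continuous_features, residuals[ok],
            rf_params=self.rf_params, seed=self.split.seed)

        res = TwoStageRFResults(model=self, stage1=stage1, stage2=stage2,
                                train=train, test=test)
        if holdout and len(test):
            res._evaluate_holdout()
        return res


class TwoStageRFResults:
    """Fitted two-stage model: predictions, metrics, importances, maps."""

    def __init__(self, model: TwoStageRF, stage1: StageModel, stage2: StageModel,
                 train: pd.DataFrame, test: pd.DataFrame):
        self.model = model
        self.stage1 = stage1
        self.stage2 = stage2
        self.train = train
        self.test = test
        self.metrics: dict[str, MetricsReport] = {}

    # -- point prediction ---------------------------------------------------

    def predict(self, table: pd.DataFrame) -> pd.DataFrame:
        """Predict concentrations for feature rows.

        Returns a frame with ``baseline`` (stage 1), ``correction``
        (stage 2, NaN on flagged rows), ``final_raw`` = baseline +
        correction (baseline alone on flagged rows, noted in
        ``baseline_only``) and ``final`` (clipped at 0 when configured).
        """
        if self.model.add_quarter_dummies and "Q1" not in table.columns:
            table = table.copy()
            for q in (1, 2, 3, 4):
                table[f"Q{q}"] = (table["quarter"] == q).astype(float)
        y1 = self.stage1.predict(table)
        flagged = table["flagged"].to_numpy(dtype=bool) if "flagged" in table \
            else np.zeros(len(table), dtype=bool)
        r = np.full(len(table), np.nan)
        if (~flagged).any():
            r[~flagged] = self.stage2.predict(table.loc[~flagged])
        final_raw = np.where(flagged, y1, y1 + np.nan_to_num(r))
        final = final_raw.copy()
        if self.model.clip_negative:
            neg = final < 0
            if neg.any():
                warnings.warn(f"clipped {int(neg.sum())} negative prediction(s) to 0")
                final[neg] = 0.0
        return pd.DataFrame({
            "baseline": y1, "correction": r, "final_raw": final_raw,
            "final": final, "baseline_only": flagged,
        }, index=table.index)

    # -- hold-out metrics ---------------------------------------------------

    def _evaluate_holdout(self) -> None:
        test = self.test
        pred = self.predict(test)
        y = test["concentration"].to_numpy(dtype=float)
        self.metrics["stage1"] = evaluate(pred["baseline"], y)
        ok = ~pred["baseline_only"].to_numpy(dtype=bool)
        if ok.any():
            realized = y[ok] - pred.loc[ok, "baseline"].to_numpy()
            self.metrics["stage2"] = evaluate(pred.loc[ok, "correction"], realized)
        self.metrics["final"] = evaluate(pred["final"], y)

    # -- map prediction -----------------------------------------------------

    def predict_map(self, composite: QuarterComposite,
                    wetlands: list[WetlandUnit],
                    climate: pd.DataFrame | None = None) -> PredictionMap:
        """Per-pixel prediction map for one quarterly composite.

        The baseline layer is constant within each wetland polygon (a
        single stage-1 prediction per wetland); the correction layer is
        the stage-2 prediction on each pixel's composite features; the
        final layer is their pixelwise sum. Pixels outside every polygon
        are nodata. Missing composite bands required by stage 2 raise a
        ``KeyError`` naming them.
        """
        grid = composite.grid
        missing = [n for n in self.stage2.feature_names if n not in composite.bands]
        if missing:
            raise KeyError(f"composite lacks bands required by stage 2: {missing}")

        cols = np.arange(grid.n_cols) * grid.pixel_size + grid.pixel_size / 2
        rows = np.arange(grid.n_rows) * grid.pixel_size + grid.pixel_size / 2
        px = grid.origin_x + cols
        py = grid.origin_y - rows
        xx, yy = np.meshgrid(px, py)

        baseline = np.full(grid.shape, np.nan)
        q_start, q_end = composite.key.date_range()
        for w in wetlands:
            inside = shapely.contains_xy(w.polygon, xx, yy)
            if not inside.any():
                continue
            rain, temp = w.ave_rain, w.ave_temp
            if climate is not None:
                # quarter-mean climate, over whatever days the series covers
                sub = climate[(climate["wetland_id"] == w.wetland_id)
                              & (climate["date"] >= pd.Timestamp(q_start))
                              & (climate["date"] < pd.Timestamp(q_end))]
                if not sub.empty:
                    rain = float(sub["rain_mm"].mean())
                    temp = float(sub["temp_F"].mean())
            feats = {
                "Area": w.area, "Perimeter": w.perimeter,
                "SCI": w.perimeter / w.area,
                "PPS": 4.0 * np.pi * w.area / w.perimeter**2,
                "AveRain": rain, "AveTemp": temp,
            }
            for cls in LANDUSE_CLASSES:
                feats[cls] = w.landuse_pct.get(cls, 0.0)
            for q in (1, 2, 3, 4):
                feats[f"Q{q}"] = float(composite.key.quarter == q)
            row = pd.DataFrame([feats])
            baseline[inside] = float(self.stage1.predict(row)[0])

        in_any = np.isfinite(baseline)
        feat_ok = np.ones(grid.shape, dtype=bool)
        for n in self.stage2.feature_names:
            feat_ok &= composite.bands[n].valid
        valid = in_any & feat_ok

        correction = np.full(grid.shape, np.nan)
        if valid.any():
            X = np.column_stack([composite.bands[n].values[valid]
                                 for n in self.stage2.feature_names])
            correction[valid] = self.stage2.model_handle.predict(X)

        final_raw = baseline + correction
        final = final_raw.copy()
        if self.model.clip_negative:
            final[np.isfinite(final) & (final < 0)] = 0.0

        mk = lambda name, vals: RasterBand(grid=grid, name=name, values=vals,
                                           units="mg_per_L")
        return PredictionMap(
            key=composite.key,
            baseline=mk("baseline", np.where(valid, baseline, np.nan)),
            correction=mk("correction", correction),
            final=mk("final", np.where(valid, final, np.nan)),
            final_raw=mk("final_raw", np.where(valid, final_raw, np.nan)),
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = []
        nut = self.model.nutrient or "all"
        lines.append("Two-stage hybrid random-forest regression")
        lines.append("=" * 58)
        lines.append(f"Nutrient: {nut:>4}    train rows: {len(self.train):>5}"
                     f"    test rows: {len(self.test):>5}")
        p = self.model.rf_params
        lines.append(f"Trees: {p.n_estimators}   mtry: floor(p/3)"
                     f"   residuals: {self.model.residual_source}")
        if self.metrics:
            lines.append("-" * 58)
            lines.append(f"{'':10}{'r2':>10}{'RMSE':>12}{'MAE':>12}{'MBE':>12}")
            for name in ("stage1", "stage2", "final"):
                if name in self.metrics:
                    m = self.metrics[name]
                    lines.append(f"{name:10}{m.r2:>10.3f}{m.rmse:>12.4f}"
                                 f"{m.mae:>12.4f}{m.mbe:>12.4f}")
        for sm in (self.stage1, self.stage2):
            lines.append("-" * 58)
            lines.append(f"Stage {sm.stage} top importances:")
            for name, score in sm.ranked_features()[:5]:
                lines.append(f"  {name:10} {score:8.4f}")
        return "\n".join(lines)

    def metrics_dict(self) -> dict:
        return {k: v.to_dict() for k, v in self.metrics.items()}


# ---------------------------------------------------------------------------
# Model scope orchestration and importance heatmaps


def fit_scoped(table: pd.DataFrame, schema: FeatureSchema,
               nutrient: str | None = None, scope: str = "per_quarter",
               min_train_rows: int = 20, **kwargs
               ) -> dict[QuarterKey | str, TwoStageRFResults]:
    """Fit per-(year, quarter) models when sample counts permit, else pool.

    ``scope`` = "per_quarter" fits one model per (year, quarter) group if
    every group yields at least ``min_train_rows`` training rows after
    the 70/30 split; otherwise (or with scope="pooled") a single pooled
    model with quarter one-hot features is fitted under the key
    ``"pooled"``.
    """
    sub = table if nutrient is None else table[table["nutrient"] == nutrient]
    if sub.empty:
        raise ValueError("no rows for the requested nutrient")
    if scope not in ("per_quarter", "pooled"):
        raise ValueError("scope must be 'per_quarter' or 'pooled'")
    split = kwargs.get("split") or SplitSpec()
    if scope == "per_quarter":
        groups = sub.groupby(["year", "quarter"])
        feasible = all(
            int(round(split.train_fraction * len(g))) >= min_train_rows
            for _, g in groups)
        if feasible:
            out: dict[QuarterKey | str, TwoStageRFResults] = {}
            for (year, q), grp in groups:
                model = TwoStageRF(grp, schema, nutrient=nutrient, **kwargs)
                out[QuarterKey(int(year), int(q))] = model.fit()
            return out
    model = TwoStageRF(sub, schema, nutrient=nutrient,
                       add_quarter_dummies=True, **kwargs)
    return {"pooled": model.fit()}


def fit_quarterly_importance(table: pd.DataFrame, schema: FeatureSchema,
                             nutrient: str | None = None,
                             **kwargs) -> list[tuple[QuarterKey, TwoStageRFResults]]:
    """Fit one model per (year, quarter) on all rows of that group.

    These fits exist to supply the per-quarter importance profiles that
    the seasonal heatmaps average over years; no hold-out evaluation is
    performed (groups are small).
    """
    sub = table if nutrient is None else table[table["nutrient"] == nutrient]
    out = []
    for (year, q), grp in sub.groupby(["year", "quarter"]):
        model = TwoStageRF(grp, schema, nutrient=nutrient, **kwargs)
        out.append((QuarterKey(int(year), int(q)), model.fit(holdout=False)))
    return out


def importance_heatmap(models: list[tuple[QuarterKey, StageModel]],
                       stage: int) -> ImportanceHeatmap:
    """Average per-quarter importances over years into a feature x Q matrix.

    cell(f, Qk) is the mean importance of feature f over the year-models
    of quarter k that contain f; year-models missing a feature are
    excluded from that cell's mean and flagged in ``partial_cells``.
    """
    models = [(k, m) for k, m in models if m.stage == stage]
    if not models:
        raise ValueError(f"no stage-{stage} models supplied")
    quarters = sorted({k.quarter for k, _ in models})
    features: list[str] = []
    for _, m in models:
        for f in m.feature_names:
            if f not in features:
                features.append(f)
    cols = [f"Q{q}" for q in quarters]
    data = pd.DataFrame(np.nan, index=features, columns=cols)
    provenance: dict[str, list[int]] = {c: [] for c in cols}
    partial: list[tuple[str, str]] = []
    for q in quarters:
        col = f"Q{q}"
        group = [(k, m) for k, m in models if k.quarter == q]
        provenance[col] = sorted({k.year for k, _ in group})
        for f in features:
            vals = [m.importances[f] for _, m in group if f in m.importances]
            if not vals:
                continue
            if len(vals) < len(group):
                partial.append((f, col))
            data.loc[f, col] = float(np.mean(vals))
    return ImportanceHeatmap(table=data, stage=stage, provenance=provenance,
                             partial_cells=partial)


def plot_importance_heatmap(hm: ImportanceHeatmap, path) -> None:
    """Render the importance matrix as a PNG heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 0.3 * len(hm.table) + 1.5))
    im = ax.imshow(hm.table.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(hm.table.columns)), hm.table.columns)
    ax.set_yticks(range(len(hm.table)), hm.table.index, fontsize=7)
    ax.set_title(f"Stage {hm.stage} importance (year-averaged)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
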