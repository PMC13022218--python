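"""End-to-end orchestration: scenes -> composites -> features -> model.

This is the programmatic counterpart of the command-line ``run``
subcommand; the CLI is a thin wrapper over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .composite import (FeatureSchema, QuarterComposite, QuarterKey,
                        build_feature_table, composite_by_quarter, default_schema)
from .geoio import SampleRecord, WetlandUnit
from .grid import SceneStack
from .indices import db_to_linear
from .model import (RFParams, SplitSpec, TwoStageRF, TwoStageRFResults,
                    fit_quarterly_importance, fit_scoped, importance_heatmap)


def sar_to_linear(scenes: list[SceneStack]) -> list[SceneStack]:
    """Convert every dB band of the SAR stacks to linear power."""
    out = []
    for s in scenes:
        if s.sensor != "S1":
            out.append(s)
            continue
        bands = {n: (db_to_linear(b) if b.units == "dB" else b)
                 for n, b in s.bands.items()}
        out.append(SceneStack(date=s.date, bands=bands, sensor=s.sensor))
    return out


@dataclass
class PipelineResult:
    """Everything one nutrient run produces."""

    composites: dict[QuarterKey, QuarterComposite]
    features: pd.DataFrame
    schema: FeatureSchema
    fits: dict = field(default_factory=dict)          # scope key -> results
    importance_models: list = field(default_factory=list)

    @property
    def pooled(self) -> TwoStageRFResults:
        if "pooled" in self.fits:
            return self.fits["pooled"]
        raise KeyError("run used per-quarter scope; no pooled fit")


def run_pipeline(
    scenes: list[SceneStack],
    wetlands: list[WetlandUnit],
    samples: list[SampleRecord],
    climate: pd.DataFrame | None = None,
    nutrient: str | None = None,
    seed: int = 0,
    rf_params: RFParams | None = None,
    scope: str = "per_quarter",
    residual_source: str = "oob",
    srvi_numerator: str = "vv",
    clip_negative: bool = True,
    quarters: set[int] | None = None,
    with_importance: bool = True,
) -> PipelineResult:
    """Composite, assemble features, fit the two-stage model, evaluate.

    ``quarters`` restricts the run to a subset of calendar quarters.
    ``scope`` follows :func:`wetstage.model.fit_scoped`: per-(year,
    quarter) models where counts permit, otherwise one pooled model with
    quarter one-hot features.
    """
    scenes = sar_to_linear(scenes)
    composites = composite_by_quarter(scenes, srvi_numerator=srvi_numerator)
    if quarters is not None:
        composites = {k: c for k, c in composites.items() if k.quarter in quarters}
        samples = [s for s in samples
                   if (s.date.month - 1) // 3 + 1 in quarters]
    features, schema = build_feature_table(
        samples, composites, {w.wetland_id: w for w in wetlands},
        climate=climate, schema=default_schema())
    split = SplitSpec(seed=seed)
    fits = fit_scoped(features, schema, nutrient=nutrient, scope=scope,
                      split=split, rf_params=rf_params,
                      residual_source=residual_source,
                      clip_negative=clip_negative)
    result = PipelineResult(composites=composites, features=features,
                            schema=schema, fits=fits)
    if with_importance:
        result.importance_models = fit_quarterly_importance(
            features, schema, nutrient=nutrient, split=split,
            rf_params=rf_params, residual_source=residual_source)
    return result


def heatmaps(result: PipelineResult):
    """Stage-1 and stage-2 seasonal importance heatmaps for a run."""
    s1 = importance_heatmap(
        [(k, r.stage1) for k, r in result.importance_models], stage=1)
    s2 = importance_heatmap(
        [(k, r.stage2) for k, r in result.importance_models], stage=2)
    return s1, s2
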