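"""Quarterly temporal compositing and per-sample feature assembly.

Field samples are matched to the mean environmental state of their
calendar quarter: every optical and SAR scene acquired inside the
quarter is averaged per pixel (ignoring nodata), derived indices are
computed from the composited bands, and each sample's continuous
features are read off the composite at the sample's coordinates. The
discrete block (morphometrics, land-use percentages, 7-day climate
means) comes from the sample's wetland and date.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indices as _ix
from .geoio import LANDUSE_CLASSES, LinkageError, SampleRecord, WetlandUnit, point_sample
from .grid import GridSpec, RasterBand, SceneStack

#: default Sentinel-2 band subset used as continuous predictors
DEFAULT_S2_BANDS = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")

SPECTRAL_INDEX_NAMES = ("NDVI", "NDWI", "EVI")
SAR_FEATURE_NAMES = ("VV", "VH", "VV_VH", "VH_VV", "SRVI")

DISCRETE_BASE = ("Area", "Perimeter", "SCI", "PPS", "AveRain", "AveTemp")


@dataclass(frozen=True, order=True)
class QuarterKey:
    """A calendar quarter: Q1 = Jan 1 – Mar 31, ..., Q4 = Oct 1 – Dec 31."""

    year: int
    quarter: int

    def __post_init__(self) -> None:
        if self.quarter not in (1, 2, 3, 4):
            raise ValueError("quarter must be 1..4")

    @property
    def label(self) -> str:
        return f"{self.year}-Q{self.quarter}"

    def date_range(self) -> tuple[_dt.date, _dt.date]:
        """Half-open [start, end) date range of the quarter."""
        start = _dt.date(self.year, 3 * (self.quarter - 1) + 1, 1)
        if self.quarter == 4:
            end = _dt.date(self.year + 1, 1, 1)
        else:
            end = _dt.date(self.year, 3 * self.quarter + 1, 1)
        return start, end

    def contains(self, date: _dt.date) -> bool:
        start, end = self.date_range()
        return start <= date < end


def assign_quarter(date: _dt.date) -> QuarterKey:
    """Map a calendar date to its QuarterKey."""
    return QuarterKey(year=date.year, quarter=(date.month - 1) // 3 + 1)


@dataclass
class QuarterComposite:
    """Per-quarter, per-pixel mean of scene bands plus derived indices."""

    key: QuarterKey
    bands: dict[str, RasterBand]
    n_scenes: dict[str, int] = field(default_factory=dict)

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.bands.values())).grid

    def __getitem__(self, name: str) -> RasterBand:
        return self.bands[name]


@dataclass
class FeatureSchema:
    """Recorded ordering of the discrete and continuous feature blocks."""

    discrete: list[str]
    continuous: list[str]

    @property
    def all_features(self) -> list[str]:
        return list(self.discrete) + list(self.continuous)

    def to_dict(self) -> dict:
        return {"discrete": list(self.discrete), "continuous": list(self.continuous)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(discrete=list(d["discrete"]), continuous=list(d["continuous"]))


def _masked_mean(bands: list[RasterBand], grid: GridSpec, name: str,
                 units: str) -> RasterBand:
    """Pixelwise mean ignoring nodata; nodata where no scene contributes."""
    acc = np.zeros(grid.shape)
    cnt = np.zeros(grid.shape, dtype=int)
    for b in bands:
        v = b.valid
        acc[v] += b.values[v]
        cnt[v] += 1
    vals = np.full(grid.shape, np.nan)
    np.divide(acc, cnt, out=vals, where=cnt > 0)
    return RasterBand(grid=grid, name=name, values=vals,
                      nodata_mask=cnt == 0, units=units)


def quarterly_composite(scenes: list[SceneStack], key: QuarterKey,
                        srvi_numerator: str = "vv") -> QuarterComposite:
    """Mean-composite all scenes falling in a quarter and derive indices.

    Optical ("S2") and SAR ("S1") stacks are composited independently,
    band by band; NDVI/NDWI/EVI and the SAR ratios are then computed from
    the composited bands (mean-then-index). SAR bands must already be in
    linear power. Raises ``ValueError`` if no scene falls in the quarter.
    """
    in_q = [s for s in scenes if key.contains(s.date)]
    if not in_q:
        raise ValueError(f"no scenes fall inside quarter {key.label}")
    grids = {s.grid for s in in_q}
    if len(grids) != 1:
        raise _ix.AlignmentError("scenes are on different grids; resample first")
    grid = in_q[0].grid

    by_sensor: dict[str, list[SceneStack]] = {}
    for s in in_q:
        by_sensor.setdefault(s.sensor, []).append(s)

    bands: dict[str, RasterBand] = {}
    n_scenes: dict[str, int] = {}
    for sensor, group in by_sensor.items():
        n_scenes[sensor] = len(group)
        names: list[str] = []
        for s in group:
            for n in s.band_names:
                if n not in names:
                    names.append(n)
        for n in names:
            contrib = [s.bands[n] for s in group if n in s.bands]
            bands[n] = _masked_mean(contrib, grid, n, contrib[0].units)

    # indices from composited bands
    if {"B8", "B4"} <= bands.keys():
        bands["NDVI"] = _ix.ndvi(bands["B8"], bands["B4"])
    if {"B3", "B8"} <= bands.keys():
        bands["NDWI"] = _ix.ndwi(bands["B3"], bands["B8"])
    if {"B8", "B4", "B2"} <= bands.keys():
        bands["EVI"] = _ix.evi(bands["B8"], bands["B4"], bands["B2"])
    if {"VV", "VH"} <= bands.keys():
        sar = _ix.sar_indices(bands["VV"], bands["VH"], srvi_numerator=srvi_numerator)
        bands["VV_VH"] = sar.vv_vh_ratio
        bands["VH_VV"] = sar.cross_ratio
        bands["SRVI"] = sar.srvi
    return QuarterComposite(key=key, bands=bands, n_scenes=n_scenes)


def composite_by_quarter(scenes: list[SceneStack],
                         srvi_numerator: str = "vv") -> dict[QuarterKey, QuarterComposite]:
    """Group a scene series by calendar quarter and composite each group."""
    keys = sorted({assign_quarter(s.date) for s in scenes})
    return {k: quarterly_composite(scenes, k, srvi_numerator=srvi_numerator)
            for k in keys}


# ---------------------------------------------------------------------------
# Climate helpers


def trailing_climate_means(climate: pd.DataFrame, wetland_id: str,
                           date: _dt.date, window_days: int = 7) -> tuple[float, float]:
    """7-day trailing means of rain (mm) and temperature (°F) ending on date."""
    end = pd.Timestamp(date)
    start = end - pd.Timedelta(days=window_days - 1)
    sub = climate[(climate["wetland_id"] == wetland_id)
                  & (climate["date"] >= start) & (climate["date"] <= end)]
    if sub.empty:
        raise LinkageError(f"no climate records for {wetland_id} in "
                           f"[{start.date()}, {end.date()}]")
    return float(sub["rain_mm"].mean()), float(sub["temp_F"].mean())


# ---------------------------------------------------------------------------
# Feature table


def default_schema(s2_bands: tuple[str, ...] = DEFAULT_S2_BANDS,
                   landuse: tuple[str, ...] = LANDUSE_CLASSES) -> FeatureSchema:
    return FeatureSchema(
        discrete=list(DISCRETE_BASE) + list(landuse),
        continuous=list(s2_bands) + list(SPECTRAL_INDEX_NAMES) + list(SAR_FEATURE_NAMES),
    )


def build_feature_table(
    samples: list[SampleRecord],
    composites: dict[QuarterKey, QuarterComposite],
    wetlands: dict[str, WetlandUnit],
    climate: pd.DataFrame | None = None,
    schema: FeatureSchema | None = None,
) -> tuple[pd.DataFrame, FeatureSchema]:
    """One row per sample: discrete + continuous features and the target.

    Continuous features are point-sampled from the sample quarter's
    composite at the sample coordinates. Rows with any nodata continuous
    feature are flagged (``flagged`` column), never silently dropped.
    Raises :class:`LinkageError` listing every sample whose quarter has no
    composite or whose wetland id is unknown.
    """
    if schema is None:
        schema = default_schema()

    missing_q = sorted({assign_quarter(s.date).label for s in samples
                        if assign_quarter(s.date) not in composites})
    missing_w = sorted({s.wetland_id for s in samples if s.wetland_id not in wetlands})
    if missing_q or missing_w:
        raise LinkageError(
            f"unresolved links — quarters without composites: {missing_q}; "
            f"unknown wetlands: {missing_w}"
        )

    rows = []
    for i, s in enumerate(samples):
        qk = assign_quarter(s.date)
        comp = composites[qk]
        w = wetlands[s.wetland_id]
        row: dict[str, object] = {
            "sample_id": i,
            "wetland_id": s.wetland_id,
            "station": s.station,
            "date": s.date,
            "year": qk.year,
            "quarter": qk.quarter,
            "nutrient": s.nutrient,
            "concentration": s.concentration,
        }
        if climate is not None:
            rain, temp = trailing_climate_means(climate, s.wetland_id, s.date)
        else:
            rain, temp = w.ave_rain, w.ave_temp
        discrete_vals = {
            "Area": w.area, "Perimeter": w.perimeter,
            "SCI": w.perimeter / w.area,
            "PPS": 4.0 * np.pi * w.area / w.perimeter**2,
            "AveRain": rain, "AveTemp": temp,
        }
        for cls in LANDUSE_CLASSES:
            discrete_vals[cls] = w.landuse_pct.get(cls, 0.0)
        for name in schema.discrete:
            row[name] = discrete_vals.get(name, np.nan)

        flagged = False
        for name in schema.continuous:
            band = comp.bands.get(name)
            if band is None:
                val = np.nan
            else:
                try:
                    val = point_sample(band, s.x, s.y)
                except IndexError:
                    val = np.nan
            if not np.isfinite(val):
                flagged = True
            row[name] = val
        row["flagged"] = flagged
        rows.append(row)

    df = pd.DataFrame(rows)
    return df, schema
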