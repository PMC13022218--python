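"""Readers and writers for scene rasters, wetland polygons, and sample tables.

Rasters travel as multi-band TIFF files with the grid geometry, band
names, units, sensor and date serialized as JSON in the ImageDescription
tag; nodata pixels are stored as NaN. Wetland polygons use GeoJSON
FeatureCollections, sample records and daily climate use plain CSV.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, shape as _shapely_shape, mapping as _shapely_mapping

from .grid import GridSpec, RasterBand, SceneStack

#: Land-use class codes carried by every WetlandUnit (NLCD-style aggregates):
#: open water, developed area, barren land, forest, shrub/scrub, herbaceous,
#: hay/pasture, cultivated crops, woody wetlands, emergent herbaceous wetlands.
LANDUSE_CLASSES = ("OP", "DA", "BL", "FO", "SS", "HB", "HP", "CC", "WW", "EHW")

STATIONS = ("inlet", "middle", "outlet")

SAMPLES_CSV_HEADER = [
    "wetland_id", "station", "x", "y", "date", "nutrient", "concentration_mg_L",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


class LinkageError(KeyError):
    """Raised when records reference keys with no matching entity."""


@dataclass
class WetlandUnit:
    """One wetland polygon with its discrete site attributes.

    ``area`` is in km², ``perimeter`` in km; land-use percentages sum to
    100 ± 0.5. ``ave_rain`` (mm) and ``ave_temp`` (°F) are 7-day means and
    act as fallbacks when no daily climate series is supplied.
    """

    wetland_id: str
    polygon: Polygon
    area: float
    perimeter: float
    landuse_pct: dict[str, float] = field(default_factory=dict)
    ave_rain: float = 0.0
    ave_temp: float = 50.0

    def __post_init__(self) -> None:
        if self.area <= 0 or self.perimeter <= 0:
            raise ValueError("area and perimeter must be positive")
        for cls, pct in self.landuse_pct.items():
            if not (0.0 <= pct <= 100.0):
                raise ValueError(f"land-use {cls} percentage {pct} outside [0, 100]")
        total = sum(self.landuse_pct.values())
        if self.landuse_pct and abs(total - 100.0) > 0.5:
            raise ValueError(f"land-use percentages sum to {total:.2f}, not 100 ± 0.5")


@dataclass(frozen=True)
class SampleRecord:
    """A dated point water sample of one nutrient, in mg/L."""

    wetland_id: str
    station: str
    x: float
    y: float
    date: _dt.date
    nutrient: str
    concentration: float

    def __post_init__(self) -> None:
        if self.station not in STATIONS:
            raise ValueError(f"station must be one of {STATIONS}")
        if self.nutrient not in ("N", "P"):
            raise ValueError("nutrient must be 'N' or 'P'")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


# ---------------------------------------------------------------------------
# Scene raster I/O


def write_scene(path: str | Path, scene: SceneStack) -> None:
    """Write a SceneStack to a multi-band TIFF (nodata as NaN)."""
    names = scene.band_names
    data = np.stack([scene.bands[n].filled(np.nan) for n in names]).astype(np.float32)
    meta = {
        "grid": scene.grid.to_dict(),
        "bands": [{"name": n, "units": scene.bands[n].units} for n in names],
        "sensor": scene.sensor,
        "date": scene.date.isoformat(),
    }
    tifffile.imwrite(str(path), data, description=json.dumps(meta),
                     photometric="minisblack", planarconfig="separate")


def read_scene(path: str | Path, band_names: list[str] | None = None) -> SceneStack:
    """Read a scene written by :func:`write_scene`.

    If ``band_names`` is given it must match the band count in the file;
    it renames bands positionally. NaN pixels become nodata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc)
        grid = GridSpec.from_dict(meta["grid"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"{path}: missing or malformed scene metadata") from exc
    if data.ndim == 2:
        data = data[None]
    if data.shape[1:] != grid.shape:
        raise FormatError(f"{path}: raster shape {data.shape[1:]} != grid {grid.shape}")
    stored = meta["bands"]
    if len(stored) != data.shape[0]:
        raise FormatError(f"{path}: {data.shape[0]} planes but {len(stored)} band entries")
    if band_names is not None and len(band_names) != data.shape[0]:
        raise FormatError(
            f"{path}: file has {data.shape[0]} bands, {len(band_names)} names requested"
        )
    names = band_names if band_names is not None else [b["name"] for b in stored]
    bands = {
        name: RasterBand(grid=grid, name=name, values=data[i].astype(float),
                         units=stored[i]["units"])
        for i, name in enumerate(names)
    }
    return SceneStack(
        date=_dt.date.fromisoformat(meta["date"]), bands=bands, sensor=meta["sensor"]
    )


def write_bands(path: str | Path, bands: list[RasterBand], sensor: str = "derived",
                date: _dt.date | None = None) -> None:
    """Write loose bands (e.g. a composite or prediction map) as one TIFF."""
    scene = SceneStack(date=date or _dt.date(1970, 1, 1),
                       bands={b.name: b for b in bands}, sensor=sensor)
    write_scene(path, scene)


# ---------------------------------------------------------------------------
# Resampling and point extraction


def resample_to_grid(band: RasterBand, target: GridSpec,
                     method: str = "nearest") -> RasterBand:
    """Resample a band onto a target grid by nearest-neighbour or bilinear.

    Both grids must share a CRS label and overlapping extents. Output
    pixels whose sampling location falls outside the source, or on nodata
    source cells, are nodata. On an identical grid the band is returned as
    a bitwise-equal copy.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError("method must be 'nearest' or 'bilinear'")
    if band.grid.crs_label != target.crs_label:
        raise ValueError("source and target grids use different CRS labels")
    if band.grid == target:
        return band.copy(grid=target)

    sxmin, symin, sxmax, symax = band.grid.extent
    txmin, tymin, txmax, tymax = target.extent
    if txmin >= sxmax or txmax <= sxmin or tymin >= symax or tymax <= symin:
        raise ValueError("target grid extent is disjoint from the source band")

    # target pixel centers in source fractional (row, col) coordinates
    tc = np.arange(target.n_cols) * target.pixel_size + target.pixel_size / 2
    tr = np.arange(target.n_rows) * target.pixel_size + target.pixel_size / 2
    xs = target.origin_x + tc
    ys = target.origin_y - tr
    fcol = (xs - band.grid.origin_x) / band.grid.pixel_size - 0.5
    frow = (band.grid.origin_y - ys) / band.grid.pixel_size - 0.5
    fcol2d, frow2d = np.meshgrid(fcol, frow)

    src = band.filled(np.nan)
    nr, nc = band.grid.shape
    if method == "nearest":
        rr = np.rint(frow2d).astype(int)
        cc = np.rint(fcol2d).astype(int)
        inside = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
        out = np.full(target.shape, np.nan)
        out[inside] = src[rr[inside], cc[inside]]
    else:
        r0 = np.clip(np.floor(frow2d).astype(int), 0, nr - 1)
        c0 = np.clip(np.floor(fcol2d).astype(int), 0, nc - 1)
        r1 = np.clip(r0 + 1, 0, nr - 1)
        c1 = np.clip(c0 + 1, 0, nc - 1)
        wr = np.clip(frow2d - r0, 0.0, 1.0)
        wc = np.clip(fcol2d - c0, 0.0, 1.0)
        out = (
            src[r0, c0] * (1 - wr) * (1 - wc)
            + src[r0, c1] * (1 - wr) * wc
            + src[r1, c0] * wr * (1 - wc)
            + src[r1, c1] * wr * wc
        )
        center_inside = (frow2d >= -0.5) & (frow2d <= nr - 0.5) & \
                        (fcol2d >= -0.5) & (fcol2d <= nc - 0.5)
        out[~center_inside] = np.nan
    return RasterBand(grid=target, name=band.name, values=out, units=band.units)


def point_sample(band: RasterBand, x: float, y: float) -> float:
    """Value of the pixel whose cell contains (x, y); NaN on nodata.

    Cells are half-open ([x0, x0+ps) by (y0-ps, y0]); points outside the
    grid extent raise ``IndexError``.
    """
    row, col = band.grid.cell_of(x, y)
    if band.nodata_mask[row, col]:
        return float("nan")
    return float(band.values[row, col])


# ---------------------------------------------------------------------------
# Wetland GeoJSON


def write_wetlands(path: str | Path, wetlands: list[WetlandUnit],
                   crs_label: str = "local") -> None:
    features = []
    for w in wetlands:
        props = {
            "wetland_id": w.wetland_id,
            "area_km2": w.area,
            "perimeter_km": w.perimeter,
            "ave_rain_mm": w.ave_rain,
            "ave_temp_F": w.ave_temp,
            "landuse_pct": w.landuse_pct,
        }
        features.append({
            "type": "Feature",
            "geometry": _shapely_mapping(w.polygon),
            "properties": props,
        })
    doc = {"type": "FeatureCollection", "crs_label": crs_label, "features": features}
    Path(path).write_text(json.dumps(doc))


def read_wetlands(path: str | Path) -> list[WetlandUnit]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = json.loads(path.read_text())
        feats = doc["features"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise FormatError(f"{path}: not a GeoJSON FeatureCollection") from exc
    out = []
    for f in feats:
        geom = _shapely_shape(f["geometry"])
        p = f["properties"]
        out.append(WetlandUnit(
            wetland_id=p["wetland_id"],
            polygon=geom,
            area=p["area_km2"],
            perimeter=p["perimeter_km"],
            landuse_pct=dict(p["landuse_pct"]),
            ave_rain=p.get("ave_rain_mm", 0.0),
            ave_temp=p.get("ave_temp_F", 50.0),
        ))
    return out


# ---------------------------------------------------------------------------
# Sample and climate CSV


def write_samples(path: str | Path, samples: list[SampleRecord]) -> None:
    df = pd.DataFrame([
        {
            "wetland_id": s.wetland_id, "station": s.station,
            "x": s.x, "y": s.y, "date": s.date.isoformat(),
            "nutrient": s.nutrient, "concentration_mg_L": s.concentration,
        }
        for s in samples
    ], columns=SAMPLES_CSV_HEADER)
    df.to_csv(path, index=False)


def read_samples(path: str | Path) -> list[SampleRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(SAMPLES_CSV_HEADER) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        SampleRecord(
            wetland_id=str(r.wetland_id), station=str(r.station),
            x=float(r.x), y=float(r.y),
            date=_dt.date.fromisoformat(str(r.date)),
            nutrient=str(r.nutrient), concentration=float(r.concentration_mg_L),
        )
        for r in df.itertuples(index=False)
    ]


def write_climate(path: str | Path, climate: pd.DataFrame) -> None:
    """Daily climate series: columns wetland_id, date, rain_mm, temp_F."""
    climate.to_csv(path, index=False)


def read_climate(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, parse_dates=["date"])
    need = {"wetland_id", "date", "rain_mm", "temp_F"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
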