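"""Synthetic study generator: wetlands, Sentinel-like scenes, samples.

The generator emulates the full set of study inputs from a known
additive model so every pipeline stage can be tested without any
download:

    concentration = intercept
                  + sum_f beta_f * discrete_f(wetland, date)     (baseline)
                  + sum_g gamma_g * continuous_g(pixel, month)   (residual)
                  + seasonal(quarter) + trend(year) + noise,     truncated at 0

Discrete attributes are per-wetland land-use percentages, morphometrics
and 7-day trailing climate means; continuous predictors are read off
smooth Gaussian-random-field imagery (optical reflectance in [0, 1],
SAR backscatter in dB with VV above VH). Within a calendar quarter the
latent fields are fixed and monthly scenes add only a small jitter, so
the quarterly mean composite the pipeline builds is a faithful stand-in
for the monthly values the generator samples. The exact decomposition of
every sample is retained in :class:`SyntheticTruth` for recovery tests.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Polygon

from . import indices as _ix
from .composite import assign_quarter
from .geoio import (LANDUSE_CLASSES, STATIONS, SampleRecord, WetlandUnit,
                    write_climate, write_samples, write_scene, write_wetlands)
from .grid import GridSpec, RasterBand, SceneStack

#: mean reflectance, brightness loading and greenness loading per band
_S2_BAND_MODEL = {
    "B2": (0.06, 0.020, -0.005),
    "B3": (0.08, 0.025, -0.005),
    "B4": (0.09, 0.030, -0.035),
    "B5": (0.14, 0.030, 0.020),
    "B6": (0.22, 0.030, 0.060),
    "B7": (0.26, 0.030, 0.080),
    "B8": (0.30, 0.030, 0.100),
    "B8A": (0.31, 0.030, 0.100),
    "B11": (0.22, 0.040, -0.040),
    "B12": (0.15, 0.040, -0.030),
}


def default_months(years: tuple[int, ...] = (2021, 2022, 2023, 2024)) -> list[_dt.date]:
    """Default field-visit dates: the 15th of March through November.

    Nine visit months per year over four years gives 36 visits; with
    three wetlands and three stations each this yields 324 samples.
    """
    return [_dt.date(y, m, 15) for y in years for m in range(3, 12)]


@dataclass
class GenerativeSpec:
    """Parameters of the synthetic study.

    Concentrations are in mg/L; coefficients are per unit of the feature
    they multiply (land-use in %, rain in mm, NDVI dimensionless...).
    """

    n_wetlands: int = 3
    stations_per_wetland: int = 3
    months: list[_dt.date] = field(default_factory=default_months)
    grid: GridSpec = field(default_factory=lambda: GridSpec(
        origin_x=500000.0, origin_y=4420000.0, pixel_size=10.0,
        n_rows=200, n_cols=200, crs_label="synthetic-utm"))
    beta_discrete: dict[str, float] = field(
        default_factory=lambda: {"HP": 0.08, "AveRain": 0.05})
    gamma_continuous: dict[str, float] = field(
        default_factory=lambda: {"NDVI": 0.6})
    intercept: float = 0.5
    seasonal_amplitude: float = 0.45
    trend_per_year: float = 0.0
    noise_sd: float = 0.1
    nutrient: str = "N"
    seed: int = 0
    correlation_length: float = 5.0     # pixels
    scene_temporal_jitter: float = 0.01  # reflectance units, within-quarter
    landuse_preset: str = "bwg-like"    # or "independent"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.stations_per_wetland != len(STATIONS):
            raise ValueError("stations_per_wetland must be 3 (inlet/middle/outlet)")


def preset_phosphorus(seed: int = 0) -> GenerativeSpec:
    """A phosphorus-like preset.

    Roughly two orders of magnitude below the nitrogen scale, dominated
    by source loading from land use (stage 1) with a near-negligible
    continuous component, plus a small year-on-year decline that no
    predictor carries (an acknowledged unexplainable drift emulating
    multi-year recovery).
    """
    return GenerativeSpec(
        beta_discrete={"HP": 0.003, "DA": 0.0008},
        gamma_continuous={"NDVI": 0.004},
        intercept=0.15, seasonal_amplitude=0.01, trend_per_year=-0.01,
        noise_sd=0.004, nutrient="P", seed=seed)


@dataclass
class SyntheticTruth:
    """Lossless per-sample decomposition of the generated concentrations."""

    table: pd.DataFrame  # one row per sample with every additive component
    spec_seed: int

    @property
    def truncation_rate(self) -> float:
        return float(self.table["truncated"].mean())

    def to_json(self, path) -> None:
        doc = {
            "spec_seed": self.spec_seed,
            "columns": list(self.table.columns),
            "rows": self.table.assign(
                date=self.table["date"].astype(str)).to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        doc = json.loads(Path(path).read_text())
        df = pd.DataFrame(doc["rows"], columns=doc["columns"])
        df["date"] = pd.to_datetime(df["date"]).dt.date
        return cls(table=df, spec_seed=doc["spec_seed"])


@dataclass
class SyntheticStudy:
    """All generated inputs of one synthetic study run."""

    spec: GenerativeSpec
    wetlands: list[WetlandUnit]
    scenes: list[SceneStack]
    samples: list[SampleRecord]
    climate: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Random-field helpers


def _grf(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field (wrapped convolution)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


# ---------------------------------------------------------------------------
# Wetlands


def _radial_polygon(rng: np.random.Generator, cx: float, cy: float,
                    radius: float, n_vertices: int = 28,
                    roughness: float = 0.22) -> Polygon:
    """A simple star-convex polygon: smooth noise on a circle's radius."""
    for _ in range(30):
        theta = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
        bumps = rng.standard_normal(n_vertices)
        kernel = np.exp(-0.5 * (np.arange(-5, 6) / 2.0) ** 2)
        kernel /= kernel.sum()
        smooth = np.convolve(np.tile(bumps, 3), kernel, mode="same")[
            n_vertices:2 * n_vertices]
        smooth /= max(np.abs(smooth).max(), 1e-9)
        r = radius * (1.0 + roughness * smooth)
        poly = Polygon(zip(cx + r * np.cos(theta), cy + r * np.sin(theta)))
        if poly.is_valid and poly.area > 0:
            return poly
    raise RuntimeError("failed to draw a valid polygon")


def _hp_gradient(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Stratified hay/pasture shares spanning [lo, hi].

    Survey-style site selection: wetlands are picked to span a land-use
    gradient, so one share is drawn per equal-width stratum and the
    assignment shuffled.
    """
    strata = (np.arange(n) + rng.uniform(0.0, 1.0, n)) / n
    return rng.permutation(lo + (hi - lo) * strata)


def _landuse_mix(rng: np.random.Generator, preset: str,
                 hp: float) -> dict[str, float]:
    if preset == "bwg-like":
        # developed / cultivated / forest shares near the mixed-use landscape
        # the study presets emulate; HP varies more strongly across wetlands
        da = 26.2 + rng.uniform(-2, 2)
        cc = 38.2 + rng.uniform(-2, 2)
        fo = 14.7 + rng.uniform(-2, 2)
        rest = 100.0 - da - cc - fo - hp
        others = ("OP", "BL", "SS", "HB", "WW", "EHW")
        w = rng.dirichlet(np.ones(len(others)))
        mix = {"DA": da, "CC": cc, "FO": fo, "HP": hp}
        mix.update({c: rest * wi for c, wi in zip(others, w)})
    elif preset == "independent":
        # independent draws decouple threshold orderings across wetlands,
        # making per-feature importance attribution identifiable
        others = tuple(c for c in LANDUSE_CLASSES if c != "HP")
        w = rng.dirichlet(np.ones(len(others)))
        mix = {"HP": hp}
        mix.update({c: (100.0 - hp) * wi for c, wi in zip(others, w)})
    else:
        raise ValueError(f"unknown landuse preset {preset!r}")
    total = sum(mix.values())
    return {c: v * 100.0 / total for c, v in mix.items()}


def generate_wetlands(spec: GenerativeSpec,
                      rng: np.random.Generator | None = None) -> list[WetlandUnit]:
    """Simple polygons inside the grid with land-use and climate attributes."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    g = spec.grid
    width = g.n_cols * g.pixel_size
    height = g.n_rows * g.pixel_size
    n = spec.n_wetlands
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    dx, dy = width / ncols, height / nrows
    radius = 0.30 * min(dx, dy)
    hp_lo, hp_hi = (2.0, 14.0) if spec.landuse_preset == "bwg-like" else (0.0, 30.0)
    hp_values = _hp_gradient(rng, n, hp_lo, hp_hi)

    out = []
    for i in range(n):
        r_i, c_i = divmod(i, ncols)
        cx = g.origin_x + (c_i + 0.5) * dx + rng.uniform(-0.05, 0.05) * dx
        cy = g.origin_y - (r_i + 0.5) * dy + rng.uniform(-0.05, 0.05) * dy
        poly = _radial_polygon(rng, cx, cy, radius * rng.uniform(0.8, 1.15))
        m = _ix.morphometrics(poly, coord_units="m")
        out.append(WetlandUnit(
            wetland_id=f"W{i + 1:02d}",
            polygon=poly,
            area=m.area,
            perimeter=m.perimeter,
            landuse_pct=_landuse_mix(rng, spec.landuse_preset, float(hp_values[i])),
            ave_rain=float(rng.uniform(1.0, 4.0)),
            ave_temp=float(rng.uniform(45.0, 65.0)),
        ))
    return out


def station_points(wetland: WetlandUnit) -> dict[str, tuple[float, float]]:
    """Inlet / middle / outlet coordinates along the wetland's long chord."""
    poly = wetland.polygon
    mid = poly.representative_point()
    minx, miny, maxx, maxy = poly.bounds
    chord = LineString([(minx - 1.0, mid.y), (maxx + 1.0, mid.y)]).intersection(poly)
    if chord.geom_type == "MultiLineString":
        chord = max(chord.geoms, key=lambda s: s.length)
    if chord.is_empty or chord.geom_type != "LineString":
        # fall back to the representative point for degenerate chords
        return {s: (mid.x, mid.y) for s in STATIONS}
    inlet = chord.interpolate(0.2, normalized=True)
    outlet = chord.interpolate(0.8, normalized=True)
    return {"inlet": (inlet.x, inlet.y),
            "middle": (mid.x, mid.y),
            "outlet": (outlet.x, outlet.y)}


# ---------------------------------------------------------------------------
# Climate


def generate_climate(spec: GenerativeSpec,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily rain (mm) and temperature (°F) per wetland over the study window."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    start = min(spec.months) - _dt.timedelta(days=30)
    end = max(spec.months)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy()
    rows = []
    for i in range(spec.n_wetlands):
        wid = f"W{i + 1:02d}"
        temp = (52.0 + 22.0 * np.sin(2 * np.pi * (doy - 120) / 365.25)
                + rng.normal(0.0, 3.0, len(dates)) + rng.normal(0.0, 1.0))
        wet_season = 1.0 + 0.3 * np.sin(2 * np.pi * (doy - 150) / 365.25)
        rain = rng.gamma(0.35, 6.0, len(dates)) * wet_season
        rows.append(pd.DataFrame({
            "wetland_id": wid, "date": dates,
            "rain_mm": np.round(rain, 3), "temp_F": np.round(temp, 2),
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Scenes


def generate_scene_series(spec: GenerativeSpec,
                          rng: np.random.Generator | None = None
                          ) -> list[SceneStack]:
    """One optical and one SAR stack per month, seeded and reproducible.

    Per calendar quarter the generator draws latent greenness,
    brightness and backscatter fields; monthly scenes within the quarter
    share those fields plus a small temporal jitter, so quarterly mean
    composites closely reproduce the fields the samples were drawn from.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    g = spec.grid
    sig = spec.correlation_length

    quarters = sorted({assign_quarter(d) for d in spec.months})
    latent = {}
    for q in quarters:
        latent[q] = {
            "veg": _grf(rng, g.shape, sig),
            "bright": _grf(rng, g.shape, sig),
            "sar_v": _grf(rng, g.shape, sig),
            "sar_r": _grf(rng, g.shape, sig),
        }

    scenes = []
    for date in sorted(spec.months):
        q = assign_quarter(date)
        lat = latent[q]
        jit = _grf(rng, g.shape, sig)

        s2_bands = {}
        for name, (mean, w_bright, w_veg) in _S2_BAND_MODEL.items():
            vals = (mean + w_bright * lat["bright"] + w_veg * lat["veg"]
                    + spec.scene_temporal_jitter * jit)
            np.clip(vals, 0.005, 0.995, out=vals)
            s2_bands[name] = RasterBand(grid=g, name=name, values=vals,
                                        units="reflectance")
        scenes.append(SceneStack(date=date, bands=s2_bands, sensor="S2"))

        vv = -11.0 + 2.2 * lat["sar_v"] + 0.3 * jit
        vh = vv - 6.5 + 1.2 * lat["sar_r"]
        s1_bands = {
            "VV": RasterBand(grid=g, name="VV", values=vv, units="dB"),
            "VH": RasterBand(grid=g, name="VH", values=vh, units="dB"),
        }
        scenes.append(SceneStack(date=date, bands=s1_bands, sensor="S1"))
    return scenes


# ---------------------------------------------------------------------------
# Samples


def _point_band(scene: SceneStack, name: str, x: float, y: float) -> float:
    row, col = scene.grid.cell_of(x, y)
    return float(scene.bands[name].values[row, col])


def _continuous_value(feature: str, s2: SceneStack, s1: SceneStack,
                      x: float, y: float) -> float:
    """Evaluate one continuous predictor at a point of a monthly scene pair."""
    if feature in _S2_BAND_MODEL:
        return _point_band(s2, feature, x, y)
    if feature == "NDVI":
        nir, red = _point_band(s2, "B8", x, y), _point_band(s2, "B4", x, y)
        return (nir - red) / (nir + red)
    if feature == "NDWI":
        grn, nir = _point_band(s2, "B3", x, y), _point_band(s2, "B8", x, y)
        return (grn - nir) / (grn + nir)
    if feature == "EVI":
        nir, red, blu = (_point_band(s2, b, x, y) for b in ("B8", "B4", "B2"))
        return 2.5 * (nir - red) / (nir + 6 * red - 7.5 * blu + 1)
    vv = 10.0 ** (_point_band(s1, "VV", x, y) / 10.0)
    vh = 10.0 ** (_point_band(s1, "VH", x, y) / 10.0)
    if feature == "VV":
        return vv
    if feature == "VH":
        return vh
    if feature == "VV_VH":
        return vv / vh
    if feature == "VH_VV":
        return vh / vv
    if feature == "SRVI":
        return 4.0 * vv / (vv + vh)
    raise KeyError(f"unknown continuous feature {feature!r}")


def seasonal_component(quarter: int, amplitude: float) -> float:
    """Quarter-phase sinusoid peaking in Q2/Q3 (growing-season maximum)."""
    return amplitude * -math.cos(2 * math.pi * (quarter - 0.5) / 4.0)


def generate_samples(spec: GenerativeSpec, wetlands: list[WetlandUnit],
                     scenes: list[SceneStack],
                     climate: pd.DataFrame | None = None,
                     rng: np.random.Generator | None = None
                     ) -> tuple[list[SampleRecord], SyntheticTruth]:
    """Draw dated station samples from the additive generative model."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 404]))
    if climate is None:
        climate = generate_climate(spec)
    from .composite import trailing_climate_means

    s2_by_date = {s.date: s for s in scenes if s.sensor == "S2"}
    s1_by_date = {s.date: s for s in scenes if s.sensor == "S1"}
    year0 = min(d.year for d in spec.months)

    samples, rows = [], []
    for w in wetlands:
        pts = station_points(w)
        for date in sorted(spec.months):
            s2, s1 = s2_by_date[date], s1_by_date[date]
            q = assign_quarter(date)
            rain, temp = trailing_climate_means(climate, w.wetland_id, date)
            discrete_vals = {
                "Area": w.area, "Perimeter": w.perimeter,
                "SCI": w.perimeter / w.area,
                "PPS": 4.0 * math.pi * w.area / w.perimeter**2,
                "AveRain": rain, "AveTemp": temp,
                **{c: w.landuse_pct.get(c, 0.0) for c in LANDUSE_CLASSES},
            }
            for station in STATIONS:
                x, y = pts[station]
                contribs = {f: b * discrete_vals[f]
                            for f, b in spec.beta_discrete.items()}
                baseline = spec.intercept + sum(contribs.values())
                cont = sum(gmm * _continuous_value(f, s2, s1, x, y)
                           for f, gmm in spec.gamma_continuous.items())
                seas = (seasonal_component(q.quarter, spec.seasonal_amplitude)
                        + spec.trend_per_year * (q.year - year0))
                noise = float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd else 0.0
                total = baseline + cont + seas + noise
                conc = max(0.0, total)
                samples.append(SampleRecord(
                    wetland_id=w.wetland_id, station=station, x=x, y=y,
                    date=date, nutrient=spec.nutrient, concentration=conc))
                rows.append({
                    "wetland_id": w.wetland_id, "station": station, "date": date,
                    "year": q.year, "quarter": q.quarter,
                    "baseline_component": baseline,
                    "continuous_component": cont,
                    "seasonal_component": seas,
                    "noise": noise,
                    "concentration": conc,
                    "truncated": total < 0,
                    **{f"contrib_{f}": v for f, v in contribs.items()},
                })
    truth = SyntheticTruth(table=pd.DataFrame(rows), spec_seed=spec.seed)
    return samples, truth


def generate_study(spec: GenerativeSpec) -> SyntheticStudy:
    """Generate every input of one synthetic study from a single seed."""
    ss = np.random.SeedSequence([spec.seed])
    r_wet, r_clim, r_scene, r_samp = (np.random.default_rng(c)
                                      for c in ss.spawn(4))
    wetlands = generate_wetlands(spec, r_wet)
    climate = generate_climate(spec, r_clim)
    scenes = generate_scene_series(spec, r_scene)
    samples, truth = generate_samples(spec, wetlands, scenes, climate, r_samp)
    return SyntheticStudy(spec=spec, wetlands=wetlands, scenes=scenes,
                          samples=samples, climate=climate, truth=truth)


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Serialize a study to GeoJSON / TIFF / CSV / truth JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_wetlands(outdir / "wetlands.geojson", study.wetlands,
                   crs_label=study.spec.grid.crs_label)
    scene_dir = outdir / "scenes"
    scene_dir.mkdir(exist_ok=True)
    for s in study.scenes:
        name = f"scene_{s.sensor.lower()}_{s.date.isoformat()}.tif"
        write_scene(scene_dir / name, s)
    write_samples(outdir / "samples.csv", study.samples)
    write_climate(outdir / "climate.csv", study.climate)
    study.truth.to_json(outdir / "truth.json")
    return {"wetlands": str(outdir / "wetlands.geojson"),
            "scenes": str(scene_dir),
            "samples": str(outdir / "samples.csv"),
            "climate": str(outdir / "climate.csv"),
            "truth": str(outdir / "truth.json")}
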