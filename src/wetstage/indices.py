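"""Derived predictor variables: spectral indices, SAR conversions and
ratios, and wetland shape morphometrics.

Optical indices follow the usual definitions over surface reflectance in
[0, 1]:

    NDVI = (NIR - Red) / (NIR + Red)
    NDWI = (Green - NIR) / (Green + NIR)
    EVI  = 2.5 (NIR - Red) / (NIR + 6 Red - 7.5 Blue + 1)

SAR backscatter arrives in dB and is converted to linear power,
a = 10^(dB/10), before any ratio is formed. The radar vegetation index
used here (SRVI) is 4·aVV/(aVV + aVH) over linear power; note the
co-polarized channel sits in the numerator (the classical RVI uses the
cross-polarized channel — see `srvi_numerator`). Shape descriptors are
the shape complexity index SCI = perimeter/area (km per km², so
scale-dependent) and the dimensionless Polsby-Popper score
PPS = 4π·area/perimeter², which is 1 for a circle and < 1 otherwise.

Every elementwise division is guarded: zero denominators yield nodata,
never infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .grid import GridSpec, RasterBand


class AlignmentError(ValueError):
    """Input bands do not share one grid."""


class GeometryError(ValueError):
    """Polygon is not a valid simple ring."""


@dataclass
class SpectralIndexSet:
    ndvi: RasterBand
    ndwi: RasterBand
    evi: RasterBand


@dataclass
class SarIndexSet:
    vv_lin: RasterBand
    vh_lin: RasterBand
    vv_vh_ratio: RasterBand
    cross_ratio: RasterBand
    srvi: RasterBand


@dataclass(frozen=True)
class Morphometrics:
    area: float        # km^2
    perimeter: float   # km
    sci: float         # km / km^2
    pps: float         # dimensionless, in (0, 1]


def _require_aligned(*bands: RasterBand) -> GridSpec:
    grids = {b.grid for b in bands}
    if len(grids) != 1:
        raise AlignmentError("input bands are on different grids")
    return bands[0].grid


def _guarded_ratio(num: np.ndarray, den: np.ndarray,
                   valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise num/den with nodata wherever den == 0 or inputs invalid."""
    ok = valid & (den != 0)
    out = np.full(num.shape, np.nan)
    np.divide(num, den, out=out, where=ok)
    return out, ~ok


def ndvi(nir: RasterBand, red: RasterBand) -> RasterBand:
    grid = _require_aligned(nir, red)
    valid = nir.valid & red.valid
    vals, mask = _guarded_ratio(nir.values - red.values, nir.values + red.values, valid)
    return RasterBand(grid=grid, name="NDVI", values=vals, nodata_mask=mask, units="index")


def ndwi(green: RasterBand, nir: RasterBand) -> RasterBand:
    grid = _require_aligned(green, nir)
    valid = green.valid & nir.valid
    vals, mask = _guarded_ratio(green.values - nir.values, green.values + nir.values, valid)
    return RasterBand(grid=grid, name="NDWI", values=vals, nodata_mask=mask, units="index")


def evi(nir: RasterBand, red: RasterBand, blue: RasterBand) -> RasterBand:
    grid = _require_aligned(nir, red, blue)
    valid = nir.valid & red.valid & blue.valid
    den = nir.values + 6.0 * red.values - 7.5 * blue.values + 1.0
    vals, mask = _guarded_ratio(2.5 * (nir.values - red.values), den, valid)
    return RasterBand(grid=grid, name="EVI", values=vals, nodata_mask=mask, units="index")


def db_to_linear(band: RasterBand) -> RasterBand:
    """Convert backscatter from dB to linear power: a = 10^(dB/10)."""
    if band.units != "dB":
        raise ValueError(f"band '{band.name}' has units {band.units!r}, expected 'dB'")
    vals = np.power(10.0, band.values / 10.0)
    return RasterBand(grid=band.grid, name=band.name, values=vals,
                      nodata_mask=band.nodata_mask.copy(), units="linear_power")


def linear_to_db(band: RasterBand) -> RasterBand:
    """Inverse of :func:`db_to_linear`; nonpositive powers become nodata."""
    if band.units != "linear_power":
        raise ValueError(f"band '{band.name}' has units {band.units!r}, "
                         "expected 'linear_power'")
    ok = band.valid & (band.values > 0)
    vals = np.full(band.values.shape, np.nan)
    np.log10(band.values, out=vals, where=ok)
    vals *= 10.0
    return RasterBand(grid=band.grid, name=band.name, values=vals,
                      nodata_mask=~ok, units="dB")


def sar_indices(vv_lin: RasterBand, vh_lin: RasterBand,
                srvi_numerator: str = "vv") -> SarIndexSet:
    """Backscatter ratios and the radar vegetation index from linear power.

    ``srvi_numerator`` selects which channel scales the index: "vv"
    (default, 4·aVV/(aVV+aVH)) or "vh" (the classical cross-pol RVI,
    4·aVH/(aVV+aVH)). Valid pixels must hold strictly positive power.
    """
    grid = _require_aligned(vv_lin, vh_lin)
    for b in (vv_lin, vh_lin):
        if b.units != "linear_power":
            raise ValueError(f"band '{b.name}' must be in linear power")
        if np.any(b.values[b.valid] <= 0):
            raise ValueError(f"band '{b.name}' holds nonpositive power at valid pixels")
    if srvi_numerator not in ("vv", "vh"):
        raise ValueError("srvi_numerator must be 'vv' or 'vh'")
    valid = vv_lin.valid & vh_lin.valid
    avv, avh = vv_lin.values, vh_lin.values

    rat, rat_mask = _guarded_ratio(avv, avh, valid)
    crs, crs_mask = _guarded_ratio(avh, avv, valid)
    num = avv if srvi_numerator == "vv" else avh
    srv, srv_mask = _guarded_ratio(4.0 * num, avv + avh, valid)

    mk = lambda name, vals, mask: RasterBand(
        grid=grid, name=name, values=vals, nodata_mask=mask, units="index")
    return SarIndexSet(
        vv_lin=vv_lin, vh_lin=vh_lin,
        vv_vh_ratio=mk("VV_VH", rat, rat_mask),
        cross_ratio=mk("VH_VV", crs, crs_mask),
        srvi=mk("SRVI", srv, srv_mask),
    )


def morphometrics(polygon: Polygon, coord_units: str = "m") -> Morphometrics:
    """Area, perimeter, SCI and PPS of a wetland polygon.

    ``coord_units`` is the unit of the ring coordinates ("m" or "km");
    area is reported in km² and perimeter in km either way. PPS is
    computed unit-free from 4π·A/P².
    """
    if not isinstance(polygon, Polygon):
        polygon = Polygon(polygon)
    if polygon.is_empty or not polygon.is_valid:
        raise GeometryError("polygon is empty or self-intersecting")
    scale = {"m": 1e-3, "km": 1.0}.get(coord_units)
    if scale is None:
        raise ValueError("coord_units must be 'm' or 'km'")
    area_km2 = polygon.area * scale**2
    perim_km = polygon.length * scale
    if area_km2 <= 0 or perim_km <= 0:
        raise GeometryError("degenerate polygon")
    return Morphometrics(
        area=area_km2,
        perimeter=perim_km,
        sci=perim_km / area_km2,
        pps=4.0 * math.pi * area_km2 / perim_km**2,
    )
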