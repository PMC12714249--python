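"""Bathymetry-derived terrain attributes.

All attributes are computed on *elevation* (negated depth) so that
directional conventions match terrestrial DEM practice: "ridge" means a
shoal crest, aspect points down-slope (the direction water deepens), and
positive curvature means convex-up.

Layers
------
slope        degrees from horizontal, Horn 3x3 finite differences
aspect       compass degrees clockwise from grid north, flat cells get a
             sentinel (-1) rather than a fake direction
northness/eastness   cos/sin of aspect; 0 on flat cells
curvature    Zevenbergen-Thorne mean curvature, positive = convex-up,
             scaled per 100 m (configurable)
vrm          vector ruggedness measure in [0, 1] over a moving window
geomorphon   six collapsed landform classes from 8-direction line-of-sight
             ternary patterns
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import Raster

__all__ = [
    "TerrainLayer",
    "TerrainParams",
    "FLAT_ASPECT",
    "GEOMORPHON_CODES",
    "GEOMORPHON_NAMES",
    "compute_slope_aspect",
    "aspect_to_components",
    "compute_mean_curvature",
    "compute_vrm",
    "compute_geomorphons",
    "one_hot_geomorphons",
    "aggregate_to_coarse",
    "compute_all_terrain",
]

FLAT_ASPECT = -1.0

# Collapsed 6-form vocabulary, stable integer codes.
GEOMORPHON_CODES = {
    "flat": 1,
    "ridge": 2,
    "shoulder": 3,
    "slope_gm": 4,
    "footslope": 5,
    "valley": 6,
}
GEOMORPHON_NAMES = {v: k for k, v in GEOMORPHON_CODES.items()}

# Ten-form lookup indexed by (count of '-' directions, count of '+'
# directions); -1 marks impossible combinations (counts exceed 8 rays).
# Duals (peak/pit, ridge/valley, shoulder/footslope, spur/hollow) make the
# table antisymmetric about its diagonal.
_FL, _PK, _RI, _SH, _SP, _SL, _HL, _FS, _VL, _PT = range(10)
_TEN_FORM = np.array(
    [
        [_FL, _FL, _FL, _FS, _FS, _VL, _VL, _VL, _PT],
        [_FL, _FL, _FS, _FS, _FS, _VL, _VL, _VL, -1],
        [_FL, _SH, _SL, _SL, _HL, _HL, _VL, -1, -1],
        [_SH, _SH, _SL, _SL, _SL, _HL, -1, -1, -1],
        [_SH, _SH, _SP, _SL, _SL, -1, -1, -1, -1],
        [_RI, _RI, _SP, _SP, -1, -1, -1, -1, -1],
        [_RI, _RI, _RI, -1, -1, -1, -1, -1, -1],
        [_RI, _RI, -1, -1, -1, -1, -1, -1, -1],
        [_PK, -1, -1, -1, -1, -1, -1, -1, -1],
    ],
    dtype=int,
)
# Collapse: peak & spur -> ridge; pit & hollow -> valley.
_COLLAPSE = {
    _FL: GEOMORPHON_CODES["flat"],
    _PK: GEOMORPHON_CODES["ridge"],
    _RI: GEOMORPHON_CODES["ridge"],
    _SP: GEOMORPHON_CODES["ridge"],
    _SH: GEOMORPHON_CODES["shoulder"],
    _SL: GEOMORPHON_CODES["slope_gm"],
    _FS: GEOMORPHON_CODES["footslope"],
    _HL: GEOMORPHON_CODES["valley"],
    _VL: GEOMORPHON_CODES["valley"],
    _PT: GEOMORPHON_CODES["valley"],
}
_COLLAPSED_FORM = np.full((9, 9), -1, dtype=int)
for _m in range(9):
    for _p in range(9 - _m):
        _COLLAPSED_FORM[_m, _p] = _COLLAPSE[_TEN_FORM[_m, _p]]

_EIGHT_DIRS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass
class TerrainLayer(Raster):
    name: str = ""
    units: str = ""


@dataclass
class TerrainParams:
    """Tunables for the terrain attributes.

    vrm_window: odd moving-window width in cells for the ruggedness measure.
    flatness_angle: degrees below which a line-of-sight relief angle counts
        as level in geomorphon coding.
    geomorphon_lookup: line-of-sight search distance in cells.
    curvature_scale: multiplier on the raw 1/m curvature (100 reproduces the
        common GIS "per 100 m" convention).
    flat_aspect_policy: "zero" maps flat cells to northness=eastness=0;
        "nodata" drops them.
    """

    vrm_window: int = 3
    flatness_angle: float = 2.5
    geomorphon_lookup: int = 10
    curvature_scale: float = 100.0
    flat_aspect_policy: str = "zero"

    def __post_init__(self) -> None:
        if self.vrm_window < 3 or self.vrm_window % 2 == 0:
            raise ValueError("vrm_window must be odd and >= 3")
        if self.flatness_angle <= 0:
            raise ValueError("flatness_angle must be positive")
        if self.geomorphon_lookup < 1:
            raise ValueError("geomorphon_lookup must be >= 1")
        if self.flat_aspect_policy not in ("zero", "nodata"):
            raise ValueError("flat_aspect_policy must be 'zero' or 'nodata'")


def _elevation(depth: Raster) -> np.ndarray:
    """Negated depth with NaN at nodata cells."""
    return -depth.masked()


def _shift(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift with NaN fill so out-of-grid neighbours drop out of fmax/fmin."""
    out = np.full_like(arr, np.nan)
    rows, cols = arr.shape
    rs = slice(max(dr, 0), rows + min(dr, 0))
    rd = slice(max(-dr, 0), rows + min(-dr, 0))
    cs = slice(max(dc, 0), cols + min(dc, 0))
    cd = slice(max(-dc, 0), cols + min(-dc, 0))
    out[rd, cd] = arr[rs, cs]
    return out


def compute_slope_aspect(depth: Raster) -> tuple[TerrainLayer, TerrainLayer]:
    """Slope (degrees) and down-slope aspect (compass degrees) by Horn's
    3x3 weighted finite differences.

    Cells on the border or adjacent to nodata become nodata. Zero-gradient
    cells receive the flat-aspect sentinel.
    """
    z = _elevation(depth)
    if not np.isfinite(z).any():
        raise ValueError("depth raster contains no valid cells")
    L = depth.cell_size

    n = {(dr, dc): _shift(z, dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)}
    # Horn weights; rows increase southward, columns eastward.
    dzdx = (
        (n[(-1, 1)] + 2 * n[(0, 1)] + n[(1, 1)])
        - (n[(-1, -1)] + 2 * n[(0, -1)] + n[(1, -1)])
    ) / (8 * L)
    dzdy = (
        (n[(-1, -1)] + 2 * n[(-1, 0)] + n[(-1, 1)])
        - (n[(1, -1)] + 2 * n[(1, 0)] + n[(1, 1)])
    ) / (8 * L)

    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    # Down-slope compass bearing: gradient points uphill, so negate.
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[grad == 0] = FLAT_ASPECT

    invalid = ~np.isfinite(slope)
    slope[invalid] = np.nan
    aspect[invalid] = np.nan
    return (
        TerrainLayer(slope, depth.cell_size, depth.origin, depth.nodata,
                     name="slope", units="degrees"),
        TerrainLayer(aspect, depth.cell_size, depth.origin, depth.nodata,
                     name="aspect", units="degrees"),
    )


def aspect_to_components(
    aspect: TerrainLayer, policy: str = "zero"
) -> tuple[TerrainLayer, TerrainLayer]:
    """Decompose aspect into northness = cos(aspect) and eastness =
    sin(aspect).

    Flat-sentinel cells have no direction; under the default policy both
    components are set to 0 so the sentinel never leaks into trigonometry.
    """
    a = aspect.masked()
    flat = a == FLAT_ASPECT
    rad = np.radians(a)
    northness = np.cos(rad)
    eastness = np.sin(rad)
    if policy == "zero":
        northness[flat] = 0.0
        eastness[flat] = 0.0
    else:
        northness[flat] = np.nan
        eastness[flat] = np.nan
    return (
        aspect.like(northness, name="northness", units="dimensionless"),
        aspect.like(eastness, name="eastness", units="dimensionless"),
    )


def compute_mean_curvature(
    depth: Raster, scale: float = 100.0
) -> TerrainLayer:
    """Zevenbergen-Thorne mean curvature from the 3x3 quadratic surface.

    With the quadratic z = Ax2y2 + ... + Dx2 + Ey2 + ..., the reported value
    is -2(D + E) * scale, so positive = convex-up (a dome-shaped shoal) and
    the default scale of 100 yields the common per-100 m units.
    """
    z = _elevation(depth)
    if not np.isfinite(z).any():
        raise ValueError("depth raster contains no valid cells")
    L2 = depth.cell_size**2
    zn = _shift(z, -1, 0)
    zs = _shift(z, 1, 0)
    zw = _shift(z, 0, -1)
    ze = _shift(z, 0, 1)
    D = ((zw + ze) / 2 - z) / L2
    E = ((zn + zs) / 2 - z) / L2
    curv = -2.0 * (D + E) * scale
    return TerrainLayer(curv, depth.cell_size, depth.origin, depth.nodata,
                        name="curvature", units=f"1/({scale:g} m)")


def compute_vrm(
    slope: TerrainLayer, aspect: TerrainLayer, params: TerrainParams
) -> TerrainLayer:
    """Vector ruggedness measure over a moving window.

    Each cell contributes the unit normal of its slope/aspect facet,
    n = (sin S sin A, sin S cos A, cos S); flat cells contribute (0, 0, 1).
    VRM = 1 - |sum n| / n_valid, so 0 on any plane and -> 1 as orientations
    decohere. Nodata cells are excluded from both the sum and the count.
    """
    w = params.vrm_window
    if w > min(slope.shape):
        raise ValueError("vrm_window exceeds grid extent")
    s = np.radians(slope.masked())
    a = np.radians(aspect.masked())
    flat = aspect.masked() == FLAT_ASPECT
    valid = np.isfinite(s) & np.isfinite(a)

    sin_s = np.where(valid, np.sin(s), 0.0)
    cos_s = np.where(valid, np.cos(s), 0.0)
    sin_a = np.where(valid & ~flat, np.sin(a), 0.0)
    cos_a = np.where(valid & ~flat, np.cos(a), 0.0)
    # Flat facets point straight up.
    sin_s[flat & valid] = 0.0
    cos_s[flat & valid] = 1.0

    x = sin_s * sin_a
    y = sin_s * cos_a
    zc = cos_s

    def wsum(arr: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(arr, size=w, mode="constant") * w * w

    count = wsum(valid.astype(float))
    resultant = np.sqrt(wsum(x) ** 2 + wsum(y) ** 2 + wsum(zc) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        vrm = 1.0 - resultant / count
    vrm = np.clip(vrm, 0.0, 1.0)
    vrm[~valid] = np.nan
    vrm[count == 0] = np.nan
    return slope.like(vrm, name="vrm", units="dimensionless")


def compute_geomorphons(depth: Raster, params: TerrainParams) -> TerrainLayer:
    """Classify each cell into one of six landforms from its 8-direction
    line-of-sight ternary pattern.

    For each compass ray, the largest upward and largest downward relief
    angles to cells within ``geomorphon_lookup`` cells are found on the
    elevation surface (negated depth). The ray codes '+' (terrain above),
    '-' (terrain below) or '0' (level) by comparing the sum of those two
    extreme angles against the flatness angle; the (count of '-', count of
    '+') pair indexes the standard ten-form lookup, collapsed to six forms
    (peak and spur count as ridge, pit and hollow as valley).
    """
    z = _elevation(depth)
    if not np.isfinite(z).any():
        raise ValueError("depth raster contains no valid cells")
    L = params.geomorphon_lookup
    t = math.radians(params.flatness_angle)
    cell = depth.cell_size

    n_plus = np.zeros(z.shape, dtype=int)
    n_minus = np.zeros(z.shape, dtype=int)
    for dr, dc in _EIGHT_DIRS:
        step = cell * math.hypot(dr, dc)
        alpha = np.full(z.shape, np.nan)
        beta = np.full(z.shape, np.nan)
        for k in range(1, L + 1):
            dz = _shift(z, k * dr, k * dc) - z
            ang = np.arctan(dz / (k * step))
            alpha = np.fmax(alpha, ang)
            beta = np.fmin(beta, ang)
        asym = alpha + beta  # NaN where the ray leaves the grid entirely
        n_plus += (asym > t).astype(int)
        n_minus += (asym < -t).astype(int)

    codes = _COLLAPSED_FORM[n_minus, n_plus].astype(float)
    codes[~np.isfinite(z)] = np.nan
    return TerrainLayer(codes, depth.cell_size, depth.origin, depth.nodata,
                        name="geomorphon", units="class-code")


def one_hot_geomorphons(gm: TerrainLayer) -> list[TerrainLayer]:
    """Expand the 6-form class raster into six {0,1} indicator layers.

    Valid cells are covered by exactly one indicator.
    """
    vals = gm.masked()
    known = set(GEOMORPHON_CODES.values())
    observed = set(np.unique(vals[np.isfinite(vals)]).astype(int))
    if not observed <= known:
        raise ValueError(f"unknown geomorphon codes: {sorted(observed - known)}")
    layers = []
    for name, code in GEOMORPHON_CODES.items():
        ind = np.where(np.isfinite(vals), (vals == code).astype(float), np.nan)
        layers.append(gm.like(ind, name=name, units="binary"))
    return layers


def aggregate_to_coarse(layer: Raster, coarse_cell_size: float,
                        categorical: bool = False) -> Raster:
    """Downsample to the analysis resolution by fine-cell-centre membership.

    Every fine cell belongs to the coarse cell containing its centre, which
    also handles non-integer resolution ratios (e.g., 4 m -> 30 m).
    Continuous layers take the mean of valid members; indicator layers
    (``categorical=True``) take the majority, with fraction >= 0.5 -> 1.
    Coarse cells with no valid member are nodata.
    """
    if coarse_cell_size <= layer.cell_size:
        raise ValueError("coarse_cell_size must exceed the fine cell size")
    fine = layer.cell_size
    rows, cols = layer.shape
    crows = math.ceil(rows * fine / coarse_cell_size - 1e-9)
    ccols = math.ceil(cols * fine / coarse_cell_size - 1e-9)

    ri = np.minimum(((np.arange(rows) + 0.5) * fine / coarse_cell_size).astype(int),
                    crows - 1)
    ci = np.minimum(((np.arange(cols) + 0.5) * fine / coarse_cell_size).astype(int),
                    ccols - 1)
    flat_idx = (ri[:, None] * ccols + ci[None, :]).ravel()

    vals = layer.masked().ravel()
    valid = np.isfinite(vals)
    sums = np.bincount(flat_idx[valid], weights=vals[valid], minlength=crows * ccols)
    counts = np.bincount(flat_idx[valid], minlength=crows * ccols)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    mean[counts == 0] = np.nan
    out = mean.reshape(crows, ccols)
    if categorical:
        out = np.where(np.isfinite(out), (out >= 0.5).astype(float), np.nan)

    # Keep the lower-left corner fixed; the top edge may gain padding when
    # the extent is not an exact multiple of the coarse size.
    origin = layer.origin
    result = Raster(out, coarse_cell_size, origin, layer.nodata)
    if isinstance(layer, TerrainLayer):
        result = TerrainLayer(result.values, coarse_cell_size, origin,
                              layer.nodata, name=layer.name, units=layer.units)
    return result


def compute_all_terrain(
    depth: Raster, params: TerrainParams | None = None
) -> dict[str, TerrainLayer]:
    """All fine-resolution terrain predictors keyed by layer name."""
    params = params or TerrainParams()
    slope, aspect = compute_slope_aspect(depth)
    northness, eastness = aspect_to_components(aspect, params.flat_aspect_policy)
    curvature = compute_mean_curvature(depth, params.curvature_scale)
    vrm = compute_vrm(slope, aspect, params)
    gm = compute_geomorphons(depth, params)
    layers = {
        "slope": slope,
        "curvature": curvature,
        "northness": northness,
        "eastness": eastness,
        "vrm": vrm,
        "geomorphon": gm,
    }
    for onehot in one_hot_geomorphons(gm):
        layers[onehot.name] = onehot
    return layers
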