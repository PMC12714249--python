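"""Independent per-cell reference implementations of the terrain attributes.

Deliberately written as plain per-cell loops, straight from the defining
formulas, sharing no code with the package; used to cross-check the
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

FLAT = -1.0


def horn_cell(elev: np.ndarray, r: int, c: int, cell: float):
    """(slope_deg, aspect_deg) at one interior cell by Horn's method."""
    z = elev[r - 1 : r + 2, c - 1 : c + 2]
    if np.isnan(z).any():
        return np.nan, np.nan
    a, b, cc = z[0]
    d, _, f = z[1]
    g, h, i = z[2]
    dzdx = ((cc + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    dzdy = ((a + 2 * b + cc) - (g + 2 * h + i)) / (8 * cell)
    slope = math.degrees(math.atan(math.hypot(dzdx, dzdy)))
    if dzdx == 0 and dzdy == 0:
        return slope, FLAT
    aspect = math.degrees(math.atan2(-dzdx, -dzdy)) % 360.0
    return slope, aspect


def zt_curvature_cell(elev: np.ndarray, r: int, c: int, cell: float,
                      scale: float = 100.0) -> float:
    """Zevenbergen-Thorne -2(D+E) curvature at one interior cell."""
    z = elev[r - 1 : r + 2, c - 1 : c + 2]
    if np.isnan(z[0, 1]) or np.isnan(z[2, 1]) or np.isnan(z[1, 0]) \
            or np.isnan(z[1, 2]) or np.isnan(z[1, 1]):
        return np.nan
    L2 = cell * cell
    D = ((z[1, 0] + z[1, 2]) / 2 - z[1, 1]) / L2
    E = ((z[0, 1] + z[2, 1]) / 2 - z[1, 1]) / L2
    return -2.0 * (D + E) * scale


def vrm_cell(slope_deg: np.ndarray, aspect_deg: np.ndarray,
             r: int, c: int, window: int) -> float:
    """VRM at one cell from unit surface normals over the window."""
    half = window // 2
    sx = sy = sz = 0.0
    n = 0
    for i in range(r - half, r + half + 1):
        for j in range(c - half, c + half + 1):
            if not (0 <= i < slope_deg.shape[0] and 0 <= j < slope_deg.shape[1]):
                continue
            s = slope_deg[i, j]
            a = aspect_deg[i, j]
            if np.isnan(s) or np.isnan(a):
                continue
            s_rad = math.radians(s)
            if a == FLAT:
                nx, ny, nz = 0.0, 0.0, 1.0
            else:
                a_rad = math.radians(a)
                nx = math.sin(s_rad) * math.sin(a_rad)
                ny = math.sin(s_rad) * math.cos(a_rad)
                nz = math.cos(s_rad)
            sx += nx
            sy += ny
            sz += nz
            n += 1
    if n == 0:
        return np.nan
    return 1.0 - math.sqrt(sx * sx + sy * sy + sz * sz) / n


# Ten-form table as published: rows = number of '-' rays (terrain below),
# columns = number of '+' rays (terrain above).
_TEN = [
    ["FL", "FL", "FL", "FS", "FS", "VL", "VL", "VL", "PT"],
    ["FL", "FL", "FS", "FS", "FS", "VL", "VL", "VL", None],
    ["FL", "SH", "SL", "SL", "HL", "HL", "VL", None, None],
    ["SH", "SH", "SL", "SL", "SL", "HL", None, None, None],
    ["SH", "SH", "SP", "SL", "SL", None, None, None, None],
    ["RI", "RI", "SP", "SP", None, None, None, None, None],
    ["RI", "RI", "RI", None, None, None, None, None, None],
    ["RI", "RI", None, None, None, None, None, None, None],
    ["PK", None, None, None, None, None, None, None, None],
]
_SIX = {
    "FL": 1, "PK": 2, "RI": 2, "SP": 2, "SH": 3, "SL": 4,
    "FS": 5, "HL": 6, "VL": 6, "PT": 6,
}


def geomorphon_cell(elev: np.ndarray, r: int, c: int, cell: float,
                    lookup: int, flat_deg: float) -> float:
    """Collapsed 6-form geomorphon code at one cell by explicit
    line-of-sight search in the 8 compass directions."""
    if np.isnan(elev[r, c]):
        return np.nan
    rows, cols = elev.shape
    t = math.radians(flat_deg)
    n_plus = n_minus = 0
    for dr, dc in [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1),
                   (0, -1), (-1, -1)]:
        angles = []
        for k in range(1, lookup + 1):
            i, j = r + k * dr, c + k * dc
            if not (0 <= i < rows and 0 <= j < cols):
                break
            if np.isnan(elev[i, j]):
                continue
            dist = k * cell * math.hypot(dr, dc)
            angles.append(math.atan((elev[i, j] - elev[r, c]) / dist))
        if not angles:
            continue  # ray sees nothing: level by convention
        asym = max(angles) + min(angles)
        if asym > t:
            n_plus += 1
        elif asym < -t:
            n_minus += 1
    return float(_SIX[_TEN[n_minus][n_plus]])
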