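"""Predictor-stack assembly and the collinearity screen.

The stack holds every candidate predictor co-registered at the analysis
resolution together with a validity mask (area of interest, land removed
via a minimum depth, and nodata in any layer). The screen draws one shared
random sample of valid cells, computes pairwise Pearson correlations among
the continuous layers, and discards the lower-priority member of every
pair beyond the threshold — reproducing the judgement that statistics less
robust to outliers (mean vs median, range vs sd) go first, while depth and
the terrain attributes are never discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .raster import Raster

__all__ = [
    "PredictorStack",
    "CollinearityReport",
    "build_stack",
    "collinearity_screen",
    "DEFAULT_PRIORITY",
    "PROTECTED_LAYERS",
]

CONTINUOUS_ORDER = [
    "depth", "slope", "curvature", "northness", "eastness", "vrm",
    "sst_mean", "sst_median", "sst_sd", "sst_range",
]
ONEHOT_ORDER = ["flat", "ridge", "shoulder", "slope_gm", "footslope", "valley"]

# Drop order within a collinear pair: the later name loses.
DEFAULT_PRIORITY = [
    "depth", "slope", "curvature", "northness", "eastness", "vrm",
    "sst_median", "sst_sd", "sst_mean", "sst_range",
]
# Depth and the terrain attributes are never discarded by default.
PROTECTED_LAYERS = frozenset(
    {"depth", "slope", "curvature", "northness", "eastness", "vrm"}
)


@dataclass
class PredictorStack:
    layers: dict[str, Raster]
    mask: np.ndarray
    continuous: list[str]
    onehot: list[str]

    def __post_init__(self) -> None:
        shapes = {r.shape for r in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers are not co-registered: shapes {shapes}")
        if len(self.layers) != len(set(self.layers)):
            raise ValueError("duplicate layer names")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def matrix(self, cells: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, n_layers) value matrix at the given flat cell indices
        (default: all mask-valid cells, row-major order)."""
        if cells is None:
            cells = np.flatnonzero(self.mask.ravel())
        cols = [lyr.masked().ravel()[cells] for lyr in self.layers.values()]
        return np.column_stack(cols)

    def subset(self, names: list[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"unknown layers: {missing}")
        return PredictorStack(
            layers={n: self.layers[n] for n in names},
            mask=self.mask,
            continuous=[n for n in names if n in self.continuous],
            onehot=[n for n in names if n in self.onehot],
        )


@dataclass
class CollinearityReport:
    sampled_cell_count: int
    pairs: list[tuple[str, str, float]]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (name, reason)


def build_stack(
    terrain_layers: dict[str, Raster],
    sst_stats,
    depth_coarse: Raster,
    aoi_mask: np.ndarray | None = None,
    min_depth: float = 1.0,
) -> PredictorStack:
    """Assemble the 16 candidate predictors and the analysis mask.

    The mask keeps cells that are inside the AOI, at least ``min_depth``
    metres below datum (removing land and intertidal area), and valid in
    every layer.
    """
    layers: dict[str, Raster] = {"depth": depth_coarse}
    for name in CONTINUOUS_ORDER[1:6]:
        if name not in terrain_layers:
            raise ValueError(f"missing terrain layer {name!r}")
        layers[name] = terrain_layers[name]
    layers["sst_mean"] = sst_stats.mean
    layers["sst_median"] = sst_stats.median
    layers["sst_sd"] = sst_stats.sd
    layers["sst_range"] = sst_stats.range
    for name in ONEHOT_ORDER:
        if name not in terrain_layers:
            raise ValueError(f"missing geomorphon indicator {name!r}")
        layers[name] = terrain_layers[name]

    shape = depth_coarse.shape
    for name, lyr in layers.items():
        if lyr.shape != shape:
            raise ValueError(f"layer {name!r} shape {lyr.shape} != {shape}")

    mask = np.ones(shape, dtype=bool) if aoi_mask is None else np.asarray(aoi_mask, bool)
    depth_vals = depth_coarse.masked()
    mask = mask & np.isfinite(depth_vals) & (depth_vals >= min_depth)
    for lyr in layers.values():
        mask &= lyr.valid_mask()

    return PredictorStack(
        layers=layers,
        mask=mask,
        continuous=list(CONTINUOUS_ORDER),
        onehot=list(ONEHOT_ORDER),
    )


def collinearity_screen(
    stack: PredictorStack,
    n_cells: int = 10_000,
    threshold: float = 0.7,
    priority: list[str] | None = None,
    protected: frozenset[str] | set[str] | None = None,
    seed: int | None = None,
) -> tuple[PredictorStack, CollinearityReport]:
    """Screen continuous predictors for pairwise collinearity.

    One random sample of ``n_cells`` mask-valid cells (all of them, with a
    warning, if fewer exist) is shared by every pair. For each pair with
    |r| >= threshold the member appearing later in ``priority`` is dropped,
    except that protected layers are never dropped; if both members are
    protected the pair is only reported. Indicator layers are exempt from
    screening. Constant layers have undefined correlations, reported as NaN
    and treated as not collinear.
    """
    priority = list(DEFAULT_PRIORITY) if priority is None else list(priority)
    protected = PROTECTED_LAYERS if protected is None else frozenset(protected)
    rng = np.random.default_rng(seed)

    valid_cells = np.flatnonzero(stack.mask.ravel())
    if valid_cells.size == 0:
        raise ValueError("stack mask has no valid cells")
    if valid_cells.size < n_cells:
        warnings.warn(
            f"only {valid_cells.size} valid cells available; using all",
            stacklevel=2,
        )
        sample = valid_cells
    else:
        sample = rng.choice(valid_cells, size=n_cells, replace=False)

    cont = [n for n in stack.names if n in stack.continuous]
    sub = stack.subset(cont)
    X = sub.matrix(sample)

    def rank(name: str) -> int:
        return priority.index(name) if name in priority else len(priority)

    pairs: list[tuple[str, str, float]] = []
    dropped: dict[str, str] = {}
    sd = X.std(axis=0)
    flagged: list[tuple[str, str, float]] = []
    for (i, a), (j, b) in combinations(enumerate(cont), 2):
        if sd[i] == 0 or sd[j] == 0:
            warnings.warn(f"constant layer in sample: {a if sd[i]==0 else b}",
                          stacklevel=2)
            r = float("nan")
        else:
            r = float(np.corrcoef(X[:, i], X[:, j])[0, 1])
        pairs.append((a, b, r))
        if np.isfinite(r) and abs(r) >= threshold:
            flagged.append((a, b, r))

    for a, b, r in flagged:
        if a in dropped or b in dropped:
            continue  # already resolved through another pair
        loser = max(a, b, key=rank)
        winner = a if loser == b else b
        if loser in protected and winner in protected:
            continue  # both protected: reported but kept
        if loser in protected:
            loser, winner = winner, loser
        dropped[loser] = f"|r|={abs(r):.3f} with {winner} >= {threshold}"

    kept = [n for n in stack.names if n not in dropped]
    report = CollinearityReport(
        sampled_cell_count=int(sample.size),
        pairs=pairs,
        dropped=sorted(dropped.items()),
    )
    return stack.subset(kept), report
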