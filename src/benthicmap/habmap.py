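"""Ensemble habitat mapping: per-cell votes, confidence tiers, cover table.

Every Monte-Carlo simulation's fitted forest classifies the whole predictor
stack, yielding one classified raster per simulation. Votes are tallied per
cell; the plurality class is tiered by the agreeing fraction f:

* f >= 0.75          high confidence
* 0.50 <= f < 0.75   low confidence
* f < 0.50, or tie   no-majority

for a nine-category map (four classes x two tiers + no-majority), finally
masked to a maximum depth. Both tier boundaries are inclusive at their
lower edge; ties are never broken arbitrarily toward a class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster
from .stack import PredictorStack

__all__ = [
    "VoteRaster",
    "ConfidenceMap",
    "classify_stack",
    "threshold_map",
    "cover_table",
    "category_legend",
]

NO_MAJORITY = "no-majority"


@dataclass
class VoteRaster:
    counts: np.ndarray  # (n_classes, rows, cols) integer votes
    classes: list[str]
    n_sim: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape[0] != len(self.classes):
            raise ValueError("vote planes do not match class list")


@dataclass
class ConfidenceMap:
    codes: Raster  # integer category codes, nodata outside the map
    categories: dict[int, str]  # code -> category name
    classes: list[str]
    high: float
    low: float


def category_legend(classes: list[str]) -> dict[int, str]:
    """Stable code table: class k -> codes 2k+1 (high) and 2k+2 (low),
    with the last code reserved for no-majority."""
    legend = {}
    for k, cls in enumerate(classes):
        legend[2 * k + 1] = f"{cls}-high"
        legend[2 * k + 2] = f"{cls}-low"
    legend[2 * len(classes) + 1] = NO_MAJORITY
    return legend


def classify_stack(
    stack: PredictorStack, results: list
) -> VoteRaster:
    """Tally per-cell class votes from every simulation's model.

    The stack must expose exactly the predictors the models were trained
    on; each model classifies every mask-valid cell once.
    """
    if not results:
        raise ValueError("no simulation results to classify with")
    feature_names = results[0].feature_names
    missing = [n for n in feature_names if n not in stack.layers]
    if missing:
        raise ValueError(f"stack lacks trained predictors: {missing}")

    classes = list(results[0].per_class.index)
    cells = np.flatnonzero(stack.mask.ravel())
    X = stack.subset(feature_names).matrix(cells)

    rows, cols = stack.shape
    counts = np.zeros((len(classes), rows, cols), dtype=int)
    flat_counts = np.zeros((len(classes), cells.size), dtype=int)
    for res in results:
        pred = res.model.predict(X).astype(int)
        for k in range(len(classes)):
            flat_counts[k] += pred == k
    for k in range(len(classes)):
        counts[k].ravel()[cells] = flat_counts[k]
    return VoteRaster(
        counts=counts, classes=classes, n_sim=len(results), mask=stack.mask.copy()
    )


def threshold_map(
    votes: VoteRaster,
    high: float = 0.75,
    low: float = 0.50,
    depth_coarse: Raster | None = None,
    max_depth: float = 50.0,
) -> ConfidenceMap:
    """Tier the plurality class per cell by its agreeing vote fraction.

    Cells deeper than ``max_depth`` (beyond the depth range the habitat
    classes occupy) or outside the vote mask become nodata.
    """
    if not high > low:
        raise ValueError("high threshold must exceed low threshold")
    counts = votes.counts
    n_classes, rows, cols = counts.shape
    legend = category_legend(votes.classes)
    no_majority_code = 2 * n_classes + 1

    top = counts.max(axis=0)
    winner = counts.argmax(axis=0)
    tied = (counts == top).sum(axis=0) > 1
    frac = top / votes.n_sim

    codes = np.full((rows, cols), np.nan)
    high_cat = 2 * winner + 1
    low_cat = 2 * winner + 2
    codes[votes.mask] = np.where(
        tied | (frac < low),
        no_majority_code,
        np.where(frac >= high, high_cat, low_cat),
    )[votes.mask]

    if depth_coarse is not None:
        depth = depth_coarse.masked()
        codes[~np.isfinite(depth) | (depth > max_depth)] = np.nan

    template = depth_coarse if depth_coarse is not None else None
    raster = (
        template.like(codes)
        if template is not None
        else Raster(np.where(np.isfinite(codes), codes, -9999.0), 1.0)
    )
    return ConfidenceMap(
        codes=raster, categories=legend, classes=votes.classes, high=high, low=low
    )


def cover_table(conf_map: ConfidenceMap) -> pd.DataFrame:
    """Percent cover by class and confidence tier over valid cells.

    Columns: high, low, total (percent of valid cells) and high_share (the
    high-confidence fraction of each class's own cover). The no-majority
    row carries only a total. Totals sum to 100 across rows.
    """
    vals = conf_map.codes.masked()
    valid = np.isfinite(vals)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("confidence map has no valid cells")

    rows = []
    for k, cls in enumerate(conf_map.classes):
        n_high = int((vals[valid] == 2 * k + 1).sum())
        n_low = int((vals[valid] == 2 * k + 2).sum())
        total = n_high + n_low
        rows.append(
            {
                "class": cls,
                "high": 100.0 * n_high / n_valid,
                "low": 100.0 * n_low / n_valid,
                "total": 100.0 * total / n_valid,
                "high_share": 100.0 * n_high / total if total else np.nan,
            }
        )
    nm_code = 2 * len(conf_map.classes) + 1
    n_nm = int((vals[valid] == nm_code).sum())
    rows.append(
        {
            "class": NO_MAJORITY,
            "high": np.nan,
            "low": np.nan,
            "total": 100.0 * n_nm / n_valid,
            "high_share": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("class")
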