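"""Sea-surface-temperature compositing from a stack of thermal scenes.

A scene is a per-pixel temperature grid (Kelvin as acquired) plus a QA
bitmask flagging cloud and cloud shadow. The pipeline masks flagged pixels,
rejects scenes with more than 25% cloud over the area of interest, converts
to Celsius, and reduces the surviving stack to per-cell mean, median,
standard deviation and range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date as _date

import numpy as np

from .raster import Raster

__all__ = [
    "QA_CLOUD",
    "QA_SHADOW",
    "ThermalScene",
    "ThermalCollection",
    "SSTStats",
    "mask_clouds",
    "reject_cloudy_scenes",
    "to_celsius",
    "reduce_collection",
    "composite_sst",
]

# QA bit semantics are defined by this package (a simplified stand-in for
# satellite QA products): bit 0 = cloud, bit 1 = cloud shadow.
QA_CLOUD = 0b01
QA_SHADOW = 0b10
KELVIN_OFFSET = 273.15


@dataclass
class ThermalScene:
    temperature: Raster
    qa: np.ndarray
    date: _date | None = None

    def __post_init__(self) -> None:
        self.qa = np.asarray(self.qa, dtype=int)
        if self.qa.shape != self.temperature.shape:
            raise ValueError("temperature and qa grids are not co-registered")


@dataclass
class ThermalCollection:
    scenes: list[ThermalScene]
    aoi_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.aoi_mask is None and self.scenes:
            self.aoi_mask = np.ones(self.scenes[0].temperature.shape, dtype=bool)
        self.aoi_mask = np.asarray(self.aoi_mask, dtype=bool)
        for scene in self.scenes:
            if scene.temperature.shape != self.aoi_mask.shape:
                raise ValueError("scene not co-registered with aoi_mask")


@dataclass
class SSTStats:
    """Per-cell summary layers of the composited collection (Celsius)."""

    mean: Raster
    median: Raster
    sd: Raster
    range: Raster
    n_obs: np.ndarray


def mask_clouds(scene: ThermalScene, bits: int = QA_CLOUD | QA_SHADOW) -> ThermalScene:
    """Set temperature to nodata wherever any of the given QA bits is set."""
    flagged = (scene.qa & bits) != 0
    vals = scene.temperature.masked()
    vals[flagged] = np.nan
    return replace(scene, temperature=scene.temperature.like(vals))


def cloud_fraction(scene: ThermalScene, aoi_mask: np.ndarray) -> float:
    """Fraction of AOI cells whose temperature is masked out."""
    aoi = np.asarray(aoi_mask, dtype=bool)
    if aoi.sum() == 0:
        return 0.0
    invalid = ~scene.temperature.valid_mask()
    return float(invalid[aoi].sum() / aoi.sum())


def reject_cloudy_scenes(
    coll: ThermalCollection, max_cloud: float = 0.25
) -> ThermalCollection:
    """Drop scenes whose masked fraction over the AOI strictly exceeds
    ``max_cloud``; a scene at exactly the threshold is retained.
    """
    kept = [s for s in coll.scenes if cloud_fraction(s, coll.aoi_mask) <= max_cloud]
    if not kept:
        warnings.warn("all scenes exceeded the cloud threshold", stacklevel=2)
    return ThermalCollection(scenes=kept, aoi_mask=coll.aoi_mask)


def to_celsius(scene: ThermalScene) -> ThermalScene:
    """Kelvin -> Celsius on valid cells; nodata propagates."""
    vals = scene.temperature.masked() - KELVIN_OFFSET
    return replace(scene, temperature=scene.temperature.like(vals))


def reduce_collection(coll: ThermalCollection, min_obs: int = 3) -> SSTStats:
    """Per-cell mean / median / sample sd / range over valid observations.

    Cells seen in fewer than ``min_obs`` scenes are nodata in all four
    layers: a standard deviation over one or two looks is noise, not signal.
    """
    if not coll.scenes:
        warnings.warn("empty collection; SST statistics are all nodata",
                      stacklevel=2)
        empty = np.full(coll.aoi_mask.shape, np.nan)
        template = Raster(empty, 1.0)
        return SSTStats(template, template, template, template,
                        np.zeros(coll.aoi_mask.shape, dtype=int))

    cube = np.stack([s.temperature.masked() for s in coll.scenes])
    n_obs = np.isfinite(cube).sum(axis=0)
    thin = n_obs < min_obs

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        mean = np.nanmean(cube, axis=0)
        median = np.nanmedian(cube, axis=0)
        sd = np.nanstd(cube, axis=0, ddof=1)
        rng = np.nanmax(cube, axis=0) - np.nanmin(cube, axis=0)
    for layer in (mean, median, sd, rng):
        layer[thin] = np.nan

    template = coll.scenes[0].temperature
    return SSTStats(
        mean=template.like(mean),
        median=template.like(median),
        sd=template.like(sd),
        range=template.like(rng),
        n_obs=n_obs,
    )


def composite_sst(
    coll: ThermalCollection, max_cloud: float = 0.25, min_obs: int = 3
) -> tuple[SSTStats, int]:
    """Full compositing chain: mask -> reject -> Celsius -> reduce.

    Returns the statistics and the number of scenes retained.
    """
    masked = ThermalCollection(
        scenes=[mask_clouds(s) for s in coll.scenes], aoi_mask=coll.aoi_mask
    )
    kept = reject_cloudy_scenes(masked, max_cloud=max_cloud)
    celsius = ThermalCollection(
        scenes=[to_celsius(s) for s in kept.scenes], aoi_mask=kept.aoi_mask
    )
    return reduce_collection(celsius, min_obs=min_obs), len(kept.scenes)
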