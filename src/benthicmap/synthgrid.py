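"""Synthetic study area: bathymetry, thermal scene stacks, drop-camera truth.

The generator emulates the three inputs a coastal habitat-mapping campaign
produces — a fine-resolution multibeam depth grid with island shoals, a
collection of coarse thermal scenes with cloud/shadow QA flags, and a table
of drop-camera observations in four benthic cover classes (bare substrate,
kelp-dominated, mixed macroalgae, red turf) — from a known generative rule,
so every downstream stage can be tested end to end and parameter recovery
can be measured against ground truth that is, for once, actually true.

The habitat rule is a multinomial logit on standardized depth, terrain
ruggedness (VRM) and median SST: kelp favours deep, cool cells; red turf
shallow, warm ones; bare substrate smooth (low-VRM) cells; the mixed class
takes rugged, warm cells at intermediate depth.
Class priors follow a realistic field-survey imbalance. Every output is a
pure function of the config (seeded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster
from .thermal import QA_CLOUD, QA_SHADOW, ThermalCollection, ThermalScene

__all__ = [
    "CLASS_LABELS",
    "SynthConfig",
    "generate_bathymetry",
    "generate_thermal_collection",
    "generate_ground_truth",
    "habitat_utilities",
]

CLASS_LABELS = ["bare", "kelp", "mixed", "red"]

# Rule coefficients on standardized (depth, vrm, sst_median): rows are
# classes. Signs encode the ecology being emulated; magnitudes set how
# separable the classes are before noise.
DEFAULT_RULE = {
    "bare": (0.0, -3.5, 0.0),
    "kelp": (3.0, 0.6, -0.8),
    "mixed": (0.0, 0.8, 2.0),
    "red": (-3.0, 0.4, 1.0),
}
# Class priors matching a 79/77/45/46-style survey imbalance.
DEFAULT_WEIGHTS = (0.32, 0.31, 0.18, 0.19)


@dataclass
class SynthConfig:
    grid_shape: tuple[int, int] = (240, 240)
    fine_cell_size: float = 5.0
    coarse_cell_size: float = 30.0
    n_scenes: int = 16
    cloud_fraction_range: tuple[float, float] = (0.0, 0.45)
    n_drops: int = 61
    cells_per_drop: tuple[int, int] = (2, 5)
    class_weights: tuple[float, ...] = DEFAULT_WEIGHTS
    rule_coefficients: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RULE)
    )
    noise_scale: float = 0.5
    seed: int = 0
    # Bathymetry shape parameters (metres).
    mean_depth: float = 28.0
    relief_amplitude: float = 24.0
    island_amplitude: float = 35.0
    roughness_amplitude: float = 0.5

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        ratio = self.coarse_cell_size / self.fine_cell_size
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError("coarse_cell_size must be an integer multiple "
                             "of fine_cell_size")
        if abs(sum(self.class_weights) - 1.0) > 1e-6:
            raise ValueError("class_weights must sum to 1")
        lo, hi = self.cloud_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("cloud_fraction_range must be an ordered pair in [0,1]")
        lo_c, hi_c = self.cells_per_drop
        if lo_c < 1 or hi_c < lo_c:
            raise ValueError("cells_per_drop must be an ordered positive range")

    @property
    def ratio(self) -> int:
        return round(self.coarse_cell_size / self.fine_cell_size)

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return (
            math.ceil(self.grid_shape[0] / self.ratio),
            math.ceil(self.grid_shape[1] / self.ratio),
        )


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _smooth_noise(rng, shape, sigma) -> np.ndarray:
    """Zero-mean, unit-sd smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_bathymetry(cfg: SynthConfig) -> Raster:
    """Fine-resolution positive-down depth grid.

    Depth = mean + large-scale relief + island shoals + fine-scale
    roughness whose local amplitude varies *independently* of the
    large-scale relief, so ruggedness carries information that slope does
    not. With all amplitudes non-zero the field is stretched to guarantee
    both intertidal (< 1 m, including emergent land) and deep (> 50 m)
    cells, mimicking an island-group study site.
    """
    rng = _rng(cfg, 1)
    rows, cols = cfg.grid_shape

    relief = _smooth_noise(rng, (rows, cols), sigma=min(rows, cols) / 8)
    depth = cfg.mean_depth + cfg.relief_amplitude * relief

    # Island shoals: a handful of gaussian bumps rising toward the surface.
    n_islands = max(1, round(rows * cols / 160**2) + 2)
    yy, xx = np.mgrid[0:rows, 0:cols]
    bumps = np.zeros((rows, cols))
    for _ in range(n_islands):
        cy, cx = rng.uniform(0.1, 0.9) * rows, rng.uniform(0.1, 0.9) * cols
        sig = rng.uniform(0.04, 0.09) * min(rows, cols)
        bumps += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
    depth -= cfg.island_amplitude * bumps

    # Roughness modulated by its own smooth amplitude field.
    amp = 1 / (1 + np.exp(-2 * _smooth_noise(rng, (rows, cols), sigma=min(rows, cols) / 10)))
    fine = _smooth_noise(rng, (rows, cols), sigma=1.0)
    depth += cfg.roughness_amplitude * amp * fine

    if cfg.relief_amplitude > 0 or cfg.island_amplitude > 0:
        # Affine stretch so the site spans emergent land to >50 m water.
        lo, hi = depth.min(), depth.max()
        target_lo, target_hi = min(lo, -2.0), max(hi, 52.0)
        if hi > lo:
            depth = target_lo + (depth - lo) * (target_hi - target_lo) / (hi - lo)

    return Raster(depth, cfg.fine_cell_size)


def generate_thermal_collection(
    cfg: SynthConfig, depth: Raster
) -> ThermalCollection:
    """Coarse-resolution thermal scenes (Kelvin) with blob-shaped cloud and
    cloud-shadow QA flags.

    Each scene = shared spatial pattern (cross-shore gradient plus a smooth
    anomaly) + scene-wide offset + pixel noise. Per-scene cloud fractions
    are drawn from ``cloud_fraction_range`` by quantile-thresholding a
    smooth field, so the masked fraction over the AOI is controlled; when
    the range allows, at least one scene exceeds the 25% rejection level.
    """
    if cfg.n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    rng = _rng(cfg, 2)
    crows, ccols = cfg.coarse_shape
    aoi = np.ones((crows, ccols), dtype=bool)

    # Cross-shore gradient in a seed-random direction plus a smaller-scale
    # smooth anomaly; keeping the directional ramp modest stops the SST
    # pattern from aliasing onto broad terrain-aspect structure.
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:crows, 0:ccols]
    ramp = (np.cos(theta) * (yy / max(crows - 1, 1) - 0.5)
            + np.sin(theta) * (xx / max(ccols - 1, 1) - 0.5))
    anomaly = _smooth_noise(rng, (crows, ccols), sigma=max(2, crows // 12))
    base = 290.5 + 0.8 * ramp + 0.7 * anomaly
    # Spatially varying temporal variability (e.g., exposure to offshore
    # water-mass swings): scene-to-scene offsets are amplified where the
    # exposure field is high, giving the per-cell SST spread real spatial
    # structure (and making sd and range strongly collinear, as temporal
    # statistics of the same spread are).
    exposure = np.clip(
        1.0 + 0.6 * _smooth_noise(rng, (crows, ccols), sigma=max(2, crows // 10)),
        0.2, None,
    )

    lo, hi = cfg.cloud_fraction_range
    fracs = rng.uniform(lo, hi, size=cfg.n_scenes)
    if hi > 0.26 and (fracs <= 0.25).all():
        fracs[-1] = (max(lo, 0.26) + hi) / 2

    # Demeaned scene offsets: the collection-wide mean shift is already in
    # ``base``, so the exposure field modulates only scene-to-scene spread.
    offsets = rng.normal(0.0, 1.2, size=cfg.n_scenes)
    offsets -= offsets.mean()

    scenes = []
    for i in range(cfg.n_scenes):
        noise = rng.normal(0.0, 0.25, size=(crows, ccols))
        temp = base + offsets[i] * exposure + noise

        qa = np.zeros((crows, ccols), dtype=int)
        f = fracs[i]
        if f > 0:
            blob = ndimage.gaussian_filter(
                rng.standard_normal((crows, ccols)), sigma=max(2, crows // 12),
                mode="reflect",
            )
            thresh = np.quantile(blob[aoi], 1.0 - f)
            blobby = blob >= thresh
            # Split the blob into cloud and trailing shadow pixels.
            shifted = np.roll(blobby, shift=(2, 2), axis=(0, 1))
            qa[blobby & ~shifted] |= QA_CLOUD
            qa[blobby & shifted] |= QA_SHADOW

        acq = date(2019 + i % 5, 7 + (i // 5) % 3, 1 + (3 * i) % 28)
        scenes.append(
            ThermalScene(Raster(temp, cfg.coarse_cell_size), qa, date=acq)
        )
    return ThermalCollection(scenes=scenes, aoi_mask=aoi)


def habitat_utilities(cfg: SynthConfig, features: np.ndarray) -> np.ndarray:
    """Class utilities of the generative rule at standardized features.

    ``features`` is (n, 3) standardized (depth, vrm, sst_median); returns
    (n, 4) utilities. Intercepts are calibrated by a deterministic softmax
    fixed point so that the marginal class proportions over ``features``
    match ``class_weights`` — the priors then mean what they say regardless
    of how the coefficient magnitudes differ between classes.
    """
    coefs = np.array([cfg.rule_coefficients[c] for c in CLASS_LABELS])
    base = features @ coefs.T
    w = np.asarray(cfg.class_weights)
    b = np.log(w)
    # Gumbel-max sampling at scale s draws from softmax(U/s); s is floored
    # so the noiseless (argmax) case still calibrates.
    s = max(cfg.noise_scale, 0.05)
    for _ in range(200):
        u = (base + b) / s
        u -= u.max(axis=1, keepdims=True)
        p = np.exp(u)
        p /= p.sum(axis=1, keepdims=True)
        pbar = np.clip(p.mean(axis=0), 1e-9, None)
        b += 0.5 * s * (np.log(w) - np.log(pbar))
    return base + b


def generate_ground_truth(cfg: SynthConfig, predictors) -> pd.DataFrame:
    """Drop-camera ground truth on the coarse grid.

    Each of ``n_drops`` camera drops lands on a random mask-valid cell and
    drifts across a 4-connected run of 2-5 contiguous cells (the camera
    frame dragging with the vessel); every visited cell yields one labelled
    observation. Labels follow the multinomial-logit habitat rule with
    Gumbel noise of scale ``noise_scale`` (0 = deterministic argmax).

    Returns a table with columns drop_id, row, col, class.
    """
    rng = _rng(cfg, 3)
    needed = {"depth", "vrm", "sst_median"}
    if not needed <= set(predictors.names):
        raise ValueError(f"predictors must include {sorted(needed)}")

    mask = predictors.mask
    crows, ccols = mask.shape
    eligible = np.flatnonzero(mask.ravel())
    if eligible.size < cfg.n_drops:
        raise ValueError(
            f"only {eligible.size} eligible cells for {cfg.n_drops} drops"
        )

    feats = np.column_stack([
        predictors.layers[name].masked().ravel()
        for name in ("depth", "vrm", "sst_median")
    ])
    mu = np.nanmean(feats[eligible], axis=0)
    sd = np.nanstd(feats[eligible], axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    # Intercepts calibrate against the whole eligible area, not the drops.
    utilities = habitat_utilities(cfg, z[eligible])
    util_at = {int(cell): utilities[i] for i, cell in enumerate(eligible)}

    records = []
    for drop_id in range(cfg.n_drops):
        size = int(rng.integers(cfg.cells_per_drop[0], cfg.cells_per_drop[1] + 1))
        run: list[int] = []
        for _ in range(40):  # retries if the walk dead-ends early
            start = int(rng.choice(eligible))
            run = [start]
            while len(run) < size:
                r, c = divmod(run[-1], ccols)
                steps = [(r + dr, c + dc) for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))]
                cand = [
                    rr * ccols + cc
                    for rr, cc in steps
                    if 0 <= rr < crows and 0 <= cc < ccols
                    and mask[rr, cc] and rr * ccols + cc not in run
                ]
                if not cand:
                    break
                run.append(int(rng.choice(cand)))
            if len(run) == size:
                break
        if len(run) < size:
            raise ValueError("could not place a contiguous drop; mask too sparse")
        for cell in run:
            u = util_at[cell]
            if cfg.noise_scale > 0:
                u = u + cfg.noise_scale * rng.gumbel(size=u.shape)
            label = CLASS_LABELS[int(np.argmax(u))]
            r, c = divmod(cell, ccols)
            records.append((drop_id, r, c, label))

    return pd.DataFrame(records, columns=["drop_id", "row", "col", "class"])
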