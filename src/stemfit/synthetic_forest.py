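"""Synthetic forest-plot scans with known ground truth.

Emulates a handheld-MLS map of a small surveyed plot: ~71 stems on a
rectangular plot of ~130 m perimeter, DBH between 11.75 and 32.78 cm with a
mean near 20.93 cm, gently undulating ground, and a thin horizontal "warning
line" of clutter about 2 m above ground around the plot boundary.  Every
generated point carries a label (ground / stem id / clutter), and the stem
table records the true diameter at breast height (1.3 m above *local* ground),
so each downstream stage can be validated without field data.

Error sources of a walking scan are modelled explicitly: Gaussian radial
sensor noise on stem surfaces, one-sided occlusion of stems
(:func:`apply_occlusion`) and platform-shake density variation
(:func:`jitter_density`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import yaml

from .io_formats import PointCloud

__all__ = [
    "ForestConfig",
    "SyntheticScene",
    "generate_forest",
    "apply_occlusion",
    "jitter_density",
    "ground_elevation",
    "LABEL_GROUND",
    "LABEL_CLUTTER",
]

# per-point label codes in the "label" attribute
LABEL_GROUND = 0
LABEL_CLUTTER = -1
# stems use their positive integer tree id


@dataclass(frozen=True)
class ForestConfig:
    """Parameters of the simulated plot.

    Defaults follow the study plot: 71 stems, ~130 m perimeter
    (35 m x 30 m rectangle), DBH in [11.75, 32.78] cm averaging 20.93 cm, and
    a warning line ~2 m above the ground around the plot.
    """

    n_trees: int = 71
    plot_extent: tuple[float, float] = (35.0, 30.0)
    dbh_range_cm: tuple[float, float] = (11.75, 32.78)
    dbh_mean_cm: float = 20.93
    stem_height_m: float = 8.0
    taper_rate: float = 0.01          # fractional radius decrease per metre
    points_per_m2_stem_surface: float = 5000.0
    points_per_m2_ground: float = 800.0
    noise_sigma_m: float = 0.01       # Gaussian radial noise
    ground_undulation_amp_m: float = 0.15
    clutter_line_height_m: float = 2.0
    occlusion_fraction: float = 0.0
    min_spacing_m: float = 2.0
    edge_margin_m: float = 1.0        # keep stems off the warning line
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.dbh_range_cm
        if not (0 < lo < hi):
            raise ValueError("dbh_range_cm must satisfy 0 < min < max")
        if not (lo <= self.dbh_mean_cm <= hi):
            raise ValueError("dbh_mean_cm must lie inside dbh_range_cm")
        if self.min_spacing_m <= 0:
            raise ValueError("min_spacing_m must be positive")
        if self.points_per_m2_stem_surface <= 0 or self.points_per_m2_ground <= 0:
            raise ValueError("point densities must be positive")
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if not (0 <= self.occlusion_fraction < 1):
            raise ValueError("occlusion_fraction must be in [0, 1)")

    @staticmethod
    def from_yaml(path) -> "ForestConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("plot_extent", "dbh_range_cm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return ForestConfig(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SyntheticScene:
    """A generated cloud, its stem table, and the config that produced it."""

    cloud: PointCloud
    truth: "pd.DataFrame"  # noqa: F821 - columns tree_id, x, y, dbh_cm
    config: ForestConfig

    @property
    def labels(self) -> np.ndarray:
        return self.cloud.attributes["label"]

    def stem_mask(self, tree_id: int | None = None) -> np.ndarray:
        if tree_id is None:
            return self.labels >= 1
        return self.labels == tree_id

    @property
    def ground_mask(self) -> np.ndarray:
        return self.labels == LABEL_GROUND

    @property
    def clutter_mask(self) -> np.ndarray:
        return self.labels == LABEL_CLUTTER


# ---------------------------------------------------------------------------
# terrain
# ---------------------------------------------------------------------------


def _ground_waves(config: ForestConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequencies (cycles/m along x and y) and phases of the two terrain waves."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD7]))
    w, d = config.plot_extent
    # low spatial frequencies: 1-2 cycles across the plot in each direction
    fx = rng.uniform(0.8, 1.8, size=2) / max(w, 1e-9)
    fy = rng.uniform(0.8, 1.8, size=2) / max(d, 1e-9)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    return np.column_stack([fx, fy]), phases, np.array([0.5, 0.5])


def ground_elevation(config: ForestConfig, xy: np.ndarray) -> np.ndarray:
    """Analytic terrain height (m) at the given ``(.., 2)`` xy positions.

    A sum of two low-frequency sinusoids whose combined amplitude equals
    ``ground_undulation_amp_m``; deterministic in the config seed, so tests can
    compare measured heights against the exact surface.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
    freqs, phases, weights = _ground_waves(config)
    z = np.zeros(len(xy))
    for (fx, fy), ph, wgt in zip(freqs, phases, weights):
        z += wgt * np.sin(2 * np.pi * (fx * xy[:, 0] + fy * xy[:, 1]) + ph)
    return config.ground_undulation_amp_m * z


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _place_stems(config: ForestConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample stem centres with a minimum spacing."""
    w, d = config.plot_extent
    m = config.edge_margin_m
    if w - 2 * m <= 0 or d - 2 * m <= 0:
        raise ValueError("plot_extent too small for edge margin")
    placed: list[np.ndarray] = []
    max_attempts = 2000 * max(config.n_trees, 1)
    attempts = 0
    while len(placed) < config.n_trees:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {config.n_trees} stems with spacing "
                f"{config.min_spacing_m} m in a {w}x{d} m plot; reduce n_trees "
                "or enlarge plot_extent"
            )
        attempts += 1
        cand = rng.uniform([m, m], [w - m, d - m])
        if all(np.hypot(*(cand - p)) >= config.min_spacing_m for p in placed):
            placed.append(cand)
    return np.asarray(placed).reshape(config.n_trees, 2)


def _sample_dbh(config: ForestConfig, rng: np.random.Generator) -> np.ndarray:
    """DBH values (cm) from a scaled Beta matching the plot's range and mean."""
    lo, hi = config.dbh_range_cm
    frac = (config.dbh_mean_cm - lo) / (hi - lo)
    conc = 6.0  # moderate spread; sd ~ 4 cm on the default range
    a, b = frac * conc, (1 - frac) * conc
    return lo + (hi - lo) * rng.beta(a, b, size=config.n_trees)


def _sample_stem(center: np.ndarray, z0: float, r13: float,
                 config: ForestConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample one tapered-cylinder stem surface with Gaussian radial noise.

    ``r13`` is the radius at 1.3 m above local ground; the taper model is
    r(h) = r0 * (1 - taper_rate * h) with r0 the radius at the local ground.
    """
    H = config.stem_height_m
    t = config.taper_rate
    r0 = r13 / (1.0 - t * 1.3)
    r_top = r0 * (1.0 - t * H)
    if r_top <= 0:
        raise ValueError("taper_rate too large: stem radius vanishes below stem_height_m")
    # lateral surface area of the truncated cone
    slant = np.hypot(H, r0 - r_top)
    area = np.pi * (r0 + r_top) * slant
    n = rng.poisson(config.points_per_m2_stem_surface * area)
    # height pdf proportional to local circumference r(h): inverse-CDF sample
    u = rng.uniform(size=n)
    if t > 0:
        # CDF(h) = (r0*h - r0*t*h^2/2) / (r0*H - r0*t*H^2/2)
        norm = H - t * H * H / 2.0
        h = (1.0 - np.sqrt(1.0 - 2.0 * t * u * norm)) / t
    else:
        h = u * H
    theta = rng.uniform(0, 2 * np.pi, size=n)
    radius = r0 * (1.0 - t * h) + rng.normal(0.0, config.noise_sigma_m, size=n)
    x = center[0] + radius * np.cos(theta)
    y = center[1] + radius * np.sin(theta)
    z = z0 + h
    return np.column_stack([x, y, z])


def _sample_ground(config: ForestConfig, rng: np.random.Generator) -> np.ndarray:
    w, d = config.plot_extent
    n = rng.poisson(config.points_per_m2_ground * w * d)
    xy = rng.uniform([0.0, 0.0], [w, d], size=(n, 2))
    z = ground_elevation(config, xy) + rng.normal(0.0, config.noise_sigma_m, size=n)
    return np.column_stack([xy, z])


def _sample_clutter(config: ForestConfig, rng: np.random.Generator) -> np.ndarray:
    """Warning-line tape around the plot boundary at a fixed height.

    Scanned sparsely: short dense dashes with gaps, as a thin reflective tape
    appears in a walking scan, at ``clutter_line_height_m`` above datum.
    """
    w, d = config.plot_extent
    perimeter = 2 * (w + d)
    dash_period, dash_len, pts_per_dash = 1.0, 0.25, 15
    starts = np.arange(0.0, perimeter - dash_len, dash_period)
    s = (starts[:, None] + rng.uniform(0, dash_len, size=(len(starts), pts_per_dash))).ravel()
    # arc-length position -> rectangle boundary coordinates
    xy = np.empty((len(s), 2))
    s = np.mod(s, perimeter)
    side1 = s < w
    side2 = (s >= w) & (s < w + d)
    side3 = (s >= w + d) & (s < 2 * w + d)
    side4 = s >= 2 * w + d
    xy[side1] = np.column_stack([s[side1], np.zeros(side1.sum())])
    xy[side2] = np.column_stack([np.full(side2.sum(), w), s[side2] - w])
    xy[side3] = np.column_stack([2 * w + d - s[side3], np.full(side3.sum(), d)])
    xy[side4] = np.column_stack([np.zeros(side4.sum()), perimeter - s[side4]])
    z = config.clutter_line_height_m + rng.normal(0.0, config.noise_sigma_m, size=len(s))
    return np.column_stack([xy, z])


def generate_forest(config: ForestConfig | None = None) -> SyntheticScene:
    """Generate a labelled plot scan; deterministic for a fixed config seed.

    Independent random streams are used for stem placement, DBH values, stem
    surface sampling, ground sampling and clutter, so e.g. changing a density
    does not move the stems.
    """
    import pandas as pd

    if config is None:
        config = ForestConfig()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(np.random.SeedSequence([config.seed, salt]))
        for name, salt in [("place", 1), ("dbh", 2), ("stems", 3),
                           ("ground", 4), ("clutter", 5), ("occlude", 6)]
    }
    del root

    centers = _place_stems(config, streams["place"])
    dbh_cm = _sample_dbh(config, streams["dbh"])

    parts: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    ground = _sample_ground(config, streams["ground"])
    parts.append(ground)
    labels.append(np.full(len(ground), LABEL_GROUND, dtype=np.int64))

    for k in range(config.n_trees):
        z0 = float(ground_elevation(config, centers[k][None, :])[0])
        pts = _sample_stem(centers[k], z0, dbh_cm[k] / 200.0, config, streams["stems"])
        parts.append(pts)
        labels.append(np.full(len(pts), k + 1, dtype=np.int64))

    clutter = _sample_clutter(config, streams["clutter"])
    parts.append(clutter)
    labels.append(np.full(len(clutter), LABEL_CLUTTER, dtype=np.int64))

    cloud = PointCloud(
        np.concatenate(parts, axis=0),
        {"label": np.concatenate(labels)},
        frame_note=f"synthetic forest (seed={config.seed})",
    )
    truth = pd.DataFrame(
        {
            "tree_id": np.arange(1, config.n_trees + 1),
            "x": centers[:, 0] if config.n_trees else np.array([]),
            "y": centers[:, 1] if config.n_trees else np.array([]),
            "dbh_cm": dbh_cm,
        }
    )
    scene = SyntheticScene(cloud, truth, config)
    if config.occlusion_fraction > 0:
        scene = apply_occlusion(scene, config.occlusion_fraction,
                                seed=int(streams["occlude"].integers(2**31)))
    return scene


# ---------------------------------------------------------------------------
# degradation operators
# ---------------------------------------------------------------------------


def apply_occlusion(scene: SyntheticScene, fraction: float, seed: int = 0) -> SyntheticScene:
    """Remove a contiguous azimuthal sector of each stem (one-sided scanning).

    For each stem, points are ordered by azimuth around the stem centre and a
    circular run starting at a random azimuth, containing ``round(fraction*n)``
    points, is deleted.  Ground and clutter are untouched.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return scene
    rng = np.random.default_rng(seed)
    labels = scene.labels
    keep = np.ones(len(scene.cloud), dtype=bool)
    for _, row in scene.truth.iterrows():
        tid = int(row["tree_id"])
        idx = np.flatnonzero(labels == tid)
        if len(idx) == 0:
            continue
        rel = scene.cloud.coords[idx, :2] - np.array([row["x"], row["y"]])
        azimuth = np.arctan2(rel[:, 1], rel[:, 0])
        order = np.argsort(azimuth, kind="stable")
        n_remove = int(round(fraction * len(idx)))
        start = rng.integers(len(idx))
        circular = np.arange(start, start + n_remove) % len(idx)
        keep[idx[order[circular]]] = False
    return SyntheticScene(scene.cloud.select(keep), scene.truth, scene.config)


def jitter_density(scene: SyntheticScene, along_axis_amplitude: float,
                   seed: int = 0) -> SyntheticScene:
    """Thin the cloud with an x-varying keep probability (platform shake).

    keep probability q(x) = 1 - a * (0.5 + 0.5*sin(2*pi*x*3/W)); a=0 is the
    identity.  Deterministic per seed.
    """
    if along_axis_amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if along_axis_amplitude == 0:
        return scene
    if along_axis_amplitude > 1:
        raise ValueError("amplitude must be <= 1")
    rng = np.random.default_rng(seed)
    q = keep_probability(scene.config, scene.cloud.coords[:, 0], along_axis_amplitude)
    keep = rng.uniform(size=len(scene.cloud)) < q
    return SyntheticScene(scene.cloud.select(keep), scene.truth, scene.config)


def keep_probability(config: ForestConfig, x: np.ndarray, amplitude: float) -> np.ndarray:
    """The analytic keep-probability field used by :func:`jitter_density`."""
    w = config.plot_extent[0]
    return 1.0 - amplitude * (0.5 + 0.5 * np.sin(2 * np.pi * 3.0 * np.asarray(x) / w))
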