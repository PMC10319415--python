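"""Synthetic plot-image generator.

Produces labelled time series of canopy images — green crop rows over
textured soil with perspective fore-shortening and logistic canopy growth —
plus a linear yield model with additive per-seed-combination effects. This
stands in for a private field dataset so that every downstream stage can be
tested against known ground truth.

All randomness derives from one integer seed through per-plot/per-timestamp
``numpy`` SeedSequences (``default_rng([seed, plot_id, timestamp])``), so
any item is reproducible independently of generation order.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image

from .errors import InvalidArgumentError
from .records import PlotRecord

__all__ = [
    "SeedCombo", "SceneParams", "YieldModelParams", "SyntheticDataset",
    "TREATMENTS", "REFERENCE_TREATMENT_COUNTS", "enumerate_seed_combos",
    "default_seed_effects", "render_plot_image", "sample_yield",
    "generate_dataset",
]

TREATMENTS = (
    "non_treated_control",
    "base_control",
    "ilevo_alone",
    "ilevo_base",
    "saltro_base",
    "other",
)
#: per-treatment combination counts of the reference field trial
REFERENCE_TREATMENT_COUNTS = (5, 9, 2, 9, 10, 16)

_VARIETIES = ("resistant", "susceptible")
_RATES = ("110K", "140K", "170K")


@dataclass(frozen=True)
class SeedCombo:
    treatment: str
    variety: str
    rate: str
    index: int


def enumerate_seed_combos(counts_per_treatment=REFERENCE_TREATMENT_COUNTS) -> list[SeedCombo]:
    """Enumerate seed combinations, ``counts_per_treatment[i]`` per treatment.

    Combos are ordered lexicographically by (treatment position, variety,
    rate) and indexed 0..n-1. When a treatment needs more combos than the
    base variety x rate grid provides, rate labels gain a deterministic
    replicate suffix.
    """
    combos: list[SeedCombo] = []
    for t_idx, count in enumerate(counts_per_treatment):
        if count < 0:
            raise InvalidArgumentError(f"negative count at position {t_idx}")
        treatment = TREATMENTS[t_idx] if t_idx < len(TREATMENTS) \
            else f"treatment_{t_idx}"
        grid = []
        rep = 0
        while len(grid) < count:
            suffix = "" if rep == 0 else f".{rep}"
            for variety in _VARIETIES:
                for rate in _RATES:
                    grid.append((variety, rate + suffix))
            rep += 1
        grid = sorted(grid[:count])
        for variety, rate in grid:
            combos.append(SeedCombo(treatment, variety, rate, len(combos)))
    return combos


@dataclass(frozen=True)
class SceneParams:
    """Geometry, palette and growth parameters of one rendered plot."""

    image_size: tuple[int, int] = (128, 128)  # (H, W)
    n_timestamps: int = 3
    n_rows: int = 4
    row_spacing: int = 28
    perspective_factor: float = 0.45
    soil_color_mean: tuple[float, float, float] = (0.45, 0.32, 0.22)
    plant_color_mean: tuple[float, float, float] = (0.20, 0.55, 0.15)
    coverage_rate: float = 1.6      # logistic growth rate (per timestamp)
    coverage_midpoint: float = 0.8  # logistic midpoint (timestamp units)
    coverage_max: float = 1.0       # plateau canopy coverage
    greenness: float = 0.6          # modulates the plant green channel
    noise_sd: float = 0.02          # pixel-intensity noise, [0,1] units

    def coverage_at(self, t: int) -> float:
        c = self.coverage_max / (
            1.0 + math.exp(-self.coverage_rate * (t - self.coverage_midpoint)))
        return min(max(c, 0.0), 1.0)


@dataclass(frozen=True)
class YieldModelParams:
    """Linear yield model: base + betas * (coverage, greenness) + seed effect."""

    base_yield: float = 3300.0
    beta_coverage: float = 1100.0
    beta_greenness: float = 600.0
    seed_effects: dict = field(default_factory=dict)  # combo index -> kg/ha
    noise_sd: float = 80.0


def default_seed_effects(n_combos: int, rng_seed: int = 0,
                         frac_negative: float = 0.2,
                         negative_effect: float = -700.0,
                         small_sd: float = 50.0) -> dict:
    """Seed effects with a designated low-yield subset.

    About ``frac_negative`` of the combos get a large negative effect (the
    low-yield tail); the rest get small zero-mean effects.
    """
    rng = np.random.default_rng([rng_seed, 7001])
    n_neg = int(round(frac_negative * n_combos))
    neg = rng.choice(n_combos, size=n_neg, replace=False)
    effects = {}
    for i in range(n_combos):
        if i in neg:
            effects[i] = negative_effect + rng.normal(0.0, abs(negative_effect) * 0.1)
        else:
            effects[i] = rng.normal(0.0, small_sd)
    return effects


def _row_geometry(scene: SceneParams):
    """Row centre y-positions and perspective shrink factors, near to far."""
    h = scene.image_size[0]
    rows = []
    y = h - scene.row_spacing // 2 - 1
    for k in range(scene.n_rows):
        depth = k / max(scene.n_rows - 1, 1)
        shrink = 1.0 - scene.perspective_factor * depth
        rows.append((y, shrink))
        y -= int(round(scene.row_spacing * (0.55 + 0.45 * shrink)))
    return rows


def render_plot_image(scene: SceneParams, timestamp: int, rng_seed: int):
    """Render one timestamp of a plot scene.

    Returns ``(image, mask)``: float RGB image of shape (H, W, 3) in [0, 1]
    and the boolean plant mask. Deterministic given ``rng_seed``.
    """
    h, w = scene.image_size
    if h <= 0 or w <= 0:
        raise InvalidArgumentError("image size must be positive")
    if timestamp >= scene.n_timestamps:
        raise InvalidArgumentError(
            f"timestamp {timestamp} >= n_timestamps {scene.n_timestamps}")
    rng = np.random.default_rng([rng_seed, timestamp])
    coverage = scene.coverage_at(timestamp)

    img = np.empty((h, w, 3))
    for c, v in enumerate(scene.soil_color_mean):
        img[:, :, c] = v
    mask = np.zeros((h, w), dtype=bool)

    plant = np.array(scene.plant_color_mean)
    plant[1] = 0.30 + 0.45 * scene.greenness  # greenness drives the G channel
    for y_c, shrink in _row_geometry(scene):
        half = coverage * scene.row_spacing * shrink / 2.0
        if half < 0.5:
            continue
        y0 = max(int(round(y_c - half)), 0)
        y1 = min(int(round(y_c + half)), h)
        if y1 > y0:
            mask[y0:y1, :] = True
    img[mask] = plant

    img += rng.normal(0.0, scene.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return img, mask


def sample_yield(coverage_final: float, greenness: float, combo: SeedCombo,
                 params: YieldModelParams, rng_seed: int) -> float:
    """Draw one yield (kg/ha) from the linear generative model."""
    rng = np.random.default_rng([rng_seed, 9001])
    mu = (params.base_yield
          + params.beta_coverage * coverage_final
          + params.beta_greenness * greenness
          + params.seed_effects.get(combo.index, 0.0))
    return float(mu + rng.normal(0.0, params.noise_sd)) if params.noise_sd > 0 \
        else float(mu)


@dataclass
class SyntheticDataset:
    plots: list            # list[PlotRecord]
    manifest: pd.DataFrame
    truth: YieldModelParams
    combos: list           # list[SeedCombo]


def _save_png(path: str, arr: np.ndarray):
    if arr.dtype == bool:
        Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(
            np.clip(arr * 255.0, 0, 255).round().astype(np.uint8)).save(path)


def generate_dataset(n_plots: int, scene: SceneParams,
                     yield_params: YieldModelParams, rng_seed: int,
                     out_dir: str | None = None,
                     combos: list[SeedCombo] | None = None,
                     write_images: bool = True) -> SyntheticDataset:
    """Generate ``n_plots`` labelled plots.

    Seed-combination assignment is balanced: plot counts per combo differ by
    at most one. When ``out_dir`` is given and ``write_images`` is true,
    images and masks are written as PNG and the manifest as CSV.
    """
    if n_plots < 1:
        raise InvalidArgumentError("n_plots must be >= 1")
    if combos is None:
        combos = enumerate_seed_combos(REFERENCE_TREATMENT_COUNTS)
    n_combos = len(combos)

    if write_images:
        if out_dir is None:
            raise InvalidArgumentError("out_dir required when write_images=True")
        try:
            os.makedirs(out_dir, exist_ok=True)
            os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
        except OSError as exc:  # unwritable target
            raise IOError(f"cannot create output directory {out_dir}: {exc}")

    master = np.random.default_rng([rng_seed])
    # balanced combo assignment: round-robin then shuffle over plots
    assignment = np.array([i % n_combos for i in range(n_plots)])
    master.shuffle(assignment)

    plots, rows = [], []
    for pid in range(n_plots):
        prng = np.random.default_rng([rng_seed, pid])
        combo = combos[int(assignment[pid])]
        plot_scene = replace(
            scene,
            coverage_rate=scene.coverage_rate * prng.uniform(0.7, 1.3),
            coverage_midpoint=scene.coverage_midpoint + prng.uniform(-0.4, 0.4),
            coverage_max=prng.uniform(0.55, 1.0),
            greenness=prng.uniform(0.3, 0.9),
            n_rows=scene.n_rows,
        )
        images, masks = [], []
        for t in range(scene.n_timestamps):
            img, mask = render_plot_image(
                plot_scene, t, rng_seed=_item_seed(rng_seed, pid))
            images.append(img)
            masks.append(mask)
        cov_final = plot_scene.coverage_at(scene.n_timestamps - 1)
        y = sample_yield(cov_final, plot_scene.greenness, combo, yield_params,
                         rng_seed=_item_seed(rng_seed, pid) + 1)
        rec = PlotRecord(pid, images, combo.index, y,
                         treatment=combo.treatment, variety=combo.variety,
                         rate=combo.rate, masks=masks)
        plots.append(rec)
        for t in range(scene.n_timestamps):
            img_path = os.path.join("images", f"plot{pid:04d}_t{t}.png")
            mask_path = os.path.join("images", f"plot{pid:04d}_t{t}_mask.png")
            if write_images:
                _save_png(os.path.join(out_dir, img_path), images[t])
                _save_png(os.path.join(out_dir, mask_path), masks[t])
            rows.append({
                "plot_id": pid, "timestamp": t,
                "image_path": img_path, "mask_path": mask_path,
                "treatment": combo.treatment, "variety": combo.variety,
                "rate": combo.rate, "combo_index": combo.index,
                "yield_kg_ha": y,
            })

    manifest = pd.DataFrame(rows)
    if write_images:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return SyntheticDataset(plots, manifest, yield_params, combos)


def _item_seed(rng_seed: int, pid: int) -> int:
    """Stable per-plot stream offset (counter-based; order-independent)."""
    return (rng_seed * 1_000_003 + pid * 97) % (2 ** 31)
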