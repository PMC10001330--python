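"""Synthetic histology-like tiles and benchmark objectives.

The tile generator emulates the structure of a five-class lung/colon
histopathology set: each class has its own background stain color,
expected density of darker nuclei-like elliptical blobs, and spatially
correlated texture.  The classes are separable by design (distinct mean
colors), which the end-to-end pipeline tests rely on.  The rendering is
purely cosmetic and not biologically calibrated.

Also provides the standard closed-form benchmark functions (sphere,
Rastrigin, Rosenbrock) used to validate the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import CLASS_NAMES, ImageTile


@dataclass
class TileRecipe:
    """Per-class generative settings.

    noise_sd sets the amplitude (gray levels) of both the correlated
    texture and the pixel noise; texture_scale is the correlation length
    in pixels.  With noise_sd = 0 and blob_density = 0 a tile is exactly
    its constant base color.
    """

    class_id: int
    name: str
    base_color: tuple[float, float, float]
    blob_density: float = 10.0   # expected nuclei-like blobs per tile
    texture_scale: float = 3.0
    noise_sd: float = 8.0


def default_recipes() -> list[TileRecipe]:
    """Five recipes with distinct stain-like mean colors and blob densities."""
    palette = [
        ("Col_Ad", (186, 118, 168), 14.0, 2.5),
        ("Col_Be", (226, 182, 204), 5.0, 4.0),
        ("Lun_Ad", (168, 140, 202), 11.0, 3.0),
        ("Lun_Be", (232, 208, 178), 3.0, 5.0),
        ("Lun_SC", (148, 98, 128), 18.0, 2.0),
    ]
    assert [name for name, *_ in palette] == list(CLASS_NAMES)
    return [TileRecipe(class_id=i, name=name, base_color=color,
                       blob_density=dens, texture_scale=scale)
            for i, (name, color, dens, scale) in enumerate(palette)]


def _render_tile(recipe: TileRecipe, size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.ones((size, size, 3)) * np.asarray(recipe.base_color, dtype=float)

    # darker elliptical "nuclei", anti-aliased by a soft edge on the
    # ellipse quadratic form
    n_blobs = rng.poisson(recipe.blob_density)
    if n_blobs > 0:
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        blob_color = np.asarray(recipe.base_color) * 0.45
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, size, size=2)
            a, b = rng.uniform(2.0, 5.0, size=2)
            theta = rng.uniform(0, np.pi)
            dy, dx = yy - cy, xx - cx
            u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
            v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
            q = u * u + v * v
            alpha = np.clip((1.2 - q) / 0.4, 0.0, 1.0)[:, :, None]
            img = alpha * blob_color + (1.0 - alpha) * img

    if recipe.noise_sd > 0:
        tex = gaussian_filter(rng.standard_normal((size, size)),
                              recipe.texture_scale)
        sd = tex.std()
        if sd > 0:
            img += recipe.noise_sd * (tex / sd)[:, :, None]
        img += 0.5 * recipe.noise_sd * rng.standard_normal((size, size, 3))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_tiles(n_per_class: int, size: int = 64,
                   recipes: Optional[Sequence[TileRecipe]] = None,
                   seed: int = 0) -> list[ImageTile]:
    """Generate ``5 * n_per_class`` labeled tiles, reproducible per seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if size < 16:
        raise ValueError("tile size must be >= 16")
    recipes = list(recipes) if recipes is not None else default_recipes()
    rng = np.random.default_rng(seed)
    tiles = []
    for k in range(n_per_class):
        for recipe in recipes:
            px = _render_tile(recipe, size, rng)
            tiles.append(ImageTile(pixels=px, label=recipe.name,
                                   source_id=f"synthetic/{recipe.name}/{k:05d}"))
    return tiles


# ---------------------------------------------------------------------------
# benchmark objectives for validating the optimizer

@dataclass
class BenchmarkObjective:
    name: str
    d: int
    fn: Callable[[np.ndarray], float]
    lb: np.ndarray
    ub: np.ndarray
    x_opt: np.ndarray
    f_opt: float


def benchmark_objective(name: str, d: int) -> BenchmarkObjective:
    """Standard test functions with known global minima."""
    if d < 1:
        raise ValueError("dimension must be >= 1")
    name = name.lower()
    if name == "sphere":
        return BenchmarkObjective(
            name="sphere", d=d, fn=lambda x: float(np.sum(np.square(x))),
            lb=np.full(d, -10.0), ub=np.full(d, 10.0),
            x_opt=np.zeros(d), f_opt=0.0)
    if name == "rastrigin":
        def rastrigin(x):
            x = np.asarray(x)
            return float(10.0 * x.size
                         + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))
        return BenchmarkObjective(
            name="rastrigin", d=d, fn=rastrigin,
            lb=np.full(d, -5.12), ub=np.full(d, 5.12),
            x_opt=np.zeros(d), f_opt=0.0)
    if name == "rosenbrock":
        def rosenbrock(x):
            x = np.asarray(x)
            return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2
                                + (1.0 - x[:-1]) ** 2))
        return BenchmarkObjective(
            name="rosenbrock", d=d, fn=rosenbrock,
            lb=np.full(d, -5.0), ub=np.full(d, 10.0),
            x_opt=np.ones(d), f_opt=0.0)
    raise ValueError(f"unknown objective {name!r}; "
                     "options: sphere, rastrigin, rosenbrock")
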