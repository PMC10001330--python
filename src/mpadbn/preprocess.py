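"""Tile loading and CLAHE contrast enhancement.

Contrast-limited adaptive histogram equalization (CLAHE) is the first stage
of the classification pipeline.  The image is divided into a grid of
non-overlapping contextual blocks; each block's histogram is clipped at a
limit proportional to the clip-limit parameter, the clipped excess is
redistributed uniformly across the bins in a single pass, and the block's
CDF defines a monotone intensity mapping.  Pixel values are produced by
bilinear interpolation between the mappings of the four nearest block
centers, which removes the block-boundary artifacts of naive per-block
equalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from skimage import color as _skcolor

logger = logging.getLogger(__name__)

#: the five tissue classes: colon adenocarcinoma / benign, lung
#: adenocarcinoma / benign / squamous cell carcinoma
CLASS_NAMES = ("Col_Ad", "Col_Be", "Lun_Ad", "Lun_Be", "Lun_SC")


@dataclass
class ImageTile:
    """One labeled RGB tile.

    pixels are H x W x 3 integer intensities in [0, 255] (uint8).
    label is one of :data:`CLASS_NAMES` or ``None`` for unlabeled tiles.
    """

    pixels: np.ndarray
    label: Optional[str] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"tile pixels must be HxWx3, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("tile intensities must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)


@dataclass
class ClaheConfig:
    """CLAHE controls: clip limit (CL), block grid (BS) and histogram bins.

    clip_limit is relative: the per-block histogram is clipped at
    ``clip_limit * block_pixels / n_bins``, i.e. a multiple of the height a
    perfectly uniform histogram would have.  block_size is the (rows, cols)
    grid of contextual regions, not the pixel size of a region.
    """

    clip_limit: float = 2.0
    block_size: tuple[int, int] = (8, 8)
    n_bins: int = 256
    color_mode: str = "lab_l"  # "lab_l" or "per_channel"

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")
        if self.block_size[0] < 1 or self.block_size[1] < 1:
            raise ValueError("block grid must be at least 1x1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.color_mode not in ("lab_l", "per_channel"):
            raise ValueError("color_mode must be 'lab_l' or 'per_channel'")


def load_tiles(root_dir, pattern: str = "**/*.png") -> list[ImageTile]:
    """Load labeled tiles from per-class subdirectories.

    The label of each tile is the name of its parent directory.  Files are
    visited in lexicographic order so the result is deterministic.
    Unreadable files are skipped with a warning; an empty result raises.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"no such directory: {root}")
    tiles: list[ImageTile] = []
    for path in sorted(root.glob(pattern)):
        if not path.is_file():
            continue
        try:
            with Image.open(path) as im:
                px = np.asarray(im.convert("RGB"))
        except Exception as exc:  # corrupt / non-image file
            logger.warning("skipping unreadable image %s: %s", path, exc)
            continue
        tiles.append(ImageTile(pixels=px, label=path.parent.name, source_id=str(path)))
    if not tiles:
        raise ValueError(f"no images found under {root} matching {pattern!r}")
    return tiles


def _bin_centers(n_bins: int) -> np.ndarray:
    """Representative intensity (0-255) of each histogram bin."""
    edges = np.arange(n_bins + 1) * 256.0 / n_bins
    return np.rint((edges[:-1] + edges[1:]) / 2.0 - 0.5)


def clipped_cdf_mapping(values: np.ndarray, clip_limit: float, n_bins: int) -> np.ndarray:
    """Return the clipped-histogram CDF lookup table for one block.

    ``values`` are the block's pixel intensities (ints in [0, 255]).  The
    histogram is clipped at ``clip_limit * len(values) / n_bins``; the
    clipped mass is redistributed uniformly over all bins in a single pass.
    The returned table maps bin index -> output level in [0, 255].

    A block whose histogram occupies a single bin has no contrast to
    stretch; it receives the identity mapping (each bin maps to its own
    representative level), which keeps constant regions unchanged and makes
    enhancement of constant tiles exactly idempotent.
    """
    values = np.asarray(values).ravel()
    n = values.size
    bins = (values.astype(np.int64) * n_bins) // 256
    hist = np.bincount(bins, minlength=n_bins).astype(float)
    if np.count_nonzero(hist) <= 1:
        return _bin_centers(n_bins)
    clip = clip_limit * n / n_bins
    excess = np.maximum(hist - clip, 0.0).sum()
    hist = np.minimum(hist, clip) + excess / n_bins
    cdf = np.cumsum(hist)
    return np.rint(cdf / n * 255.0)


def _clahe_channel(channel: np.ndarray, cfg: ClaheConfig) -> np.ndarray:
    """CLAHE on a single uint8 channel with bilinear mapping interpolation."""
    h, w = channel.shape
    gr, gc = cfg.block_size
    if gr > h:
        raise ValueError(f"block grid rows ({gr}) exceed image height ({h})")
    if gc > w:
        raise ValueError(f"block grid cols ({gc}) exceed image width ({w})")

    # reflect-pad so the block grid divides the image evenly
    th = -(-h // gr)  # ceil
    tw = -(-w // gc)
    pad_h, pad_w = th * gr - h, tw * gc - w
    padded = np.pad(channel, ((0, pad_h), (0, pad_w)), mode="reflect") if (pad_h or pad_w) else channel
    ph, pw = padded.shape

    luts = np.empty((gr, gc, cfg.n_bins))
    for i in range(gr):
        for j in range(gc):
            block = padded[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            luts[i, j] = clipped_cdf_mapping(block, cfg.clip_limit, cfg.n_bins)

    bins = (padded.astype(np.int64) * cfg.n_bins) // 256

    # fractional grid coordinates relative to block centers
    fy = np.arange(ph) / th - 0.5
    fx = np.arange(pw) / tw - 0.5
    f0y, f0x = np.floor(fy).astype(int), np.floor(fx).astype(int)
    ty, tx = fy - f0y, fx - f0x
    i0 = np.clip(f0y, 0, gr - 1)
    i1 = np.clip(f0y + 1, 0, gr - 1)
    j0 = np.clip(f0x, 0, gc - 1)
    j1 = np.clip(f0x + 1, 0, gc - 1)

    ty = ty[:, None]
    tx = tx[None, :]
    v00 = luts[i0[:, None], j0[None, :], bins]
    v01 = luts[i0[:, None], j1[None, :], bins]
    v10 = luts[i1[:, None], j0[None, :], bins]
    v11 = luts[i1[:, None], j1[None, :], bins]
    out = ((1 - ty) * (1 - tx) * v00 + (1 - ty) * tx * v01
           + ty * (1 - tx) * v10 + ty * tx * v11)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out[:h, :w]


def clahe_enhance(tile: ImageTile, cfg: ClaheConfig | None = None) -> ImageTile:
    """Apply CLAHE to a tile, preserving chroma.

    In the default ``lab_l`` mode the tile is converted to CIELAB, the
    lightness channel alone is equalized and the image converted back: the
    stain hue of histology tiles is preserved.  ``per_channel`` mode
    equalizes each RGB channel independently.
    """
    cfg = cfg or ClaheConfig()
    px = tile.pixels
    if cfg.color_mode == "per_channel":
        out = np.stack([_clahe_channel(px[:, :, c], cfg) for c in range(3)], axis=-1)
    else:
        lab = _skcolor.rgb2lab(px / 255.0)
        l8 = np.clip(np.rint(lab[:, :, 0] / 100.0 * 255.0), 0, 255).astype(np.uint8)
        l8_eq = _clahe_channel(l8, cfg)
        if np.array_equal(l8_eq, l8):
            # lightness untouched (e.g. constant tile): skip the LAB round
            # trip so the no-op case is exactly the identity
            return ImageTile(pixels=px.copy(), label=tile.label, source_id=tile.source_id)
        lab[:, :, 0] = l8_eq / 255.0 * 100.0
        rgb = np.clip(_skcolor.lab2rgb(lab), 0.0, 1.0)
        out = np.rint(rgb * 255.0).astype(np.uint8)
    return ImageTile(pixels=out, label=tile.label, source_id=tile.source_id)


def save_tiles(tiles: Sequence[ImageTile], out_dir) -> None:
    """Write tiles as PNGs into per-label subdirectories of ``out_dir``."""
    out = Path(out_dir)
    for k, tile in enumerate(tiles):
        sub = out / (tile.label or "unlabeled")
        sub.mkdir(parents=True, exist_ok=True)
        name = Path(tile.source_id).name if tile.source_id else f"tile_{k:05d}.png"
        if not name.lower().endswith(".png"):
            name += ".png"
        Image.fromarray(tile.pixels).save(sub / name)
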