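"""Contrast equalization and seeded sub-image sampling.

Each 1855 x 1855 crop is contrast-equalized, then five 1000 x 1000 analysis
windows are drawn at uniform-random offsets.  Equalization uses
contrast-limited adaptive histogram equalization pulled toward a bell-shaped
(Rayleigh) target: CLAHE redistributes local contrast under a clip limit, and
a global Rayleigh quantile map then reshapes the value distribution.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from skimage import exposure

from .io import GrayscaleImage


def derive_seed(run_seed: int, grain_id: str) -> int:
    """Stable per-grain seed < 2^31 so grain order never changes results."""
    digest = hashlib.blake2s(
        f"{run_seed}:{grain_id}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class SubImageSet:
    """The analysis windows cut from one grain's crop."""

    parent_grain_id: str
    windows: list[GrayscaleImage]
    offsets: list[tuple[int, int]]
    seed: int


def equalize_contrast(
    image: GrayscaleImage,
    tile_grid: tuple[int, int] = (8, 8),
    clip_limit: float = 0.01,
    rayleigh_sigma: float = 0.4,
) -> GrayscaleImage:
    """Contrast-limited adaptive equalization toward a bell-shaped histogram.

    Parameters
    ----------
    tile_grid
        Number of contextual tiles (rows, cols) for the adaptive step.
    clip_limit
        CLAHE clipping limit in [0, 1]; caps how much any histogram bin can
        be amplified.
    rayleigh_sigma
        Mode of the Rayleigh target distribution (in normalized intensity);
        the output histogram is pulled toward this bell shape.

    A constant image is returned unchanged: there is no contrast to
    redistribute.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    if image.height_px < tile_grid[0] or image.width_px < tile_grid[1]:
        raise ValueError("image smaller than the tile grid")
    pixels = image.pixels
    if np.ptp(pixels) == 0.0:
        return GrayscaleImage(pixels.copy(), pixel_size_nm=image.pixel_size_nm)
    kernel = (
        max(1, image.height_px // tile_grid[0]),
        max(1, image.width_px // tile_grid[1]),
    )
    flat = exposure.equalize_adapthist(
        pixels, kernel_size=kernel, clip_limit=clip_limit
    )
    out = rayleigh_quantile_map(flat, sigma=rayleigh_sigma)
    return GrayscaleImage(out, pixel_size_nm=image.pixel_size_nm)


def rayleigh_quantile_map(u: np.ndarray, sigma: float = 0.4) -> np.ndarray:
    """Monotone map sending a ~uniform [0,1] image to a Rayleigh shape.

    Applies the Rayleigh inverse CDF, truncated at its 99.9th percentile and
    rescaled back to [0, 1].  Being strictly monotone it preserves pixel
    ordering, so only the value distribution changes.
    """
    u = np.clip(u, 0.0, 1.0)
    u_max = 0.999  # truncate the unbounded Rayleigh tail
    x = sigma * np.sqrt(-2.0 * np.log1p(-u * u_max))
    x_hi = sigma * np.sqrt(-2.0 * np.log1p(-u_max))
    return x / x_hi


def rayleigh_target_cdf(x: np.ndarray, sigma: float = 0.4) -> np.ndarray:
    """CDF of the truncated-rescaled Rayleigh target on [0, 1]."""
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    u_max = 0.999
    x_hi = sigma * np.sqrt(-2.0 * np.log1p(-u_max))
    return -np.expm1(-((x * x_hi) ** 2) / (2.0 * sigma**2)) / u_max


def sample_subimages(
    image: GrayscaleImage,
    n: int = 5,
    size: int = 1000,
    seed: int = 0,
    parent_grain_id: str = "",
) -> SubImageSet:
    """Cut ``n`` square windows at uniform-random offsets (with replacement).

    Window pixels are verbatim copies of the parent crop; the same seed
    always reproduces the same offsets.
    """
    if image.height_px < size or image.width_px < size:
        raise ValueError(
            f"window size {size} exceeds image {image.pixels.shape}"
        )
    rng = np.random.default_rng(seed)
    max_r = image.height_px - size
    max_c = image.width_px - size
    offsets = [
        (int(rng.integers(0, max_r + 1)), int(rng.integers(0, max_c + 1)))
        for _ in range(n)
    ]
    windows = [
        GrayscaleImage(
            image.pixels[r : r + size, c : c + size].copy(),
            pixel_size_nm=image.pixel_size_nm,
        )
        for r, c in offsets
    ]
    return SubImageSet(
        parent_grain_id=parent_grain_id,
        windows=windows,
        offsets=offsets,
        seed=seed,
    )
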