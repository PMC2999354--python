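"""Smoothing filter bank applied to the first-echo image before segmentation.

Five window-based filters are compared: two linear kernels (mean, Gaussian)
whose weights depend only on position, the median filter, and two
edge-preserving nonlinear filters — selective blurring, which weights
neighbours purely by intensity similarity, and the bilateral filter, which
multiplies a spatial Gaussian by an intensity (range) Gaussian.  Weights are
normalized to sum to one per pixel, so constant images are preserved
exactly and every output value lies inside the window's intensity range.

All filters share one explicit padded-window formulation (reflect padding,
window offsets enumerated in row-major order) so their arithmetic matches a
per-pixel double-loop evaluation bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FILTER_KINDS = ("mean", "gaussian", "median", "selective", "bilateral")


@dataclass(frozen=True)
class FilterConfig:
    """Filter selection and window geometry.

    ``window`` is the odd side length M of the MxM neighbourhood (7 in the
    original 256x256 comparison).  ``spatial_sigma`` (pixels) applies to the
    gaussian/bilateral kinds and defaults to window/6, the conventional
    3-sigma support; ``range_sigma`` (signal units) is required for the
    selective and bilateral kinds.
    """

    kind: str = "bilateral"
    window: int = 7
    spatial_sigma: float | None = None
    range_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}; choose from {FILTER_KINDS}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.kind in ("selective", "bilateral"):
            if self.range_sigma is None or self.range_sigma <= 0:
                raise ValueError(f"{self.kind} filter requires range_sigma > 0")
        if self.spatial_sigma is not None and self.spatial_sigma <= 0:
            raise ValueError("spatial_sigma must be > 0")

    @property
    def effective_spatial_sigma(self) -> float:
        return self.spatial_sigma if self.spatial_sigma is not None else self.window / 6.0


def _window_offsets(window: int) -> tuple[np.ndarray, np.ndarray]:
    r = window // 2
    dr, dc = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    return dr.ravel(), dc.ravel()


def _neighbour_tensor(image: np.ndarray, window: int) -> np.ndarray:
    """(H, W, M*M) tensor of each pixel's reflect-padded neighbourhood."""
    r = window // 2
    padded = np.pad(image, r, mode="symmetric")
    h, w = image.shape
    dr, dc = _window_offsets(window)
    out = np.empty((h, w, dr.size), dtype=float)
    for k in range(dr.size):
        out[:, :, k] = padded[r + dr[k] : r + dr[k] + h, r + dc[k] : r + dc[k] + w]
    return out


def spatial_kernel(window: int, sigma: float) -> np.ndarray:
    """Normalized MxM spatial Gaussian, flattened in row-major order."""
    dr, dc = _window_offsets(window)
    k = np.exp(-(dr.astype(float) ** 2 + dc.astype(float) ** 2) / (2.0 * sigma**2))
    return k / k.sum()


def apply_filter(image: np.ndarray, config: FilterConfig) -> np.ndarray:
    """Filter a 2-D image with the configured kind (reflect border handling)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")

    nb = _neighbour_tensor(image, config.window)
    m2 = config.window**2

    if config.kind == "mean":
        return nb.sum(axis=2) / m2
    if config.kind == "gaussian":
        k = spatial_kernel(config.window, config.effective_spatial_sigma)
        return (nb * k).sum(axis=2)
    if config.kind == "median":
        return np.median(nb, axis=2)

    diff2 = (nb - image[:, :, None]) ** 2
    rng = np.exp(-diff2 / (2.0 * config.range_sigma**2))
    if config.kind == "selective":
        w = rng
    else:  # bilateral
        dr, dc = _window_offsets(config.window)
        spatial = np.exp(
            -(dr.astype(float) ** 2 + dc.astype(float) ** 2)
            / (2.0 * config.effective_spatial_sigma**2)
        )
        w = rng * spatial
    return (nb * w).sum(axis=2) / w.sum(axis=2)
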