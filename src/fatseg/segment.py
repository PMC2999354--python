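"""Mean-shift segmentation of the filtered first-echo image.

Every pixel is lifted into the joint spatial–range feature space
``(row/h_s, col/h_s, intensity/h_r)`` and iterated under the mean-shift
update

    x^(1) = sum_i x_i g(||x - x_i||^2) / sum_i g(||x - x_i||^2)

with a unit-bandwidth kernel profile ``g`` (Epanechnikov by default: the
indicator of the unit ball, whose finite support guarantees convergence).
Pixels whose trajectories converge to nearby modes form one region; no
cluster count is ever supplied — granularity is controlled entirely by the
two bandwidths, so inhomogeneous tissue may legitimately split into several
regions.

Mode fusion is realised as connected components over the 4-connected pixel
lattice, linking two neighbouring pixels when their converged modes lie
within ``merge_distance`` of each other in normalized joint space; this is
the transitive closure restricted to spatially coherent regions and scales
linearly in image size.  Regions below ``min_region_size`` are absorbed by
the spatially adjacent region with the nearest mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

_GAUSSIAN_SUPPORT = 3.0  # truncation radius (joint units) for the gaussian profile


@dataclass(frozen=True)
class MeanShiftConfig:
    """Bandwidths and convergence controls of the segmentation.

    ``spatial_bandwidth`` (h_s, pixels) and ``range_bandwidth`` (h_r, signal
    units) set the kernel size in the two sub-domains; ``merge_distance`` is
    in normalized joint units (1.0 = one kernel radius).
    """

    spatial_bandwidth: float = 4.0
    range_bandwidth: float = 20.0
    kernel: str = "epanechnikov"
    merge_distance: float = 1.0
    min_region_size: int = 4
    max_iterations: int = 200
    shift_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.spatial_bandwidth <= 0 or self.range_bandwidth <= 0:
            raise ValueError("bandwidths must be > 0")
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be >= 0")
        if self.kernel not in ("epanechnikov", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass
class RegionLabelMap:
    """Integer label image (0 = excluded) plus per-region summaries.

    ``region_modes[r - 1]`` is region r's mean converged mode in raw units
    (row, col, intensity); labels are ordered by decreasing region size,
    ties broken by scan order of the first member pixel.
    """

    labels: np.ndarray
    region_modes: np.ndarray
    region_sizes: np.ndarray

    @property
    def n_regions(self) -> int:
        return int(self.region_sizes.size)


def _profile_weights(d2: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "epanechnikov":
        return (d2 <= 1.0).astype(float)
    w = np.exp(-0.5 * d2)
    w[d2 > _GAUSSIAN_SUPPORT**2] = 0.0
    return w


def mean_shift_point(
    x: np.ndarray,
    data: np.ndarray,
    config: MeanShiftConfig,
    return_trajectory: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[np.ndarray]]:
    """Iterate one point to its density mode over the full data set.

    ``x`` and ``data`` are already expressed in normalized joint coordinates
    (any dimension); the kernel has unit bandwidth.  This is the reference
    semantics of the segmentation; :func:`segment_image` uses a
    window-accelerated but (for the Epanechnikov kernel) exactly equivalent
    batched version.  If the point falls outside every kernel support it is
    returned unchanged (and the event logged).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float)).copy()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 0:
        raise ValueError("data must be non-empty")
    trajectory = [x.copy()]
    for _ in range(config.max_iterations):
        d2 = np.sum((data - x) ** 2, axis=1)
        w = _profile_weights(d2, "epanechnikov" if config.kernel == "epanechnikov" else "gaussian")
        if config.kernel == "gaussian":
            w = np.exp(-0.5 * d2)  # reference path: untruncated gaussian
        sw = w.sum()
        if sw == 0.0:
            logger.warning("mean-shift point isolated beyond kernel support; returning as-is")
            break
        x_new = (data * w[:, None]).sum(axis=0) / sw
        shift = np.linalg.norm(x_new - x)
        x = x_new
        trajectory.append(x.copy())
        if shift < config.shift_tol:
            break
    if return_trajectory:
        return x, trajectory
    return x


def _batched_modes(
    image: np.ndarray, mask: np.ndarray, config: MeanShiftConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Converged joint-space position for every masked pixel.

    Returns ``(modes, converged)`` with modes in normalized units, shape
    (N, 3), in scan order of the masked pixels.  Data points live on the
    pixel grid, so the kernel support around any trajectory position is
    covered by a fixed window of the padded image — each iteration gathers
    that window for all still-active points at once.
    """
    hs, hr = config.spatial_bandwidth, config.range_bandwidth
    support = 1.0 if config.kernel == "epanechnikov" else _GAUSSIAN_SUPPORT
    radius = int(np.ceil(hs * support)) + 1
    h, w = image.shape
    img_p = np.pad(image.astype(float), radius, mode="constant")
    mask_p = np.pad(mask, radius, mode="constant", constant_values=False)

    rows, cols = np.nonzero(mask)
    pos = np.stack([rows / hs, cols / hs, image[rows, cols] / hr], axis=1)
    dr, dc = np.meshgrid(np.arange(-radius, radius + 1), np.arange(-radius, radius + 1), indexing="ij")
    dr, dc = dr.ravel(), dc.ravel()

    n = pos.shape[0]
    active = np.ones(n, dtype=bool)
    converged = np.zeros(n, dtype=bool)
    for _ in range(config.max_iterations):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        p = pos[idx]
        cr = np.clip(np.rint(p[:, 0] * hs).astype(int), 0, h - 1)
        cc = np.clip(np.rint(p[:, 1] * hs).astype(int), 0, w - 1)
        nr = cr[:, None] + dr[None, :]
        nc = cc[:, None] + dc[None, :]
        val = img_p[nr + radius, nc + radius]
        ok = mask_p[nr + radius, nc + radius]
        d2 = (
            (nr / hs - p[:, 0:1]) ** 2
            + (nc / hs - p[:, 1:2]) ** 2
            + (val / hr - p[:, 2:3]) ** 2
        )
        wgt = _profile_weights(d2, config.kernel)
        wgt[~ok] = 0.0
        sw = wgt.sum(axis=1)
        isolated = sw == 0.0
        sw_safe = np.where(isolated, 1.0, sw)
        new = np.stack(
            [
                (wgt * (nr / hs)).sum(axis=1) / sw_safe,
                (wgt * (nc / hs)).sum(axis=1) / sw_safe,
                (wgt * (val / hr)).sum(axis=1) / sw_safe,
            ],
            axis=1,
        )
        new[isolated] = p[isolated]
        shift = np.linalg.norm(new - p, axis=1)
        pos[idx] = new
        settled = (shift < config.shift_tol) | isolated
        converged[idx[settled]] = True
        active[idx] = ~settled
    if active.any():
        logger.warning("%d mean-shift trajectories hit max_iterations", int(active.sum()))
    return pos, converged | ~active


def _fuse_regions(
    mask: np.ndarray, modes_norm: np.ndarray, config: MeanShiftConfig
) -> np.ndarray:
    """Component labels (0-based, scan order of masked pixels) after fusion."""
    h, w = mask.shape
    idx_map = np.full((h, w), -1, dtype=int)
    idx_map[mask] = np.arange(modes_norm.shape[0])

    pairs_a, pairs_b = [], []
    # vertical and horizontal 4-neighbour links inside the mask
    for (sl_a, sl_b) in (
        ((slice(0, h - 1), slice(None)), (slice(1, h), slice(None))),
        ((slice(None), slice(0, w - 1)), (slice(None), slice(1, w))),
    ):
        both = mask[sl_a] & mask[sl_b]
        ia = idx_map[sl_a][both]
        ib = idx_map[sl_b][both]
        d = np.linalg.norm(modes_norm[ia] - modes_norm[ib], axis=1)
        link = d < config.merge_distance
        pairs_a.append(ia[link])
        pairs_b.append(ib[link])
    ia = np.concatenate(pairs_a)
    ib = np.concatenate(pairs_b)
    n = modes_norm.shape[0]
    graph = coo_matrix((np.ones(ia.size), (ia, ib)), shape=(n, n))
    _, comp = connected_components(graph, directed=False)
    return comp


def segment_image(
    image: np.ndarray, mask: np.ndarray, config: MeanShiftConfig
) -> RegionLabelMap:
    """Segment the (filtered) image into intensity-homogeneous regions."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")

    modes_norm, _ = _batched_modes(image, mask, config)
    comp = _fuse_regions(mask, modes_norm, config)

    rows, cols = np.nonzero(mask)
    n_comp = comp.max() + 1
    sizes = np.bincount(comp, minlength=n_comp)
    # mean converged mode per component, normalized units
    comp_modes = np.stack(
        [np.bincount(comp, weights=modes_norm[:, d], minlength=n_comp) / sizes for d in range(3)],
        axis=1,
    )

    # absorb undersized regions into the spatially adjacent region with the
    # nearest mode (smallest regions first; isolated specks keep their label)
    parent = np.arange(n_comp)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    h, w = mask.shape
    idx_map = np.full((h, w), -1, dtype=int)
    idx_map[mask] = comp
    adjacency: dict[int, set[int]] = {i: set() for i in range(n_comp)}
    for (sl_a, sl_b) in (
        ((slice(0, h - 1), slice(None)), (slice(1, h), slice(None))),
        ((slice(None), slice(0, w - 1)), (slice(None), slice(1, w))),
    ):
        both = mask[sl_a] & mask[sl_b]
        for a, b in zip(idx_map[sl_a][both], idx_map[sl_b][both]):
            if a != b:
                adjacency[a].add(b)
                adjacency[b].add(a)

    cur_sizes = sizes.astype(int).copy()
    order = sorted(range(n_comp), key=lambda i: (cur_sizes[i], i))
    for i in order:
        root = find(i)
        if cur_sizes[root] >= config.min_region_size:
            continue
        neigh_roots = {find(j) for j in adjacency[i]} - {root}
        if not neigh_roots:
            continue
        dists = {
            j: float(np.linalg.norm(comp_modes[root] - comp_modes[j])) for j in neigh_roots
        }
        target = min(sorted(dists), key=lambda j: (dists[j], j))
        # merge root into target
        merged_size = cur_sizes[root] + cur_sizes[target]
        comp_modes[target] = (
            comp_modes[root] * cur_sizes[root] + comp_modes[target] * cur_sizes[target]
        ) / merged_size
        cur_sizes[target] = merged_size
        cur_sizes[root] = 0
        parent[root] = target
        adjacency[target] |= adjacency[root]

    final_comp = np.array([find(c) for c in comp])
    # relabel: decreasing size, ties by scan order of first member pixel
    uniq = np.unique(final_comp)
    first_seen = {}
    for pos_i, c in enumerate(final_comp):
        if c not in first_seen:
            first_seen[c] = pos_i
    ordered = sorted(uniq, key=lambda c: (-cur_sizes[c], first_seen[c]))
    relabel = {c: r + 1 for r, c in enumerate(ordered)}

    labels = np.zeros(mask.shape, dtype=int)
    labels[rows, cols] = [relabel[c] for c in final_comp]
    n_regions = len(ordered)
    region_sizes = np.array([cur_sizes[c] for c in ordered], dtype=int)
    hs, hr = config.spatial_bandwidth, config.range_bandwidth
    region_modes = np.stack(
        [comp_modes[c] * np.array([hs, hs, hr]) for c in ordered], axis=0
    )
    logger.info("segmentation produced %d regions", n_regions)
    return RegionLabelMap(labels, region_modes, region_sizes)
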