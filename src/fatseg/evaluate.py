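"""Validation metrics: mask overlap percentage and volume regression.

The overlap percentage (OP) between an automatic fat mask R1 and a
reference mask R2 is intersection-over-union in percent by default
(Dice available behind ``metric="dice"``); agreement of per-slice fat
volumes against a reference series is summarised by an ordinary
least-squares line and the squared Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OverlapResult:
    op: float
    n_r1: int
    n_r2: int
    n_intersection: int
    n_union: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_slices: int


def overlap_percentage(
    r1: np.ndarray, r2: np.ndarray, metric: str = "iou"
) -> OverlapResult:
    """Overlap percentage of two masks (100 * |R1 n R2| / |R1 u R2|).

    Two empty masks agree perfectly (OP = 100); an empty mask against a
    non-empty one scores 0.  Symmetric in its arguments.
    """
    r1 = np.asarray(r1, dtype=bool)
    r2 = np.asarray(r2, dtype=bool)
    if r1.shape != r2.shape:
        raise ValueError(f"mask shapes differ: {r1.shape} vs {r2.shape}")
    if metric not in ("iou", "dice"):
        raise ValueError(f"unknown metric {metric!r}")
    n1, n2 = int(r1.sum()), int(r2.sum())
    inter = int((r1 & r2).sum())
    union = int((r1 | r2).sum())
    if union == 0:
        op = 100.0
    elif metric == "iou":
        op = 100.0 * inter / union
    else:
        op = 100.0 * 2 * inter / (n1 + n2)
    return OverlapResult(op=op, n_r1=n1, n_r2=n2, n_intersection=inter, n_union=union)


def regress_volumes(
    method_volumes: np.ndarray, reference_volumes: np.ndarray
) -> RegressionResult:
    """OLS line of method volumes on reference volumes across slices."""
    y = np.asarray(method_volumes, dtype=float)
    x = np.asarray(reference_volumes, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("method and reference volume lists must be equal-length 1-D")
    if y.size < 3:
        raise ValueError("need at least 3 slices for a regression")
    if np.ptp(x) == 0:
        raise ValueError("reference volumes have zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_slices=int(y.size),
    )


def overlap_table(
    runs: list[tuple[int, np.ndarray, list[np.ndarray]]], metric: str = "iou"
) -> pd.DataFrame:
    """Mean/std OP per resolution over slices, averaged across references.

    ``runs`` holds ``(resolution, method_mask, [reference_mask, ...])``
    entries, one per slice; each slice's OP is the average against all of
    its references, mirroring evaluation against multiple manual raters.
    """
    per_slice = []
    for resolution, mask, references in runs:
        if not references:
            raise ValueError("each run needs at least one reference mask")
        ops = [overlap_percentage(mask, ref, metric=metric).op for ref in references]
        per_slice.append({"resolution": resolution, "op": float(np.mean(ops))})
    frame = pd.DataFrame(per_slice)
    grouped = frame.groupby("resolution", sort=True)["op"]
    return pd.DataFrame(
        {
            "resolution": grouped.mean().index,
            "mean_op": grouped.mean().to_numpy(),
            "std_op": grouped.std(ddof=0).to_numpy(),
            "n_slices": grouped.size().to_numpy(),
        }
    )
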