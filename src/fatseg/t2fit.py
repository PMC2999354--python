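"""Per-pixel mono-exponential T2 fitting by (weighted) least squares.

The signal at echo ``i`` follows the mono-exponential transverse-relaxation
model

    S_i(S0, T2) = S0 * exp(-Te_i / T2),        Te_i = i * te,

where ``S0`` is the pseudo-proton density (true proton density confounded
with T1 weighting and coil response) and ``T2`` the transverse relaxation
time in ms.  Two merit functions are supported:

* LS:   Phi^2 = sum_i (I_i - S_i)^2
* WLS:  Phi^2 = sum_i w_i (I_i - S_i)^2  with  w_i = I_i

i.e. the weights are the *measured* intensities, held fixed during the
optimization — low-intensity echoes are closer to the noise floor and are
down-weighted accordingly.  Before fitting, baseline subtraction removes
all echoes below an intensity threshold, and a pixel is fitted only when at
least ``min_valid_points`` echoes survive.  Fitted T2 above ``t2_trim_max``
is treated as non-physical and the pixel is marked invalid.

The optimizer is a damped Gauss-Newton (Levenberg–Marquardt) iteration on
``(S0, log T2)`` — the log parametrization bars non-positive T2 proposals —
vectorized across all pixels of a stack so whole images fit in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import INVALID_SENTINEL, AcquisitionDescriptor, EchoStack

logger = logging.getLogger(__name__)

_T2_FALLBACK_INIT = 50.0  # ms, used when the two-point log estimate degenerates
_LOG_T2_BOUNDS = (-10.0, 25.0)
_MAX_LOG_T2_STEP = 5.0


@dataclass(frozen=True)
class DecayModelParams:
    """Fitted mono-exponential parameters for one pixel."""

    s0: float
    t2: float

    def __post_init__(self) -> None:
        if self.s0 <= 0 or self.t2 <= 0:
            raise ValueError(f"s0 and t2 must be positive, got ({self.s0}, {self.t2})")


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the per-pixel decay fit.

    ``baseline_threshold`` is in signal units; pass
    :func:`estimate_baseline_threshold` output for the 3x-background-RMS
    default.  ``min_valid_points`` implements the >= 5 valid-echo rule;
    ``t2_trim_max`` trims non-physical fits (default 200 ms).
    """

    method: str = "wls"
    baseline_threshold: float = 0.0
    min_valid_points: int = 5
    t2_trim_max: float = 200.0
    max_iterations: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.method not in ("ls", "wls"):
            raise ValueError(f"method must be 'ls' or 'wls', got {self.method!r}")
        if self.min_valid_points < 2:
            raise ValueError("min_valid_points must be >= 2")
        if self.t2_trim_max <= 0:
            raise ValueError("t2_trim_max must be > 0")


@dataclass
class T2FitResult:
    """Per-pixel fit maps; invalid pixels carry the -1 sentinel."""

    s0_map: np.ndarray
    t2_map: np.ndarray
    valid_mask: np.ndarray
    residual_map: np.ndarray


def model_signal(params: DecayModelParams, echo_index: int, te_spacing: float) -> float:
    """Model intensity ``S0 * exp(-(i*te)/T2)`` at 1-based echo ``i``."""
    if echo_index < 1:
        raise ValueError(f"echo_index is 1-based, got {echo_index}")
    if te_spacing < 0:
        raise ValueError("te_spacing must be >= 0")
    return params.s0 * float(np.exp(-(echo_index * te_spacing) / params.t2))


def model_curve(params: DecayModelParams, descriptor: AcquisitionDescriptor) -> np.ndarray:
    """Model intensities at every echo of the acquisition."""
    return params.s0 * np.exp(-descriptor.echo_times / params.t2)


def baseline_subtract(
    signal: np.ndarray, threshold: float, min_valid_points: int
) -> np.ndarray:
    """Indices (0-based echo array indices) surviving baseline subtraction.

    Echoes with intensity below ``threshold`` are removed; if fewer than
    ``min_valid_points`` survive the pixel is invalid and the empty index
    set is returned.
    """
    signal = np.asarray(signal, dtype=float)
    idx = np.flatnonzero(signal >= threshold)
    if idx.size < min_valid_points:
        return np.empty(0, dtype=int)
    return idx


def estimate_baseline_threshold(background: np.ndarray, factor: float = 3.0) -> float:
    """Default baseline threshold: ``factor`` times the background RMS."""
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background region is empty")
    return factor * float(np.sqrt(np.mean(background**2)))


def merit(
    signal: np.ndarray,
    valid_idx: np.ndarray,
    params: DecayModelParams,
    descriptor: AcquisitionDescriptor,
    method: str = "wls",
) -> float:
    """The (weighted) quadratic merit Phi^2 over the valid-point set."""
    signal = np.asarray(signal, dtype=float)
    te = descriptor.echo_times[valid_idx]
    data = signal[valid_idx]
    model = params.s0 * np.exp(-te / params.t2)
    w = data if method == "wls" else np.ones_like(data)
    return float(np.sum(w * (data - model) ** 2))


# ---------------------------------------------------------------------------
# Vectorized Levenberg–Marquardt core
# ---------------------------------------------------------------------------


def _initial_guess(
    signals: np.ndarray, te: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (S0, log T2) start per pixel.

    T2 starts at the two-point log-linear estimate through the first and
    last valid echoes; S0 extrapolates the first valid intensity back to
    t = 0 with that T2.  Degenerate pixels fall back to T2 = 50 ms.
    """
    n_pix = signals.shape[0]
    any_valid = valid.any(axis=1)
    first = np.argmax(valid, axis=1)
    last = valid.shape[1] - 1 - np.argmax(valid[:, ::-1], axis=1)
    rows = np.arange(n_pix)
    i_f = signals[rows, first]
    i_l = signals[rows, last]
    te_f = te[first]
    te_l = te[last]
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = (te_l - te_f) / np.log(i_f / i_l)
    bad = (
        ~any_valid
        | (last <= first)
        | (i_f <= 0)
        | (i_l <= 0)
        | (i_l >= i_f)
        | ~np.isfinite(t2)
        | (t2 <= 0)
    )
    t2 = np.where(bad, _T2_FALLBACK_INIT, t2)
    s0 = np.where(i_f > 0, i_f, 1.0) * np.exp(te_f / t2)
    return s0, np.log(t2)


def _fit_batch(
    signals: np.ndarray,
    te: np.ndarray,
    valid: np.ndarray,
    method: str,
    config: FitConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Levenberg–Marquardt over (S0, log T2) for a batch of pixels.

    Parameters are (P,) arrays; ``signals`` and ``valid`` are (P, E).
    Returns ``(s0, t2, merit, converged)``; pixels with no valid echoes come
    back unconverged with NaN parameters.
    """
    signals = np.asarray(signals, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n_pix = signals.shape[0]
    if n_pix == 0:
        z = np.empty(0)
        return z, z, z, np.empty(0, dtype=bool)

    w = signals.copy() if method == "wls" else np.ones_like(signals)
    w[~valid] = 0.0
    w = np.maximum(w, 0.0)
    sw = np.sqrt(w)

    s0, u = _initial_guess(signals, te, valid)
    fittable = valid.any(axis=1)

    def merit_of(s0v: np.ndarray, uv: np.ndarray, rows: np.ndarray) -> np.ndarray:
        m = s0v[:, None] * np.exp(-te[None, :] * np.exp(-uv[:, None]))
        return np.sum(w[rows] * (signals[rows] - m) ** 2, axis=1)

    phi = merit_of(s0, u, np.arange(n_pix))
    scale = np.sum(w * signals**2, axis=1) + 1e-30
    lam = np.full(n_pix, 1e-3)
    converged = np.zeros(n_pix, dtype=bool)
    active = fittable.copy()

    for _ in range(config.max_iterations):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        s0a, ua = s0[idx], u[idx]
        inv_t2 = np.exp(-ua)[:, None]
        decay = np.exp(-te[None, :] * inv_t2)  # (n, E)
        m = s0a[:, None] * decay
        r = sw[idx] * (signals[idx] - m)
        j0 = sw[idx] * decay                       # d m / d S0
        j1 = sw[idx] * m * te[None, :] * inv_t2    # d m / d u
        h00 = np.sum(j0 * j0, axis=1)
        h01 = np.sum(j0 * j1, axis=1)
        h11 = np.sum(j1 * j1, axis=1)
        g0 = np.sum(j0 * r, axis=1)
        g1 = np.sum(j1 * r, axis=1)

        a = h00 * (1.0 + lam[idx])
        c = h11 * (1.0 + lam[idx])
        det = a * c - h01**2
        ok = det > 1e-300
        det = np.where(ok, det, 1.0)
        ds0 = (c * g0 - h01 * g1) / det
        du = np.clip((a * g1 - h01 * g0) / det, -_MAX_LOG_T2_STEP, _MAX_LOG_T2_STEP)
        s0_new = s0a + np.where(ok, ds0, 0.0)
        u_new = np.clip(ua + np.where(ok, du, 0.0), *_LOG_T2_BOUNDS)

        phi_new = merit_of(s0_new, u_new, idx)
        accept = ok & (phi_new <= phi[idx])
        delta = phi[idx] - phi_new
        done_now = accept & (
            (delta <= config.convergence_tol * np.maximum(phi[idx], 1e-300))
            | (phi_new <= 1e-24 * scale[idx])
        )

        s0[idx[accept]] = s0_new[accept]
        u[idx[accept]] = u_new[accept]
        phi[idx[accept]] = phi_new[accept]
        lam[idx[accept]] = np.maximum(lam[idx[accept]] * 0.3, 1e-12)
        rej = ~accept
        lam[idx[rej]] = lam[idx[rej]] * 10.0
        # hopelessly damped pixels cannot move: stop them, unconverged
        stuck = rej & (lam[idx] > 1e14) | ~ok
        converged[idx[done_now]] = True
        active[idx[done_now | stuck]] = False

    t2 = np.exp(u)
    s0_out = np.where(fittable, s0, np.nan)
    t2_out = np.where(fittable, t2, np.nan)
    phi_out = np.where(fittable, phi, np.nan)
    converged &= fittable
    return s0_out, t2_out, phi_out, converged


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------


def fit_pixel(
    signal: np.ndarray, descriptor: AcquisitionDescriptor, config: FitConfig
) -> DecayModelParams | None:
    """Fit one pixel's decay; ``None`` when the pixel is invalid.

    A pixel is invalid when baseline subtraction leaves fewer than
    ``min_valid_points`` echoes, the optimizer fails to converge, or the
    fitted T2 exceeds ``t2_trim_max``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (descriptor.n_echoes,):
        raise ValueError(
            f"signal length {signal.shape} does not match n_echoes={descriptor.n_echoes}"
        )
    idx = baseline_subtract(signal, config.baseline_threshold, config.min_valid_points)
    if idx.size == 0:
        return None
    valid = np.zeros((1, descriptor.n_echoes), dtype=bool)
    valid[0, idx] = True
    s0, t2, _, conv = _fit_batch(
        signal[None, :], descriptor.echo_times, valid, config.method, config
    )
    if not conv[0]:
        logger.warning("pixel fit did not converge within %d iterations", config.max_iterations)
        return None
    if not (np.isfinite(s0[0]) and np.isfinite(t2[0])) or s0[0] <= 0 or t2[0] <= 0:
        return None
    if t2[0] > config.t2_trim_max:
        logger.debug("fitted T2 %.2f ms exceeds trim limit; pixel invalid", t2[0])
        return None
    return DecayModelParams(float(s0[0]), float(t2[0]))


def fit_stack(
    stack: EchoStack, config: FitConfig, roi: np.ndarray | None = None
) -> T2FitResult:
    """Fit every pixel of a stack (optionally restricted to ``roi``)."""
    shape = stack.image_shape
    if roi is None:
        roi = np.ones(shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != shape:
        raise ValueError(f"roi shape {roi.shape} does not match image shape {shape}")

    signals = stack.data.reshape(stack.descriptor.n_echoes, -1).T  # (P, E)
    flat_roi = roi.ravel()
    sel = signals[flat_roi]
    valid = sel >= config.baseline_threshold
    enough = valid.sum(axis=1) >= config.min_valid_points
    valid[~enough] = False

    s0, t2, phi, conv = _fit_batch(
        sel, stack.descriptor.echo_times, valid, config.method, config
    )
    good = (
        enough
        & conv
        & np.isfinite(t2)
        & np.isfinite(s0)
        & (s0 > 0)
        & (t2 > 0)
        & (t2 <= config.t2_trim_max)
    )
    n_pix = flat_roi.size
    s0_map = np.full(n_pix, INVALID_SENTINEL)
    t2_map = np.full(n_pix, INVALID_SENTINEL)
    res_map = np.full(n_pix, INVALID_SENTINEL)
    vmask = np.zeros(n_pix, dtype=bool)
    tgt = np.flatnonzero(flat_roi)
    s0_map[tgt[good]] = s0[good]
    t2_map[tgt[good]] = t2[good]
    res_map[tgt[good]] = phi[good]
    vmask[tgt[good]] = True
    n_unconverged = int((enough & ~conv).sum())
    if n_unconverged:
        logger.info("%d pixels did not converge and were marked invalid", n_unconverged)
    return T2FitResult(
        s0_map.reshape(shape), t2_map.reshape(shape), vmask.reshape(shape), res_map.reshape(shape)
    )


def _truncate_stack(stack: EchoStack, k: int) -> EchoStack:
    return EchoStack(stack.data[:k], stack.descriptor.with_n_echoes(k))


def compare_echo_subsets(
    stack: EchoStack,
    roi: np.ndarray,
    config: FitConfig,
    echo_counts: list[int],
) -> pd.DataFrame:
    """Refit with the first k echoes only, for LS and WLS, and summarize.

    Reproduces the phantom experiment comparing the sensitivity of LS and
    WLS to the number of echoes included (k from 5 to 10 in the original
    protocol).  Returns one row per (echo_count, method) with the mean/std
    of the fitted T2 and S0 over valid ROI pixels.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("roi is empty")
    for k in echo_counts:
        if not 2 <= k <= stack.descriptor.n_echoes:
            raise ValueError(f"echo count {k} outside [2, {stack.descriptor.n_echoes}]")
    rows = []
    for k in sorted(echo_counts):
        sub = _truncate_stack(stack, k)
        for method in ("ls", "wls"):
            res = fit_stack(sub, replace(config, method=method), roi)
            t2s = res.t2_map[res.valid_mask]
            s0s = res.s0_map[res.valid_mask]
            rows.append(
                {
                    "echo_count": k,
                    "method": method,
                    "n_valid": int(t2s.size),
                    "mean_t2": float(np.mean(t2s)) if t2s.size else np.nan,
                    "std_t2": float(np.std(t2s)) if t2s.size else np.nan,
                    "mean_s0": float(np.mean(s0s)) if s0s.size else np.nan,
                    "std_s0": float(np.std(s0s)) if s0s.size else np.nan,
                }
            )
    return pd.DataFrame(rows)
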