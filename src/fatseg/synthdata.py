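"""Digital phantoms: homogeneous lard tubes and two-compartment mouse slices.

Each tissue compartment is a set of elliptic/annular primitives carrying a
pseudo-proton density S0 and a transverse relaxation time T2; the echo
train is synthesized from the mono-exponential model

    S_i = S0 * exp(-(i * te) / T2)

echo by echo.  Partial volume is emulated by Gaussian-blurring the (S0, T2)
parameter fields before synthesis, coil/bias inhomogeneity by multiplying
S0 with a smooth low-frequency field, and noise by adding white Gaussian
noise scaled to hit a target first-echo SNR.  Ground-truth label and fat
masks come from the un-blurred geometry, so every generated data set ships
with its own reference segmentation.

Default tissue T2s (fat 60 ms, muscle 25 ms, free fluid 150 ms) are
well-separated fixture conventions, not biological claims, and are fully
configurable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibrate import compute_snr, corner_background_mask
from .io_formats import AcquisitionDescriptor, EchoStack

BACKGROUND_LABEL = 0

DEFAULT_DESCRIPTOR = AcquisitionDescriptor(te_spacing=8.3, n_echoes=10)


@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse; center/semi-axes in pixels of the base image size."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]

    def scaled(self, factor: float) -> "Ellipse":
        return Ellipse(
            (self.center[0] * factor, self.center[1] * factor),
            (self.semi_axes[0] * factor, self.semi_axes[1] * factor),
        )

    def contains(self, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
        return (
            ((rr - self.center[0]) / self.semi_axes[0]) ** 2
            + ((cc - self.center[1]) / self.semi_axes[1]) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class Annulus:
    """Elliptic ring: inside the outer ellipse, outside the inner one."""

    outer: Ellipse
    inner: Ellipse

    def scaled(self, factor: float) -> "Annulus":
        return Annulus(self.outer.scaled(factor), self.inner.scaled(factor))

    def contains(self, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
        return self.outer.contains(rr, cc) & ~self.inner.contains(rr, cc)


@dataclass(frozen=True)
class TissueSpec:
    """One tissue compartment: name, relaxation parameters and geometry."""

    name: str
    t2: float
    s0: float
    geometry: tuple = ()

    def __post_init__(self) -> None:
        if self.t2 <= 0 or self.s0 <= 0:
            raise ValueError("t2 and s0 must be positive")

    def mask(self, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
        out = np.zeros(rr.shape, dtype=bool)
        for shape in self.geometry:
            out |= shape.contains(rr, cc)
        return out


@dataclass(frozen=True)
class PhantomConfig:
    """A renderable scene at a reference resolution.

    Geometry is given in pixels of ``image_size``.
    ``partial_volume_blur_sigma`` is in pixels *of the rendered size* and is
    held fixed across resolutions: a voxel mixes tissue over its own
    footprint, so the physical extent of the mixing shrinks as the matrix
    size grows.  ``target_snr = None`` produces a noiseless stack.
    """

    image_size: int
    tissues: tuple[TissueSpec, ...]
    descriptor: AcquisitionDescriptor = DEFAULT_DESCRIPTOR
    partial_volume_blur_sigma: float = 0.0
    bias_field_amplitude: float = 0.0
    target_snr: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not self.tissues:
            raise ValueError("at least one tissue is required")


def _bias_field(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1 - amplitude, 1 + amplitude]."""
    if amplitude == 0.0:
        return np.ones((size, size))
    coarse = rng.normal(size=(4, 4))
    zoomed = gaussian_filter(
        np.kron(coarse, np.ones((size // 4 + 1, size // 4 + 1)))[:size, :size],
        sigma=size / 6.0,
        mode="nearest",
    )
    span = np.ptp(zoomed)
    if span == 0:
        return np.ones((size, size))
    return 1.0 + amplitude * (2.0 * (zoomed - zoomed.min()) / span - 1.0)


def _render_fields(
    config: PhantomConfig, size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(labels, s0_field, t2_field) at the requested size (pre-blur labels)."""
    factor = size / config.image_size
    rr, cc = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float), indexing="ij")
    labels = np.full((size, size), BACKGROUND_LABEL, dtype=int)
    s0_field = np.zeros((size, size))
    t2_field = np.zeros((size, size))
    for t_idx, tissue in enumerate(config.tissues, start=1):
        scaled = dataclasses.replace(
            tissue, geometry=tuple(g.scaled(factor) for g in tissue.geometry)
        )
        m = scaled.mask(rr, cc)
        labels[m] = t_idx
        s0_field[m] = tissue.s0
        t2_field[m] = tissue.t2
    return labels, s0_field, t2_field


def _synthesize(
    s0_field: np.ndarray, t2_field: np.ndarray, descriptor: AcquisitionDescriptor
) -> np.ndarray:
    te = descriptor.echo_times
    safe_t2 = np.where(t2_field > 0, t2_field, 1.0)
    decay = np.exp(-te[:, None, None] / safe_t2[None, :, :])
    decay[:, t2_field <= 0] = 0.0
    return s0_field[None, :, :] * decay


def generate_stack(
    config: PhantomConfig, size: int | None = None
) -> tuple[EchoStack, np.ndarray, np.ndarray]:
    """Render the scene and return ``(stack, label_image, fat_mask)``.

    The fat mask is the union of the tissues named ``"fat"`` in the
    un-blurred geometry.  Deterministic given ``config.rng_seed``.
    """
    size = config.image_size if size is None else size
    factor = size / config.image_size
    labels, s0_field, t2_field = _render_fields(config, size)
    rng = np.random.default_rng(config.rng_seed)

    blur = config.partial_volume_blur_sigma
    if blur > 0:
        s0_field = gaussian_filter(s0_field, blur, mode="nearest")
        t2_field = gaussian_filter(t2_field, blur, mode="nearest")
    s0_field = s0_field * _bias_field(size, config.bias_field_amplitude, rng)

    data = _synthesize(s0_field, t2_field, config.descriptor)
    if config.target_snr is not None:
        signal_roi = labels != BACKGROUND_LABEL
        background_roi = corner_background_mask((size, size)) & ~signal_roi
        if not signal_roi.any():
            raise ValueError("scene renders no tissue pixels; target SNR unreachable")
        mean_signal = float(data[0][signal_roi].mean())
        if mean_signal <= 0:
            raise ValueError("clean scene too dim to reach any target SNR")
        sigma = mean_signal / config.target_snr
        noisy = data + rng.normal(0.0, sigma, size=data.shape)
        achieved = compute_snr(noisy[0], signal_roi, background_roi)
        if abs(achieved - config.target_snr) / config.target_snr > 0.05:
            # one deterministic correction using the measured noise level
            sigma *= achieved / config.target_snr
            rng = np.random.default_rng(config.rng_seed)
            _ = _bias_field(size, config.bias_field_amplitude, rng)  # keep stream aligned
            noisy = data + rng.normal(0.0, sigma, size=data.shape)
        data = noisy

    stack = EchoStack(data, config.descriptor)
    fat_idx = [i for i, t in enumerate(config.tissues, start=1) if t.name == "fat"]
    fat_mask = np.isin(labels, fat_idx)
    return stack, labels, fat_mask


def resolution_series(
    config: PhantomConfig, sizes: list[int]
) -> list[tuple[EchoStack, np.ndarray, np.ndarray]]:
    """Render the same physical scene at several matrix sizes.

    Geometry scales proportionally while the partial-volume blur stays
    fixed in pixels (one voxel's worth of mixing), so its physical extent —
    and with it the boundary degradation — worsens at low resolution.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be sorted ascending")
    return [generate_stack(config, size=s) for s in sizes]


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def lard_phantom_config(
    size: int = 64,
    t2: float = 55.0,
    s0: float = 1000.0,
    target_snr: float | None = None,
    rng_seed: int = 0,
) -> PhantomConfig:
    """Uniform lard-tube phantom: one homogeneous disc on empty background."""
    tube = TissueSpec(
        name="lard",
        t2=t2,
        s0=s0,
        geometry=(Ellipse((size / 2, size / 2), (0.35 * size, 0.35 * size)),),
    )
    return PhantomConfig(
        image_size=size, tissues=(tube,), target_snr=target_snr, rng_seed=rng_seed
    )


def lard_signal_roi(size: int) -> np.ndarray:
    """Central ROI well inside the lard tube of :func:`lard_phantom_config`."""
    rr, cc = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float), indexing="ij")
    return Ellipse((size / 2, size / 2), (0.22 * size, 0.22 * size)).contains(rr, cc)


def mouse_config(
    size: int = 128,
    target_snr: float | None = 20.0,
    rng_seed: int = 0,
    fat_t2: float = 60.0,
    muscle_t2: float = 25.0,
    fluid_t2: float = 150.0,
    partial_volume_blur_sigma: float = 0.7,
    bias_field_amplitude: float = 0.05,
) -> PhantomConfig:
    """Axial mouse-like slice: subcutaneous fat ring, two visceral fat
    deposits, muscle body and a fluid pocket (geometry at base size 128)."""
    f = size / 128.0
    body_outer = Ellipse((64, 64), (46, 54))
    body_inner = Ellipse((64, 64), (36, 44))
    fat = TissueSpec(
        name="fat",
        t2=fat_t2,
        s0=1000.0,
        geometry=(
            Annulus(body_outer, body_inner),
            Ellipse((52, 58), (8, 10)),
            Ellipse((76, 74), (9, 7)),
        ),
    )
    muscle = TissueSpec(name="muscle", t2=muscle_t2, s0=800.0, geometry=(body_inner,))
    fluid = TissueSpec(name="fluid", t2=fluid_t2, s0=900.0, geometry=(Ellipse((64, 36), (6, 5)),))
    # painting order: muscle body first, fluid pocket, then fat on top
    tissues = (muscle, fluid, fat)
    if f != 1.0:
        tissues = tuple(
            dataclasses.replace(t, geometry=tuple(g.scaled(f) for g in t.geometry))
            for t in tissues
        )
    return PhantomConfig(
        image_size=size,
        tissues=tissues,
        partial_volume_blur_sigma=partial_volume_blur_sigma,
        bias_field_amplitude=bias_field_amplitude,
        target_snr=target_snr,
        rng_seed=rng_seed,
    )


def save_config(config: PhantomConfig, path: str | Path) -> Path:
    """Persist the scene description as JSON (geometry included)."""

    def encode(obj):
        if isinstance(obj, Ellipse):
            return {"shape": "ellipse", "center": list(obj.center), "semi_axes": list(obj.semi_axes)}
        if isinstance(obj, Annulus):
            return {"shape": "annulus", "outer": encode(obj.outer), "inner": encode(obj.inner)}
        raise TypeError(obj)

    payload = {
        "image_size": config.image_size,
        "descriptor": dataclasses.asdict(config.descriptor),
        "partial_volume_blur_sigma": config.partial_volume_blur_sigma,
        "bias_field_amplitude": config.bias_field_amplitude,
        "target_snr": config.target_snr,
        "rng_seed": config.rng_seed,
        "tissues": [
            {
                "name": t.name,
                "t2": t.t2,
                "s0": t.s0,
                "geometry": [encode(g) for g in t.geometry],
            }
            for t in config.tissues
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path
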