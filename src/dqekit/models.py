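"""Parametric ground-truth models of an electron-counting sensor and of an exposure.

A :class:`DetectorModel` describes the counting sensor with a handful of
interpretable parameters: a per-event localization point-spread kernel on the
(super-resolution) pixel grid, an optional long-tail backscatter kernel mixed
in with probability ``backscatter_fraction``, a counting efficiency, and the
internal/output frame rates that set the coincidence-loss regime.  The model is
both the input to the event-level simulator and the oracle for the analytic
MTF/DQE used by the recovery tests.

:class:`ExposureSpec` carries the acquisition scalars (dose rate, exposure
time, frame time, specimen pixel size) that every piece of dose arithmetic
consumes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectorModel",
    "ExposureSpec",
    "delta_kernel",
    "gaussian_kernel",
    "preset",
    "PRESETS",
]

_KERNEL_SUM_TOL = 1e-9


def delta_kernel() -> np.ndarray:
    """A 1x1 identity kernel: every event is recorded where it lands."""
    return np.ones((1, 1))


def gaussian_kernel(sigma: float, radius: int | None = None) -> np.ndarray:
    """Isotropic Gaussian localization kernel sampled on an integer offset grid.

    Parameters
    ----------
    sigma : float
        Standard deviation in kernel-grid pixels (super-resolution pixels when
        the detector counts in super-resolution mode).  ``sigma=0`` returns the
        delta kernel.
    radius : int, optional
        Half-width of the kernel support; defaults to ``ceil(4*sigma)``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return delta_kernel()
    if radius is None:
        radius = max(1, int(math.ceil(4.0 * sigma)))
    x = np.arange(-radius, radius + 1)
    g1 = np.exp(-0.5 * (x / sigma) ** 2)
    k = np.outer(g1, g1)
    return k / k.sum()


def _validate_kernel(k: np.ndarray, name: str) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    if k.ndim != 2 or k.shape[0] % 2 == 0 or k.shape[1] % 2 == 0:
        raise ValueError(f"{name} must be a 2D kernel with odd dimensions, got shape {k.shape}")
    if np.any(k < 0):
        raise ValueError(f"{name} must be element-wise non-negative")
    if abs(k.sum() - 1.0) > _KERNEL_SUM_TOL:
        raise ValueError(f"{name} must sum to 1 within {_KERNEL_SUM_TOL}, got {k.sum()!r}")
    return k


@dataclass(frozen=True)
class DetectorModel:
    """Parametric description of an electron-counting sensor.

    Attributes
    ----------
    sensor_rows, sensor_cols : int
        Sensor geometry in physical pixels.
    event_psf : ndarray
        Localization kernel for ordinary events, defined on the
        super-resolution pixel grid; non-negative, sums to 1.
    backscatter_fraction : float
        Probability in [0, 1) that an event is instead displaced by the
        long-tail ``backscatter_psf`` (electrons scattered back into the
        epilayer far from the entry point).
    backscatter_psf : ndarray
        Long-tail displacement kernel; non-negative, sums to 1.
    counting_efficiency : float
        Fraction in (0, 1] of incident electrons that produce a count,
        before coincidence loss.
    internal_frame_rate : float
        Rate of the internal counting frames (fps); current counting sensors
        run near 1500 fps, which keeps coincidence loss small below
        40 e-/pixel/s.
    output_frame_rate : float
        Rate of the summed frames delivered to the user (fps); must divide the
        internal rate to an integer.
    super_resolution_factor : int
        Sub-pixel localization factor (2 for super-resolution counting).
    """

    sensor_rows: int = 256
    sensor_cols: int = 256
    event_psf: np.ndarray = field(default_factory=delta_kernel)
    backscatter_fraction: float = 0.0
    backscatter_psf: np.ndarray = field(default_factory=delta_kernel)
    counting_efficiency: float = 1.0
    internal_frame_rate: float = 1500.0
    output_frame_rate: float = 75.0
    super_resolution_factor: int = 1

    def __post_init__(self) -> None:
        if self.sensor_rows < 1 or self.sensor_cols < 1:
            raise ValueError("sensor dimensions must be positive integers")
        object.__setattr__(self, "event_psf", _validate_kernel(self.event_psf, "event_psf"))
        object.__setattr__(
            self, "backscatter_psf", _validate_kernel(self.backscatter_psf, "backscatter_psf")
        )
        if not (0.0 <= self.backscatter_fraction < 1.0):
            raise ValueError("backscatter_fraction must be in [0, 1)")
        if not (0.0 < self.counting_efficiency <= 1.0):
            raise ValueError("counting_efficiency must be in (0, 1]")
        if not (self.internal_frame_rate >= self.output_frame_rate > 0):
            raise ValueError("need internal_frame_rate >= output_frame_rate > 0")
        ratio = self.internal_frame_rate / self.output_frame_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "internal_frame_rate must be an integer multiple of output_frame_rate"
            )
        if int(self.super_resolution_factor) != self.super_resolution_factor or (
            self.super_resolution_factor < 1
        ):
            raise ValueError("super_resolution_factor must be an integer >= 1")

    @property
    def internal_frames_per_output(self) -> int:
        return int(round(self.internal_frame_rate / self.output_frame_rate))

    @property
    def mixture_psf(self) -> np.ndarray:
        """The effective event-displacement kernel: event and backscatter mixed."""
        a, b = self.event_psf, self.backscatter_psf
        ra, rb = a.shape[0] // 2, b.shape[0] // 2
        ca, cb = a.shape[1] // 2, b.shape[1] // 2
        r, c = max(ra, rb), max(ca, cb)
        out = np.zeros((2 * r + 1, 2 * c + 1))
        out[r - ra : r + ra + 1, c - ca : c + ca + 1] += (1 - self.backscatter_fraction) * a
        out[r - rb : r + rb + 1, c - cb : c + cb + 1] += self.backscatter_fraction * b
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["event_psf"] = np.asarray(self.event_psf).tolist()
        d["backscatter_psf"] = np.asarray(self.backscatter_psf).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorModel":
        d = dict(d)
        d["event_psf"] = np.asarray(d["event_psf"], dtype=float)
        d["backscatter_psf"] = np.asarray(d["backscatter_psf"], dtype=float)
        return cls(**d)

    def content_hash(self) -> str:
        """Stable hash of the model parameters (used in output provenance)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class ExposureSpec:
    """Acquisition scalars for one exposure.

    dose_rate is in e-/pixel/s over *physical* pixels; pixel_size is the
    specimen-referred physical pixel size in Angstroms.
    """

    dose_rate: float
    exposure_time: float
    frame_time: float
    pixel_size: float

    def __post_init__(self) -> None:
        for name in ("dose_rate", "exposure_time", "frame_time", "pixel_size"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.exposure_time / self.frame_time))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _preset_ideal() -> DetectorModel:
    return DetectorModel()


def _preset_optimized() -> DetectorModel:
    # Tight localization, high efficiency, a whisper of backscatter.
    return DetectorModel(
        event_psf=gaussian_kernel(0.3),
        backscatter_fraction=0.02,
        backscatter_psf=gaussian_kernel(3.0, radius=9),
        counting_efficiency=0.95,
    )


def _preset_degraded() -> DetectorModel:
    # Broad charge spreading and heavy backscatter, as in a sensor not
    # optimized for low-voltage electrons.
    return DetectorModel(
        event_psf=gaussian_kernel(0.8),
        backscatter_fraction=0.15,
        backscatter_psf=gaussian_kernel(4.0, radius=12),
        counting_efficiency=0.6,
    )


PRESETS = {
    "ideal": _preset_ideal,
    "optimized": _preset_optimized,
    "degraded": _preset_degraded,
}


def preset(name: str) -> DetectorModel:
    """Return a named detector model (``ideal``, ``optimized``, ``degraded``)."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choices: {sorted(PRESETS)}") from None
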