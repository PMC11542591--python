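"""Event-level simulation of an electron-counting detector.

The simulator realizes the counting model behind the analytic oracles: within
each internal counting frame, electron arrivals on the sensor are a Poisson
point process (uniform for flat-field illumination, half-plane for a knife
edge).  Each arrival is counted with probability ``counting_efficiency`` and
its recorded position is displaced by a draw from the event localization
kernel — or, with probability ``backscatter_fraction``, from the long-tail
backscatter kernel.  At most one count is recorded per (super-resolution)
pixel per internal frame, which is the coincidence-loss mechanism; internal
frames are then summed into output frames.

Because counted events remain an independently thinned and displaced Poisson
point process (up to coincidence loss), the counts have a *flat* noise power
spectrum while the signal transfer carries the kernel and pixel-aperture MTF —
the property that gives counting detectors their DQE advantage.  The analytic
transfer functions :func:`analytic_mtf` and :func:`analytic_dqe` are exact in
the low-dose limit and serve as ground truth for the recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .curves import FrequencyCurve
from .errors import DataError
from .models import DetectorModel, ExposureSpec

__all__ = [
    "FrameStack",
    "EdgeImage",
    "simulate_flat_stack",
    "simulate_edge_image",
    "analytic_mtf",
    "analytic_dqe",
]

_MAX_LAMBDA = 10.0  # counting model invalid beyond this arrivals/pixel/internal-frame


@dataclass
class FrameStack:
    """A stack of counted output frames (frames x rows x cols)."""

    data: np.ndarray
    pixel_size: float  # physical pixel size at the specimen, A
    is_super_resolution: bool = False
    super_resolution_factor: int = 1
    frame_time: float | None = None  # s per output frame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError("FrameStack.data must be 3D (frames, rows, cols)")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise DataError("FrameStack.data must be integer-valued counts")
        if self.data.min(initial=0) < 0:
            raise DataError("counts must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def counted_rate(self) -> float:
        """Mean counted electrons per *physical* pixel per second."""
        if self.frame_time is None:
            raise DataError("frame_time unknown; cannot form a rate")
        sf = self.super_resolution_factor if self.is_super_resolution else 1
        n_phys = self.data.shape[1] * self.data.shape[2] / (sf * sf)
        return float(self.data.sum()) / (self.n_frames * self.frame_time * n_phys)


@dataclass
class EdgeImage:
    """A single knife-edge exposure (counts, summed over the exposure)."""

    data: np.ndarray
    nominal_orientation: str  # "horizontal" or "vertical"
    true_angle: float | None = None  # ground truth, only for simulated images
    pixel_size: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise DataError("EdgeImage.data must be 2D")
        if self.nominal_orientation not in ("horizontal", "vertical"):
            raise DataError("nominal_orientation must be 'horizontal' or 'vertical'")


def _sample_kernel(kernel: np.ndarray, n: int, rng: np.random.Generator):
    """Draw n integer (dy, dx) offsets from a normalized 2D kernel."""
    ry, rx = kernel.shape[0] // 2, kernel.shape[1] // 2
    p = kernel.ravel()
    # guard tiny negative rounding of the normalized kernel
    p = np.clip(p, 0, None)
    p = p / p.sum()
    idx = rng.choice(p.size, size=n, p=p)
    return idx // kernel.shape[1] - ry, idx % kernel.shape[1] - rx


def _simulate_counts(
    model: DetectorModel,
    dose_rate: float,
    n_internal: int,
    rng: np.random.Generator,
    region=None,
    boundary: str = "wrap",
    chunk_events: float = 4e6,
    sum_frames: bool = False,
) -> np.ndarray:
    """Core event engine.

    Returns output frames of shape (n_internal // internal_frames_per_output,
    rows*sf, cols*sf), or a single summed frame when ``sum_frames`` is set
    (cheaper for long single-image exposures).  ``region`` is an optional
    predicate over physical-pixel arrival coordinates (y, x) restricting
    illumination; ``boundary`` is "wrap" (periodic, for statistically uniform
    flats) or "drop" (events displaced off-sensor are lost, for edge
    exposures).
    """
    sf = model.super_resolution_factor
    nr, nc = model.sensor_rows, model.sensor_cols
    nrs, ncs = nr * sf, nc * sf
    npix_sr = nrs * ncs
    lam_pix = dose_rate / model.internal_frame_rate
    if lam_pix > _MAX_LAMBDA:
        raise DataError(
            f"expected arrivals/pixel/internal-frame = {lam_pix:.2f} > {_MAX_LAMBDA}; "
            "the one-count-per-pixel counting model is invalid at this dose rate"
        )
    ipo = model.internal_frames_per_output
    if n_internal % ipo:
        raise DataError("n_internal must be a multiple of internal_frames_per_output")
    n_out = 1 if sum_frames else n_internal // ipo
    lam_frame = lam_pix * nr * nc
    counts = np.zeros(n_out * npix_sr, dtype=np.int32)
    frames_per_chunk = max(1, int(chunk_events / max(lam_frame, 1.0)))
    has_bs = model.backscatter_fraction > 0

    f0 = 0
    while f0 < n_internal:
        fn = min(n_internal, f0 + frames_per_chunk)
        nev = rng.poisson(lam_frame, size=fn - f0)
        n = int(nev.sum())
        if n == 0:
            f0 = fn
            continue
        frame = np.repeat(np.arange(f0, fn, dtype=np.int64), nev)
        y = rng.uniform(0.0, nr, n)
        x = rng.uniform(0.0, nc, n)
        if model.counting_efficiency < 1.0:
            keep = rng.random(n) < model.counting_efficiency
            frame, y, x = frame[keep], y[keep], x[keep]
        if region is not None and len(x):
            keep = region(y, x)
            frame, y, x = frame[keep], y[keep], x[keep]
        n = len(x)
        if n == 0:
            f0 = fn
            continue
        dy = np.zeros(n, dtype=np.int64)
        dx = np.zeros(n, dtype=np.int64)
        bs = rng.random(n) < model.backscatter_fraction if has_bs else np.zeros(n, bool)
        for kern, mask in ((model.event_psf, ~bs), (model.backscatter_psf, bs)):
            m = int(mask.sum())
            if m == 0:
                continue
            if kern.shape == (1, 1):
                continue  # delta kernel: no displacement
            ddy, ddx = _sample_kernel(kern, m, rng)
            dy[mask] = ddy
            dx[mask] = ddx
        iy = np.floor(y * sf).astype(np.int64) + dy
        ix = np.floor(x * sf).astype(np.int64) + dx
        if boundary == "wrap":
            iy %= nrs
            ix %= ncs
        else:
            inside = (iy >= 0) & (iy < nrs) & (ix >= 0) & (ix < ncs)
            frame, iy, ix = frame[inside], iy[inside], ix[inside]
        pix = iy * ncs + ix
        # coincidence loss: one count max per super-resolution pixel per internal frame
        ukey = np.unique((frame - f0) * npix_sr + pix)
        uframe = ukey // npix_sr + f0
        upix = ukey - (uframe - f0) * npix_sr
        okey = upix if sum_frames else (uframe // ipo) * npix_sr + upix
        counts += np.bincount(okey, minlength=counts.size).astype(np.int32)
        f0 = fn
    return counts.reshape(n_out, nrs, ncs)


def simulate_flat_stack(
    model: DetectorModel,
    exposure: ExposureSpec,
    n_output_frames: int,
    seed: int,
) -> FrameStack:
    """Simulate a uniformly illuminated counted movie stack.

    Poisson arrivals at ``exposure.dose_rate`` per physical pixel per second,
    counted with the model's efficiency, PSF displacement, and per-internal-
    frame coincidence loss; internal frames are summed into output frames at
    the model's output frame rate.  Deterministic for a given seed.
    """
    if n_output_frames < 1:
        raise DataError("n_output_frames must be >= 1")
    if abs(exposure.frame_time * model.output_frame_rate - 1.0) > 1e-6:
        raise DataError(
            "exposure.frame_time inconsistent with model.output_frame_rate "
            f"({exposure.frame_time} s vs {1.0 / model.output_frame_rate} s)"
        )
    rng = np.random.default_rng(seed)
    n_internal = n_output_frames * model.internal_frames_per_output
    data = _simulate_counts(model, exposure.dose_rate, n_internal, rng, boundary="wrap")
    sf = model.super_resolution_factor
    return FrameStack(
        data=data,
        pixel_size=exposure.pixel_size,
        is_super_resolution=sf > 1,
        super_resolution_factor=sf,
        frame_time=exposure.frame_time,
        metadata={
            "seed": seed,
            "dose_rate": exposure.dose_rate,
            "model_hash": model.content_hash(),
        },
    )


def simulate_edge_image(
    model: DetectorModel,
    exposure: ExposureSpec,
    angle_deg: float,
    offset_pixels: float,
    orientation: str,
    seed: int,
) -> EdgeImage:
    """Simulate a slanted knife-edge exposure, summed over the full exposure.

    The knife edge is a straight line tilted ``angle_deg`` from the nominal
    orientation and shifted ``offset_pixels`` from the sensor center; arrivals
    occur only on the bright side.  The edge transition in the counted image
    is blurred only by the event/backscatter kernels and the pixel aperture.
    """
    if not (0.5 <= abs(angle_deg) <= 15.0):
        raise DataError(
            f"|angle| = {abs(angle_deg):.3g} deg outside the slanted-edge window [0.5, 15]"
        )
    if orientation not in ("horizontal", "vertical"):
        raise DataError("orientation must be 'horizontal' or 'vertical'")
    rng = np.random.default_rng(seed)
    nr, nc = model.sensor_rows, model.sensor_cols
    t = math.tan(math.radians(angle_deg))
    yc, xc = nr / 2.0, nc / 2.0

    if orientation == "vertical":
        # edge line x = xc + offset + tan(angle) * (y - yc); bright side x > line
        def region(y, x):
            return x > (xc + offset_pixels + t * (y - yc))

    else:
        def region(y, x):
            return y > (yc + offset_pixels + t * (x - xc))

    n_internal = int(round(exposure.exposure_time * model.internal_frame_rate))
    ipo = model.internal_frames_per_output
    n_internal = max(ipo, (n_internal // ipo) * ipo)
    frames = _simulate_counts(
        model, exposure.dose_rate, n_internal, rng, region=region, boundary="drop",
        sum_frames=True,
    )
    sf = model.super_resolution_factor
    return EdgeImage(
        data=frames[0].astype(np.int64),
        nominal_orientation=orientation,
        true_angle=angle_deg,
        pixel_size=exposure.pixel_size,
        metadata={
            "seed": seed,
            "dose_rate": exposure.dose_rate,
            "exposure_time": exposure.exposure_time,
            "offset_pixels": offset_pixels,
            "super_resolution_factor": sf,
            "model_hash": model.content_hash(),
        },
    )


def analytic_mtf(
    model: DetectorModel, frequencies: np.ndarray, axis: str = "x"
) -> FrequencyCurve:
    """Exact modulation transfer of the counting model along one axis.

    The counted image of a scene is the scene convolved with the mixture
    displacement kernel and the (super-resolution) pixel aperture, so

        MTF(f) = |DTFT of projected mixture kernel| * |sinc(f / sf)|

    with f in cycles per physical pixel and sf the super-resolution factor;
    normalized to 1 at f = 0.
    """
    f = np.asarray(frequencies, dtype=float)
    sf = model.super_resolution_factor
    mix = model.mixture_psf
    proj = mix.sum(axis=0) if axis == "x" else mix.sum(axis=1)
    offs = np.arange(len(proj)) - len(proj) // 2  # kernel-grid (sr pixel) offsets
    # DTFT of the discrete displacement distribution, offsets in physical pixels
    phase = np.exp(-2j * np.pi * np.outer(f, offs / sf))
    kernel_tf = np.abs(phase @ proj)
    aperture = np.abs(np.sinc(f / sf))
    values = kernel_tf * aperture
    if values[0] != 0 and f[0] == 0:
        values = values / values[0]
    return FrequencyCurve(
        f, values, "MTF", frequency_unit="cycles/pixel", metadata={"analytic": True, "axis": axis}
    )


def analytic_dqe(model: DetectorModel, frequencies: np.ndarray, axis: str = "x") -> FrequencyCurve:
    """Exact DQE of the counting model in the low-dose (no coincidence loss) limit.

    Counted events form an independently displaced point process, so the noise
    power spectrum is white and DQE(f) = counting_efficiency * MTF(f)^2.
    """
    mtf = analytic_mtf(model, frequencies, axis=axis)
    return FrequencyCurve(
        mtf.frequency,
        model.counting_efficiency * mtf.values**2,
        "DQE",
        frequency_unit="cycles/pixel",
        metadata={"analytic": True, "axis": axis},
    )
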