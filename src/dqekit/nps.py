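"""Noise power spectrum estimation from flat-field counted movie stacks.

Each frame is split into non-overlapping square tiles; every tile is
detrended and its 2D periodogram |FFT|^2 / area computed; periodograms are
averaged over all tiles and frames ("frame averaging"), then radially binned
into shells one Fourier sample wide.  The spectrum is normalized by the mean
counts per pixel so that an ideal Poisson counting detector gives NNPS = 1 at
every frequency.  The DC sample and the first radial shell are excluded from
the reported curve because detrending contaminates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import FrequencyCurve
from .errors import DataError
from .simulate import FrameStack

__all__ = ["NpsEstimate", "measure_nps", "nps_2d", "FlatFieldNPS", "NPSResults"]

_MIN_TILES = 8
_FIRST_REPORTED_SHELL = 2  # shells 0 (DC) and 1 are detrending-contaminated


def _tiles(frame: np.ndarray, tile: int) -> np.ndarray:
    """Non-overlapping tile view of a frame, shape (n_tiles, tile, tile)."""
    nr, nc = frame.shape
    tr, tc = nr // tile, nc // tile
    v = frame[: tr * tile, : tc * tile].reshape(tr, tile, tc, tile)
    return v.transpose(0, 2, 1, 3).reshape(tr * tc, tile, tile)


def _detrend(tiles: np.ndarray, mode: str) -> np.ndarray:
    if mode == "mean":
        return tiles - tiles.mean(axis=(1, 2), keepdims=True)
    if mode == "plane":
        t = tiles.shape[1]
        y, x = np.mgrid[0:t, 0:t].astype(float)
        y -= y.mean()
        x -= x.mean()
        denom_y = (y * y).sum()
        denom_x = (x * x).sum()
        out = tiles - tiles.mean(axis=(1, 2), keepdims=True)
        ay = np.tensordot(out, y, axes=([1, 2], [0, 1])) / denom_y
        ax = np.tensordot(out, x, axes=([1, 2], [0, 1])) / denom_x
        return out - ay[:, None, None] * y - ax[:, None, None] * x
    raise DataError("detrend must be 'mean' or 'plane'")


@dataclass
class NpsEstimate:
    """Radially averaged NNPS with its provenance."""

    radial: FrequencyCurve
    mean_counts_per_pixel: float
    n_frames: int
    n_tiles: int
    tile: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.radial.kind != "NNPS":
            raise DataError("NpsEstimate.radial must be a curve of kind NNPS")
        if not (self.mean_counts_per_pixel > 0):
            raise DataError("mean_counts_per_pixel must be > 0")
        if np.any(self.radial.values <= 0):
            raise DataError("NNPS values must be > 0")


def _averaged_periodogram(stack: FrameStack, tile: int, detrend: str):
    data = stack.data
    if data.ndim != 3 or data.shape[0] < 2:
        raise DataError("need a stack with >= 2 frames")
    if tile > min(data.shape[1], data.shape[2]):
        raise DataError("tile larger than the frame")
    n_frames = data.shape[0]
    acc = np.zeros((tile, tile))
    n_tiles_total = 0
    for i in range(n_frames):
        t = _detrend(_tiles(data[i].astype(float), tile), detrend)
        acc += (np.abs(np.fft.fft2(t, axes=(1, 2))) ** 2).sum(axis=0)
        n_tiles_total += t.shape[0]
    if n_tiles_total < _MIN_TILES:
        raise DataError(f"only {n_tiles_total} tiles in total (need >= {_MIN_TILES})")
    mean_counts = float(data.mean())
    if mean_counts <= 0 or float(data.std()) == 0:
        raise DataError("zero-variance or empty stack; no noise to measure")
    return acc / (n_tiles_total * tile * tile), mean_counts, n_frames, n_tiles_total


def nps_2d(stack: FrameStack, tile: int = 128, detrend: str = "mean") -> np.ndarray:
    """The tile- and frame-averaged 2D periodogram (unnormalized NPS).

    Diagnostic for anisotropy and fixed-pattern noise; layout follows
    numpy's fft2 (DC at [0, 0]).  The DC sample is excluded from any radial
    average downstream.
    """
    spec, _, _, _ = _averaged_periodogram(stack, tile, detrend)
    return spec


def measure_nps(stack: FrameStack, tile: int = 128, detrend: str = "mean") -> NpsEstimate:
    """Radially averaged, normalized noise power spectrum of a flat stack.

    NNPS(f) = NPS(f) / mean counts per pixel, with shells one Fourier sample
    of the tile wide; frequencies in cycles per *physical* pixel (the axis is
    scaled when the stack is super-resolution sampled).
    """
    spec, mean_counts, n_frames, n_tiles = _averaged_periodogram(stack, tile, detrend)
    k = np.fft.fftfreq(tile) * tile
    kx, ky = np.meshgrid(k, k, indexing="ij")
    shell = np.rint(np.sqrt(kx**2 + ky**2)).astype(np.int64)
    n_shells = tile // 2 + 1
    flat_shell = shell.ravel()
    flat_spec = spec.ravel()
    keep = flat_shell < n_shells
    sums = np.bincount(flat_shell[keep], weights=flat_spec[keep], minlength=n_shells)
    cnts = np.bincount(flat_shell[keep], minlength=n_shells)
    radial = sums / np.maximum(cnts, 1)
    sf = stack.super_resolution_factor if stack.is_super_resolution else 1
    freq = np.arange(n_shells) / tile * sf  # cycles per physical pixel
    s0 = _FIRST_REPORTED_SHELL
    nnps = radial[s0:] / mean_counts
    curve = FrequencyCurve(
        freq[s0:],
        nnps,
        "NNPS",
        frequency_unit="cycles/pixel",
        metadata={"tile": tile, "detrend": detrend, "first_shell": s0},
    )
    return NpsEstimate(
        radial=curve,
        mean_counts_per_pixel=mean_counts,
        n_frames=n_frames,
        n_tiles=n_tiles,
        tile=tile,
        metadata={"detrend": detrend},
    )


class FlatFieldNPS:
    """Estimator for the NNPS of a flat-field counted movie stack."""

    def __init__(self, stack: FrameStack, tile: int = 128, detrend: str = "mean"):
        self.stack = stack
        self.tile = tile
        self.detrend = detrend

    def fit(self) -> "NPSResults":
        est = measure_nps(self.stack, tile=self.tile, detrend=self.detrend)
        return NPSResults(estimate=est, model=self)


@dataclass
class NPSResults:
    estimate: NpsEstimate
    model: FlatFieldNPS = field(repr=False, default=None)

    @property
    def curve(self) -> FrequencyCurve:
        return self.estimate.radial

    def summary(self) -> str:
        e = self.estimate
        v = e.radial.values
        return "\n".join(
            [
                "Flat-field NNPS",
                "=" * 40,
                f"frames x tiles:        {e.n_frames} x {e.n_tiles // e.n_frames}"
                f" (tile {e.tile})",
                f"mean counts/pixel:     {e.mean_counts_per_pixel:.4f}",
                f"NNPS mean (all shells): {v.mean():.4f}",
                f"NNPS at Nyquist:       {v[-1]:.4f}",
            ]
        )
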