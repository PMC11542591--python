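"""Synthetic half-map pairs and subset-reconstruction FSC ensembles.

Both generators realize the standard spectral-SNR model of gold-standard
refinement: two independent reconstructions share a common signal and carry
independent noise, so the expected Fourier shell correlation at a shell with
per-half spectral SNR ``s`` is s/(s+1).  A subset reconstruction of N
particles whose per-particle SSNR at a shell is p has s = N*p, hence
E[FSC] = N*p/(N*p + 1) — the relation the per-particle SSNR analysis inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .curves import FrequencyCurve
from .errors import DataError

__all__ = [
    "HalfMapPair",
    "SubsetReconstruction",
    "simulate_half_maps",
    "simulate_subset_fscs",
]


@dataclass
class HalfMapPair:
    """Two independent reconstructions of the same structure."""

    map_a: np.ndarray
    map_b: np.ndarray
    voxel_size: float  # A
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.map_a = np.asarray(self.map_a, dtype=float)
        self.map_b = np.asarray(self.map_b, dtype=float)
        if self.map_a.shape != self.map_b.shape:
            raise DataError(
                f"half maps must share a shape, got {self.map_a.shape} vs {self.map_b.shape}"
            )
        if self.map_a.ndim != 3:
            raise DataError("half maps must be 3D volumes")
        if not (self.voxel_size > 0):
            raise DataError("voxel_size must be > 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=float)
            if self.mask.shape != self.map_a.shape:
                raise DataError("mask shape must match the maps")

    @property
    def box(self) -> int:
        return self.map_a.shape[0]

    def swapped(self) -> "HalfMapPair":
        return HalfMapPair(self.map_b, self.map_a, self.voxel_size, self.mask, dict(self.metadata))


@dataclass
class SubsetReconstruction:
    """An FSC curve from a reconstruction of n_particles particles."""

    fsc: FrequencyCurve
    n_particles: int

    def __post_init__(self) -> None:
        if self.fsc.kind != "FSC":
            raise DataError("SubsetReconstruction.fsc must be a curve of kind FSC")
        if self.n_particles <= 0:
            raise DataError("n_particles must be > 0")


def shell_radius_grid(box: int) -> np.ndarray:
    """Integer-rounded Fourier-voxel radius for a cubic box (full FFT layout)."""
    k = np.fft.fftfreq(box) * box
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    return np.rint(np.sqrt(kx**2 + ky**2 + kz**2)).astype(np.int64)


def simulate_half_maps(
    box: int,
    voxel_size: float,
    radial_half_ssnr: Callable[[np.ndarray], np.ndarray] | float,
    seed: int,
) -> HalfMapPair:
    """Generate a half-map pair with a prescribed per-shell per-half SSNR.

    A shared band-limited Gaussian random signal volume is added to
    independent white Gaussian noise in each half; the per-shell amplitude of
    the signal is set so that signal power / noise power equals
    ``radial_half_ssnr`` at that shell (``inf`` means a noiseless shell, and
    the half maps are then identical there).  Shells beyond the Nyquist sphere
    carry noise only.

    ``radial_half_ssnr`` may be a scalar or a vectorized function of shell
    frequency in 1/A.
    """
    if box < 8:
        raise DataError("box must be >= 8")
    if voxel_size <= 0:
        raise DataError("voxel_size must be > 0")
    rng = np.random.default_rng(seed)
    shells = shell_radius_grid(box)
    n_shells = box // 2 + 1
    shell_freq = np.arange(n_shells) / (box * voxel_size)
    if callable(radial_half_ssnr):
        s = np.asarray(radial_half_ssnr(shell_freq), dtype=float)
    else:
        s = np.full(n_shells, float(radial_half_ssnr))
    if s.shape != (n_shells,):
        raise DataError("radial_half_ssnr must return one value per shell")
    if np.any(s < 0):
        raise DataError("half-SSNR values must be >= 0")

    sig_amp = np.zeros(n_shells)
    noise_amp = np.ones(n_shells)
    finite = np.isfinite(s)
    sig_amp[finite] = np.sqrt(s[finite])
    sig_amp[~finite] = 1.0
    noise_amp[~finite] = 0.0

    # per-voxel radial filters; both signal and noise are band-limited to the
    # Nyquist sphere (corner voxels are zero), so a noiseless profile really
    # does produce identical half maps
    sig_vox = np.zeros_like(shells, dtype=float)
    noise_vox = np.zeros_like(shells, dtype=float)
    inside = shells < n_shells
    sig_vox[inside] = sig_amp[shells[inside]]
    noise_vox[inside] = noise_amp[shells[inside]]

    w0 = np.fft.fftn(rng.standard_normal((box, box, box)))
    wa = np.fft.fftn(rng.standard_normal((box, box, box)))
    wb = np.fft.fftn(rng.standard_normal((box, box, box)))
    map_a = np.fft.ifftn(w0 * sig_vox + wa * noise_vox).real
    map_b = np.fft.ifftn(w0 * sig_vox + wb * noise_vox).real
    return HalfMapPair(
        map_a,
        map_b,
        voxel_size,
        metadata={"seed": seed, "true_half_ssnr": s},
    )


def simulate_subset_fscs(
    per_particle_ssnr: FrequencyCurve,
    subset_sizes: Sequence[int],
    n_shell_samples: int,
    seed: int,
) -> list[SubsetReconstruction]:
    """Generate subset-reconstruction FSC curves from one per-particle SSNR profile.

    For a subset of N particles the per-half shell SSNR is N * ppSSNR(f); the
    realized FSC at each shell is the sample correlation of ``n_shell_samples``
    independent complex Fourier coefficients drawn from the shared-signal model,
    so both the expectation N*p/(N*p + 1) and the correlation-sampling noise
    are reproduced.
    """
    if per_particle_ssnr.kind not in ("PPSSNR", "SSNR"):
        raise DataError("per_particle_ssnr must be a curve of kind PPSSNR (or SSNR)")
    if n_shell_samples < 2:
        raise DataError("n_shell_samples must be >= 2")
    if len(subset_sizes) == 0:
        raise DataError("subset_sizes must be non-empty")
    rng = np.random.default_rng(seed)
    p = np.asarray(per_particle_ssnr.values, dtype=float)
    if np.any(p < 0):
        raise DataError("ppSSNR values must be >= 0")
    out = []
    nsh = len(p)
    m = int(n_shell_samples)

    def cnormal(size):
        return (rng.standard_normal(size) + 1j * rng.standard_normal(size)) / np.sqrt(2.0)

    for n_particles in subset_sizes:
        if n_particles <= 0:
            raise DataError("subset sizes must be positive")
        s = n_particles * p  # per-half shell SSNR
        sig = np.sqrt(s)[:, None] * cnormal((nsh, m))
        a = sig + cnormal((nsh, m))
        b = sig + cnormal((nsh, m))
        num = np.real(np.sum(a * np.conj(b), axis=1))
        den = np.sqrt(np.sum(np.abs(a) ** 2, axis=1) * np.sum(np.abs(b) ** 2, axis=1))
        fsc = np.clip(num / den, -1.0, 1.0)
        out.append(
            SubsetReconstruction(
                fsc=FrequencyCurve(
                    per_particle_ssnr.frequency.copy(),
                    fsc,
                    "FSC",
                    frequency_unit=per_particle_ssnr.frequency_unit,
                    metadata={"seed": seed, "n_shell_samples": m},
                ),
                n_particles=int(n_particles),
            )
        )
    return out
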