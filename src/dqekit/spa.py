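"""Single-particle map-quality metrics.

Fourier shell correlation between half maps and the 0.143 resolution
criterion; the FSC <-> SSNR relation SSNR = FSC/(1-FSC); per-particle SSNR
(ppSSNR = SSNR/N) averaged over subset reconstructions with error bars;
phase-randomization correction of mask-induced FSC; Guinier-plot B-factor
estimation; the linear Q-score <-> resolution calibration; and the dose
arithmetic used when planning and dose-weighting low-voltage exposures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .curves import FrequencyCurve
from .errors import DataError, NumericalError
from .mapsim import HalfMapPair, SubsetReconstruction, shell_radius_grid
from .models import ExposureSpec

__all__ = [
    "compute_fsc",
    "noise_substituted_fsc",
    "ResolutionResult",
    "resolution_at_threshold",
    "ssnr_from_fsc",
    "ppssnr_from_subsets",
    "soft_spherical_mask",
    "QCalibration",
    "DEFAULT_Q_CALIBRATION",
    "two_point_q_calibration",
    "qscore_to_resolution",
    "GuinierFit",
    "guinier_bfactor",
    "DoseReport",
    "cumulative_dose",
    "dose_weight_input_100kv",
    "SubsetSSNR",
    "PPSSNRResults",
    "GuinierModel",
]

FSC_THRESHOLD_DEFAULT = 0.143
_FSC_CLAMP_EPS = 1e-6

# Map-average Q-score vs resolution: the published linear fit, Q = intercept + slope*d.
_DEFAULT_Q_SLOPE = -0.1775  # Q per Angstrom
_DEFAULT_Q_INTERCEPT = 1.1192


# ---------------------------------------------------------------------------
# FSC
# ---------------------------------------------------------------------------

def _shell_sums(f1: np.ndarray, f2: np.ndarray, shells: np.ndarray, n_shells: int):
    num = np.bincount(shells.ravel(), weights=np.real(f1 * np.conj(f2)).ravel(),
                      minlength=n_shells)[:n_shells]
    p1 = np.bincount(shells.ravel(), weights=(np.abs(f1) ** 2).ravel(),
                     minlength=n_shells)[:n_shells]
    p2 = np.bincount(shells.ravel(), weights=(np.abs(f2) ** 2).ravel(),
                     minlength=n_shells)[:n_shells]
    return num, p1, p2


def compute_fsc(pair: HalfMapPair, mask: np.ndarray | None = None) -> FrequencyCurve:
    """Fourier shell correlation between the two half maps.

    Shells are one Fourier voxel wide out to the voxel Nyquist frequency; when
    a mask is given (or carried by the pair) it multiplies both maps before
    transforming.  The returned frequency axis is in 1/A.
    """
    a, b = pair.map_a, pair.map_b
    if a.shape[0] != a.shape[1] or a.shape[0] != a.shape[2]:
        raise DataError(f"FSC requires cubic volumes, got shape {a.shape}")
    if mask is None:
        mask = pair.mask
    if mask is not None:
        mask = np.asarray(mask, dtype=float)
        if mask.shape != a.shape:
            raise DataError("mask shape must match the maps")
        a = a * mask
        b = b * mask
    n = a.shape[0]
    shells = shell_radius_grid(n)
    n_shells = n // 2 + 1
    f1 = np.fft.fftn(a)
    f2 = np.fft.fftn(b)
    num, p1, p2 = _shell_sums(f1, f2, shells, n_shells)
    den = np.sqrt(p1 * p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    fsc = np.clip(fsc, -1.0, 1.0)
    freq = np.arange(n_shells) / (n * pair.voxel_size)
    # shell 0 is the DC term: identically 1 for any pair of nonzero-mean maps
    return FrequencyCurve(
        freq[1:],
        fsc[1:],
        "FSC",
        frequency_unit="1/A",
        metadata={"box": n, "voxel_size": pair.voxel_size, "masked": mask is not None},
    )


def _phase_randomized(vol: np.ndarray, shells: np.ndarray, beyond: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Replace Fourier phases beyond a shell cutoff, keeping amplitudes.

    The replacement phases are taken from the transform of a white random
    volume, which guarantees the Hermitian symmetry of a real map.
    """
    f = np.fft.fftn(vol)
    w = np.fft.fftn(rng.standard_normal(vol.shape))
    mag_w = np.abs(w)
    phase = np.where(mag_w > 0, w / np.maximum(mag_w, 1e-300), 1.0)
    sel = beyond[shells]
    f = np.where(sel, np.abs(f) * phase, f)
    return np.fft.ifftn(f).real


def noise_substituted_fsc(
    pair: HalfMapPair,
    mask: np.ndarray | None,
    randomization_resolution: float,
    seed: int = 0,
) -> FrequencyCurve:
    """Masked FSC corrected for mask-induced correlation by phase randomization.

    Phases of both half maps are randomized beyond ``randomization_resolution``
    (A); the masked FSC of the randomized pair (FSC_n) measures the spurious
    correlation introduced by the mask, and the corrected curve is
    (FSC_t - FSC_n)/(1 - FSC_n) beyond the randomization resolution, with the
    uncorrected masked FSC below it.
    """
    n = pair.box
    nyquist = 1.0 / (2.0 * pair.voxel_size)
    f_rand = 1.0 / randomization_resolution
    if f_rand >= nyquist:
        raise DataError(
            f"randomization resolution {randomization_resolution} A is finer than "
            f"Nyquist ({1.0 / nyquist:.3g} A)"
        )
    fsc_t = compute_fsc(pair, mask=mask)
    shells = shell_radius_grid(n)
    n_shells = n // 2 + 1
    shell_freq = np.arange(n_shells) / (n * pair.voxel_size)
    beyond = np.zeros(shells.max() + 1, dtype=bool)
    beyond[: n_shells] = shell_freq > f_rand
    beyond[n_shells:] = True
    rng = np.random.default_rng(seed)
    ra = _phase_randomized(pair.map_a, shells, beyond, rng)
    rb = _phase_randomized(pair.map_b, shells, beyond, rng)
    rand_pair = HalfMapPair(ra, rb, pair.voxel_size)
    fsc_n = compute_fsc(rand_pair, mask=mask)
    t = fsc_t.values
    nv = fsc_n.values
    out = t.copy()
    corr = fsc_t.frequency > f_rand
    denom = 1.0 - nv[corr]
    safe = np.abs(denom) > 1e-6
    corrected = np.where(safe, (t[corr] - nv[corr]) / np.where(safe, denom, 1.0), 0.0)
    out[corr] = np.clip(corrected, -1.0, 1.0)
    return FrequencyCurve(
        fsc_t.frequency,
        out,
        "FSC",
        frequency_unit="1/A",
        metadata={
            **fsc_t.metadata,
            "noise_substituted": True,
            "randomization_resolution_A": randomization_resolution,
        },
    )


class ResolutionResult(NamedTuple):
    resolution_A: float
    crossed: bool  # False: curve never fell below the threshold (Nyquist returned)


def resolution_at_threshold(
    fsc: FrequencyCurve, threshold: float = FSC_THRESHOLD_DEFAULT
) -> ResolutionResult:
    """Resolution at the first downward threshold crossing of an FSC curve.

    The crossing frequency is linearly interpolated between the bracketing
    shells; later re-crossings from noise are ignored.  If the curve never
    drops below the threshold the Nyquist (last-shell) resolution is returned
    with ``crossed=False``; a curve never above the threshold is rejected.
    """
    v = fsc.values
    f = fsc.frequency
    if len(v) < 2:
        raise DataError("FSC curve too short")
    if not np.any(v >= threshold):
        raise DataError(f"FSC never reaches the threshold {threshold}")
    above = v >= threshold
    for i in range(len(v) - 1):
        if above[i] and not above[i + 1]:
            f_cross = f[i] + (v[i] - threshold) / (v[i] - v[i + 1]) * (f[i + 1] - f[i])
            return ResolutionResult(float(1.0 / f_cross), True)
    return ResolutionResult(float(1.0 / f[-1]), False)


# ---------------------------------------------------------------------------
# SSNR / ppSSNR
# ---------------------------------------------------------------------------

def ssnr_from_fsc(fsc: FrequencyCurve) -> FrequencyCurve:
    """Spectral SNR from an FSC curve: SSNR = FSC / (1 - FSC).

    FSC values at or above 1 - 1e-6 are clamped (flagged in metadata), and
    negative FSC maps to SSNR = 0 (likewise flagged).
    """
    v = np.asarray(fsc.values, dtype=float)
    clamped_high = v >= 1.0 - _FSC_CLAMP_EPS
    clamped_neg = v < 0.0
    v = np.clip(v, 0.0, 1.0 - _FSC_CLAMP_EPS)
    ssnr = v / (1.0 - v)
    return FrequencyCurve(
        fsc.frequency.copy(),
        ssnr,
        "SSNR",
        frequency_unit=fsc.frequency_unit,
        metadata={
            **fsc.metadata,
            "n_clamped_high": int(clamped_high.sum()),
            "n_clamped_negative": int(clamped_neg.sum()),
        },
    )


def ppssnr_from_subsets(
    subsets: Sequence[SubsetReconstruction],
    truncate_threshold: float = FSC_THRESHOLD_DEFAULT,
) -> FrequencyCurve:
    """Per-particle SSNR averaged across subset reconstructions.

    Each subset's SSNR curve is divided by its particle count; the per-shell
    mean is taken in the linear domain and the per-shell standard deviation
    across subsets is reported as the spread.  The curve is truncated at the
    frequency where the *smallest* subset's FSC first falls below the 0.143
    threshold, and ln(mean ppSSNR) is recorded in the metadata for plotting.
    """
    if len(subsets) < 2:
        raise DataError("need >= 2 subset reconstructions")
    f0 = subsets[0].fsc.frequency
    for s in subsets[1:]:
        if len(s.fsc.frequency) != len(f0) or np.max(np.abs(s.fsc.frequency - f0)) > 1e-9:
            raise DataError("subset FSC curves must share a frequency grid")
    pp = np.vstack(
        [ssnr_from_fsc(s.fsc).values / s.n_particles for s in subsets]
    )
    mean = pp.mean(axis=0)
    spread = pp.std(axis=0, ddof=0)
    smallest = min(subsets, key=lambda s: s.n_particles)
    res = resolution_at_threshold(smallest.fsc, truncate_threshold)
    f_cut = 1.0 / res.resolution_A
    keep = f0 <= f_cut + 1e-12
    with np.errstate(divide="ignore"):
        ln_mean = np.log(mean[keep])
    return FrequencyCurve(
        f0[keep],
        mean[keep],
        "PPSSNR",
        spread=spread[keep],
        frequency_unit=subsets[0].fsc.frequency_unit,
        metadata={
            "n_subsets": len(subsets),
            "subset_sizes": sorted(s.n_particles for s in subsets),
            "truncated_at_frequency": float(f_cut),
            "truncate_threshold": truncate_threshold,
            "ln_mean": ln_mean,
        },
    )


def soft_spherical_mask(box: int, radius: float, soft_width: float = 3.0) -> np.ndarray:
    """Soft-edged spherical mask: 1 inside, cosine rolloff over soft_width voxels."""
    c = (box - 1) / 2.0
    z, y, x = np.mgrid[0:box, 0:box, 0:box].astype(float)
    r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
    m = np.clip((r - radius) / max(soft_width, 1e-9), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * m))


# ---------------------------------------------------------------------------
# Q-score calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCalibration:
    """Linear map-average Q-score vs resolution calibration: Q = intercept + slope*d."""

    slope: float = _DEFAULT_Q_SLOPE  # Q per A, negative
    intercept: float = _DEFAULT_Q_INTERCEPT  # Q at d = 0

    def __post_init__(self) -> None:
        if not (self.slope < 0):
            raise DataError("QCalibration.slope must be negative")


DEFAULT_Q_CALIBRATION = QCalibration()


def two_point_q_calibration(
    q1: float, d1: float, q2: float, d2: float
) -> QCalibration:
    """Calibration through two (Q, resolution) anchor pairs, for sensitivity checks."""
    if d1 == d2:
        raise DataError("anchor resolutions must differ")
    slope = (q2 - q1) / (d2 - d1)
    return QCalibration(slope=slope, intercept=q1 - slope * d1)


def qscore_to_resolution(
    q: float, calibration: QCalibration = DEFAULT_Q_CALIBRATION
) -> float:
    """Invert the linear Q-vs-resolution calibration: d = (intercept - Q)/(-slope)."""
    if not (0.0 < q < calibration.intercept):
        raise DataError(
            f"Q = {q} outside the invertible range (0, {calibration.intercept})"
        )
    return (calibration.intercept - q) / (-calibration.slope)


# ---------------------------------------------------------------------------
# Guinier B-factor
# ---------------------------------------------------------------------------

@dataclass
class GuinierFit:
    """Least-squares Guinier line: ln(amplitude) vs 1/d^2 over [d_min, d_max]."""

    d_max: float  # A, low-resolution end (larger)
    d_min: float  # A, high-resolution end (smaller)
    slope: float  # A^2, slope of ln A vs 1/d^2
    b_factor: float  # A^2, -4 * slope
    intercept: float = 0.0
    n_shells: int = 0

    def summary(self) -> str:
        return "\n".join(
            [
                "Guinier B-factor fit",
                "=" * 40,
                f"resolution range:  {self.d_max:g} - {self.d_min:g} A",
                f"shells used:       {self.n_shells}",
                f"slope:             {self.slope:.4f} A^2",
                f"B-factor (-4m):    {self.b_factor:.1f} A^2",
            ]
        )


def guinier_bfactor(
    amplitudes: FrequencyCurve, d_max: float, d_min: float
) -> GuinierFit:
    """Fit the Guinier line to spherically averaged structure-factor amplitudes.

    ``amplitudes`` is a curve of amplitude vs spatial frequency in 1/A; the
    fit of ln(amplitude) against 1/d^2 = f^2 is restricted to resolutions
    d in [d_min, d_max] and the B-factor is -4 times the slope.
    """
    if not (d_max > d_min > 0):
        raise DataError("need d_max > d_min > 0")
    f = amplitudes.frequency
    a = amplitudes.values
    sel = (f >= 1.0 / d_max) & (f <= 1.0 / d_min) & (a > 0)
    if sel.sum() < 4:
        raise DataError(
            f"only {int(sel.sum())} shells with positive amplitude in "
            f"[{d_min}, {d_max}] A (need >= 4)"
        )
    x = f[sel] ** 2  # 1/d^2
    y = np.log(a[sel])
    slope, intercept = np.polyfit(x, y, 1)
    return GuinierFit(
        d_max=d_max,
        d_min=d_min,
        slope=float(slope),
        b_factor=float(-4.0 * slope),
        intercept=float(intercept),
        n_shells=int(sel.sum()),
    )


class GuinierModel:
    """Estimator for the Guinier B-factor of a radial amplitude spectrum."""

    def __init__(self, amplitudes: FrequencyCurve, d_max: float = 7.0, d_min: float = 2.7):
        self.amplitudes = amplitudes
        self.d_max = d_max
        self.d_min = d_min

    def fit(self) -> GuinierFit:
        return guinier_bfactor(self.amplitudes, self.d_max, self.d_min)


# ---------------------------------------------------------------------------
# Dose arithmetic
# ---------------------------------------------------------------------------

class DoseReport(NamedTuple):
    total: float  # e-/A^2
    per_frame: float  # e-/A^2
    n_frames: int


def cumulative_dose(exposure: ExposureSpec) -> DoseReport:
    """Cumulative specimen dose of an exposure.

    total = dose_rate * exposure_time / pixel_size^2 (e-/A^2), split evenly
    over n_frames = round(exposure_time / frame_time) frames.
    """
    total = exposure.dose_rate * exposure.exposure_time / exposure.pixel_size**2
    n_frames = exposure.n_frames
    if n_frames < 1:
        raise DataError("exposure shorter than one frame")
    return DoseReport(total=total, per_frame=total / n_frames, n_frames=n_frames)


DOSE_WEIGHT_FACTOR_100KV = 1.57


def dose_weight_input_100kv(total_dose: float) -> float:
    """Scaled cumulative exposure to feed 300 keV dose-weighting code at 100 keV.

    Motion-correction software that only knows the 300 keV critical-dose curve
    underestimates damage at 100 keV, where the inelastic cross-section is
    1.57-fold larger; passing 1.57x the true cumulative exposure compensates.
    """
    if total_dose < 0:
        raise DataError("total_dose must be >= 0")
    return DOSE_WEIGHT_FACTOR_100KV * total_dose


# ---------------------------------------------------------------------------
# Estimator classes
# ---------------------------------------------------------------------------

class SubsetSSNR:
    """Estimator for the per-particle SSNR from subset reconstructions."""

    def __init__(
        self,
        subsets: Sequence[SubsetReconstruction],
        truncate_threshold: float = FSC_THRESHOLD_DEFAULT,
    ):
        self.subsets = list(subsets)
        self.truncate_threshold = truncate_threshold

    def fit(self) -> "PPSSNRResults":
        curve = ppssnr_from_subsets(self.subsets, self.truncate_threshold)
        return PPSSNRResults(curve=curve, model=self)


@dataclass
class PPSSNRResults:
    curve: FrequencyCurve
    model: SubsetSSNR = field(repr=False, default=None)

    @property
    def ln_curve(self) -> np.ndarray:
        return self.curve.metadata["ln_mean"]

    def summary(self) -> str:
        md = self.curve.metadata
        return "\n".join(
            [
                "Per-particle SSNR",
                "=" * 40,
                f"subsets:            {md['n_subsets']} (N = {md['subset_sizes']})",
                f"shells reported:    {len(self.curve)}",
                f"truncated at:       {md['truncated_at_frequency']:.4g} 1/A "
                f"(FSC {md['truncate_threshold']} of the smallest subset)",
                f"ln ppSSNR range:    [{self.ln_curve.min():.2f}, {self.ln_curve.max():.2f}]",
            ]
        )
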