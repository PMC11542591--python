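"""Tagged 1D curves over spatial frequency (MTF, NNPS, DQE, FSC, SSNR, ppSSNR)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FrequencyCurve", "CURVE_KINDS", "to_fraction_of_nyquist"]

CURVE_KINDS = ("MTF", "NNPS", "DQE", "FSC", "SSNR", "PPSSNR")


@dataclass
class FrequencyCurve:
    """A 1D curve sampled on a strictly increasing frequency grid.

    The frequency unit is cycles per physical pixel for detector curves and
    1/Angstrom for map curves; which one applies is recorded in ``frequency_unit``
    and conversions are always explicit (see :func:`to_fraction_of_nyquist`).

    ``spread`` is an optional per-point standard deviation (e.g. across repeat
    edge measurements or subset reconstructions).
    """

    frequency: np.ndarray
    values: np.ndarray
    kind: str
    spread: np.ndarray | None = None
    frequency_unit: str = "cycles/pixel"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"kind must be one of {CURVE_KINDS}, got {self.kind!r}")
        if self.frequency.ndim != 1 or self.frequency.shape != self.values.shape:
            raise ValueError("frequency and values must be 1D arrays of equal length")
        if len(self.frequency) and np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequency must be strictly increasing")
        if self.spread is not None:
            self.spread = np.asarray(self.spread, dtype=float)
            if self.spread.shape != self.values.shape:
                raise ValueError("spread must match values in shape")
        if self.kind == "FSC" and len(self.values):
            if np.any(self.values > 1 + 1e-9) or np.any(self.values < -1 - 1e-9):
                raise ValueError("FSC values must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.frequency)

    def interp(self, frequency: np.ndarray) -> np.ndarray:
        """Linear interpolation of the curve values onto a new grid."""
        return np.interp(np.asarray(frequency, dtype=float), self.frequency, self.values)

    def restricted(self, fmax: float) -> "FrequencyCurve":
        m = self.frequency <= fmax + 1e-12
        return FrequencyCurve(
            self.frequency[m],
            self.values[m],
            self.kind,
            None if self.spread is None else self.spread[m],
            self.frequency_unit,
            dict(self.metadata),
        )

    def to_dataframe(self, pixel_size: float | None = None) -> pd.DataFrame:
        """Tabular form with a fraction-of-Nyquist column.

        For detector curves (cycles/pixel) physical Nyquist is 0.5; for map
        curves (1/A) a ``pixel_size`` is required to place Nyquist.
        """
        if self.frequency_unit == "cycles/pixel":
            frac = self.frequency / 0.5
            fcol = "frequency_cyc_per_pixel"
        else:
            fcol = "frequency_inv_A"
            if pixel_size is None:
                frac = np.full_like(self.frequency, np.nan)
            else:
                frac = self.frequency * (2.0 * pixel_size)
        df = pd.DataFrame(
            {fcol: self.frequency, "fraction_nyquist": frac, "value": self.values}
        )
        if self.spread is not None:
            df["spread"] = self.spread
        return df


def to_fraction_of_nyquist(curve: FrequencyCurve, pixel_size: float | None = None) -> FrequencyCurve:
    """Rescale the frequency axis to fractions of the physical Nyquist frequency.

    For a curve in 1/A the Nyquist frequency is 1/(2*pixel_size); for a curve
    in cycles per physical pixel it is 0.5 and ``pixel_size`` is ignored.
    Values are unchanged.
    """
    if curve.frequency_unit == "fraction_nyquist":
        return curve
    if curve.frequency_unit == "cycles/pixel":
        scale = 2.0
    elif curve.frequency_unit == "1/A":
        if pixel_size is None or pixel_size <= 0:
            raise ValueError("pixel_size (A) required to rescale a 1/A curve")
        scale = 2.0 * pixel_size
    else:
        raise ValueError(f"unknown frequency unit {curve.frequency_unit!r}")
    return FrequencyCurve(
        curve.frequency * scale,
        curve.values.copy(),
        curve.kind,
        None if curve.spread is None else curve.spread.copy(),
        "fraction_nyquist",
        dict(curve.metadata),
    )
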