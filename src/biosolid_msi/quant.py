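"""Standard-curve quantification with per-sample extinction factors.

MALDI signal on a biosolid deposit is attenuated relative to the bare
slide (the imaging analogue of an LC matrix effect).  Quantification
therefore proceeds in four steps: fit an ordinary least-squares standard
curve from a dilution series spotted on the slide; measure the same top
amount spiked onto the sample and subtract the sample's own background
signal; form the extinction factor E = (spike - background) / (top slide
spot); rescale the curve by E and read the sample's background signal off
the rescaled curve, converting to a mass concentration with the deposited
biosolid mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "QuantResult",
    "fit_curve",
    "extinction_factor",
    "quantify",
    "spot_signal",
]

E_FLAG_LIMIT = 1.5  # E above this is rejected, above 1 flagged as enhancement
DEFAULT_DEPOSIT_MASS_G = 0.08  # 160 uL of a 1 g / 2 mL suspension


@dataclass
class StandardCurve:
    amounts: np.ndarray
    signals: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    unit: str = "ug"

    def predict(self, amount: float) -> float:
        return self.slope * amount + self.intercept

    def rescaled(self, e: float) -> "StandardCurve":
        """Curve attenuated by an extinction factor (slope and intercept
        both scale, keeping the calibration ratio-consistent)."""
        return StandardCurve(
            amounts=self.amounts.copy(),
            signals=self.signals * e,
            slope=self.slope * e,
            intercept=self.intercept * e,
            r_squared=self.r_squared,
            unit=self.unit,
        )


@dataclass
class QuantResult:
    analyte: str
    extinction: float
    amount_per_deposit: float  # in curve units
    unit: str
    deposit_mass_g: float
    concentration_mg_per_kg: float | None
    flags: list[str]


def fit_curve(points: list[tuple[float, float]], unit: str = "ug") -> StandardCurve:
    """Ordinary least squares I = a*q + b over (amount, signal) points.

    Requires at least two distinct amounts; a calibration with a
    non-positive slope is flagged downstream rather than rejected here.
    """
    if len(points) < 2:
        raise ValueError("need at least two calibration points")
    q = np.asarray([p[0] for p in points], dtype=float)
    i = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(q).size < 2:
        raise ValueError("calibration amounts are not distinct")
    res = stats.linregress(q, i)
    return StandardCurve(
        amounts=q,
        signals=i,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0,
        unit=unit,
    )


def extinction_factor(
    i_spike_on_sample: float, i_background: float, i_top_on_slide: float
) -> float:
    """E = (spike-on-sample - sample background) / (same amount on slide).

    E = 1 means no matrix effect; E < 1 signal extinction; E in (1, 1.5]
    is tolerated as enhancement (flagged by the caller); E <= 0 means the
    spike is indistinguishable from background and is an error.
    """
    if i_top_on_slide <= 0:
        raise ValueError("on-slide top spot signal must be positive")
    e = (i_spike_on_sample - i_background) / i_top_on_slide
    if e <= 0:
        raise ValueError("spike signal not above sample background; extinction undefined")
    if e > E_FLAG_LIMIT:
        raise ValueError(f"extinction factor {e:.3g} above plausibility limit {E_FLAG_LIMIT}")
    return e


def quantify(
    i_background: float,
    curve: StandardCurve,
    e: float,
    deposit_mass_g: float = DEFAULT_DEPOSIT_MASS_G,
    analyte: str = "",
    molar_mass: float | None = None,
) -> QuantResult:
    """Read the sample's analyte signal off the E-rescaled standard curve.

    ``q_s = (I_background - E*b) / (E*a)`` in curve units; a negative
    amount is clipped to zero and flagged.  Molar curve units (pmol)
    require a molar mass for the mass-concentration conversion; the
    concentration is ``q_s`` as mass divided by the deposited biosolid dry
    mass, reported in mg/kg.
    """
    if deposit_mass_g <= 0:
        raise ValueError("deposit mass must be positive")
    flags: list[str] = []
    if e > 1.0:
        flags.append("enhancement")  # E > 1: matrix boosts rather than extinguishes
    scaled = curve.rescaled(e)
    if scaled.slope == 0:
        raise ValueError("rescaled curve has zero slope")
    q_s = (i_background - scaled.intercept) / scaled.slope
    if q_s < 0:
        q_s = 0.0
        flags.append("clipped_negative")
    if curve.unit == "ug":
        mass_g = q_s * 1e-6
    elif curve.unit == "pmol":
        if molar_mass is None:
            mass_g = None
            flags.append("no_molar_mass")
        else:
            mass_g = q_s * 1e-12 * molar_mass
    else:
        raise ValueError(f"unknown curve unit {curve.unit!r}")
    conc = None if mass_g is None else mass_g / deposit_mass_g * 1e6  # g/g -> mg/kg
    return QuantResult(
        analyte=analyte,
        extinction=e,
        amount_per_deposit=q_s,
        unit=curve.unit,
        deposit_mass_g=deposit_mass_g,
        concentration_mg_per_kg=conc,
        flags=flags,
    )


def spot_signal(image: np.ndarray, cx: int, cy: int, radius_px: int) -> float:
    """Total (summed) ion-image intensity over a circular spot ROI; the sum
    rather than the mean makes the readout robust to spot-size variation."""
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    roi = np.hypot(xx - cx, yy - cy) <= radius_px
    return float(image[roi].sum())
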