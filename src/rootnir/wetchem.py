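"""Acetyl-bromide lignin quantification arithmetic.

Lignin solubilized with acetyl bromide is quantified by UV absorbance at
280 nm.  The blank-corrected optical density, scaled by the dilution factor
and the sample weight, gives the specific absorption coefficient

    SAC = (OD_S - OD_B) * F / W_d        [mL cm^-1 mg^-1]

which a calibration line maps to lignin content as percent of dry mass:

    L = (SAC - intercept) * 100 / slope_denominator

with the study calibration intercept 0.05 and denominator 13.06.  The cuvette
path length d (1 cm standard) appears in the units but not in the printed
formula; it is carried as a field and assumed 1 cm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class AbsorbanceReading:
    """One replicate UV reading at 280 nm."""

    od_sample: float
    od_blank: float
    weight_mg: float
    dilution_factor: float = 50.0
    path_cm: float = 1.0

    def __post_init__(self):
        if self.weight_mg <= 0:
            raise ValueError(f"sample weight must be positive, got {self.weight_mg}")
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be positive")
        if self.path_cm <= 0:
            raise ValueError("cuvette path must be positive")


@dataclass
class CalibrationCurve:
    """SAC -> lignin% line: L = (SAC - intercept) * 100 / slope_denominator."""

    intercept: float = 0.05
    slope_denominator: float = 13.06

    def __post_init__(self):
        if self.slope_denominator <= 0:
            raise ValueError("slope_denominator must be positive")


DEFAULT_CURVE = CalibrationCurve()


@dataclass
class SacEstimate:
    replicate_sacs: list
    sample_sac: float = field(init=False)

    def __post_init__(self):
        self.sample_sac = float(np.mean(self.replicate_sacs))


@dataclass
class LigninContent:
    """Lignin as % of dry mass; out-of-range values are flagged, never clipped."""

    percent: float
    out_of_range: bool = False


def compute_sac(reading: AbsorbanceReading) -> float:
    """Specific absorption coefficient of one replicate.

    A negative SAC (sample darker than blank reversed) is returned with a
    warning rather than rejected, so questionable readings stay visible in QC.
    """
    sac = (reading.od_sample - reading.od_blank) * reading.dilution_factor / reading.weight_mg
    if sac < 0:
        warnings.warn(
            f"sample OD {reading.od_sample} below blank OD {reading.od_blank}: "
            f"negative SAC {sac:.4g}"
        )
    return sac


def average_replicates(sacs) -> SacEstimate:
    """Per-sample SAC as the arithmetic mean over replicates (2-4 expected)."""
    sacs = list(sacs)
    if not sacs:
        raise ValueError("at least one replicate SAC is required")
    if not 2 <= len(sacs) <= 4:
        warnings.warn(f"{len(sacs)} replicates is outside the expected range 2-4")
    return SacEstimate(replicate_sacs=sacs)


def sac_to_lignin(sac: float, curve: CalibrationCurve = DEFAULT_CURVE) -> LigninContent:
    """Map a SAC value to lignin content through the calibration line."""
    pct = (sac - curve.intercept) * 100.0 / curve.slope_denominator
    return LigninContent(percent=pct, out_of_range=not (0.0 <= pct <= 100.0))


def lignin_to_sac(lignin_pct: float, curve: CalibrationCurve = DEFAULT_CURVE) -> float:
    """Inverse of :func:`sac_to_lignin` (used to build fixtures and standards)."""
    return curve.intercept + curve.slope_denominator * lignin_pct / 100.0


def fit_calibration_curve(standards) -> CalibrationCurve:
    """OLS calibration line from (lignin_pct, SAC) standards.

    Parameters
    ----------
    standards : sequence of (float, float)
        Pairs of known lignin amount (% of dry mass) and measured SAC,
        at least three, spanning a positive range.
    """
    standards = list(standards)
    if len(standards) < 3:
        raise ValueError("at least 3 calibration standards are required")
    amounts = np.array([s[0] for s in standards], dtype=float)
    sacs = np.array([s[1] for s in standards], dtype=float)
    if np.ptp(amounts) <= 0:
        raise ValueError("calibration standards are degenerate (all same amount)")
    slope_per_pct, intercept = np.polyfit(amounts, sacs, 1)
    return CalibrationCurve(intercept=float(intercept),
                            slope_denominator=float(slope_per_pct * 100.0))


def replicate_spread(replicate_lignins, variant: str = "sd") -> float:
    """Pooled replicate spread of lignin determinations, in % lignin.

    Parameters
    ----------
    replicate_lignins : mapping or sequence of sequences
        Per-sample replicate lignin values (each sample needs >= 2 replicates
        to contribute; samples with fewer are ignored).
    variant : {"sd", "se"}
        ``sd`` pools the replicate standard deviation,
        sqrt(sum_i sum_j (x_ij - xbar_i)^2 / sum_i (n_i - 1));
        ``se`` pools the standard error of the per-sample mean instead
        (each sample's squared deviations divided by its replicate count).
    """
    if hasattr(replicate_lignins, "values") and not isinstance(replicate_lignins, np.ndarray):
        groups = list(replicate_lignins.values())
    else:
        groups = list(replicate_lignins)
    ss, dof = 0.0, 0
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            continue
        dev2 = float(np.sum((g - g.mean()) ** 2))
        if variant == "se":
            dev2 /= g.size
        ss += dev2
        dof += g.size - 1
    if dof == 0:
        raise ValueError("no sample has >= 2 replicates; spread is undefined")
    return float(np.sqrt(ss / dof))
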