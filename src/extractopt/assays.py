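"""Assay arithmetic: percent inhibition, calibration equivalents, IC50.

Spectrophotometric assays report absorbances; activity is expressed as
percent inhibition relative to a control, 100 * (A - B) / A.  Analyte
contents (total phenolics, flavonoids, antioxidant equivalents) come from
inverting linear calibration curves y = slope * x + intercept.  IC50 is
interpolated linearly in inhibition vs log10(concentration) between the two
points bracketing 50 %; no sigmoid fit is attempted, so the estimate is
exact whenever the 50 % crossing is locally log-linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AssayError, NotEstimableError, PipelineIOError


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration y = slope * x + intercept, absorbance vs content."""

    analyte: str
    slope: float
    intercept: float
    r2: float = float("nan")
    unit: str = ""

    def __post_init__(self):
        if self.slope == 0:
            raise AssayError("calibration slope must be nonzero")


#: Published calibration curves for the date-seed assay panel.
CALIBRATION_CURVES = {
    "TPC": CalibrationCurve("TPC", 0.0512, 0.0018, 0.9835, "mg GAE/g"),
    "TFC": CalibrationCurve("TFC", 0.014, 0.0021, 0.9994, "mg CE/g"),
    "DPPH": CalibrationCurve("DPPH", 0.0069, 0.035, 0.9905, "umol AAE/g"),
    "ABTS": CalibrationCurve("ABTS", 0.0083, 0.0002, 0.9989, "umol AAE/g"),
    "CUPRAC": CalibrationCurve("CUPRAC", 0.0065, 0.039, 0.9975, "umol AAE/g"),
    "FRAP": CalibrationCurve("FRAP", 0.013, 0.0465, 0.9889, "umol AAE/g"),
}


def percent_inhibition(control: float, sample: float) -> float:
    """Radical-scavenging % inhibition: 100 * (A_control - A_sample) / A_control."""
    if control <= 0:
        raise AssayError("control absorbance must be positive")
    return 100.0 * (control - sample) / control


def melanin_inhibition(untreated: float, treated: float) -> float:
    """Melanin-production % inhibition; control is the untreated-cell reading."""
    return percent_inhibition(untreated, treated)


def equivalent_concentration(absorbance: float, curve: CalibrationCurve) -> float:
    """Invert a calibration curve: x = (y - intercept) / slope."""
    return (absorbance - curve.intercept) / curve.slope


@dataclass
class DoseResponse:
    """Paired (concentration, % inhibition) points, concentrations increasing."""

    concentrations: np.ndarray
    inhibition: np.ndarray
    analyte: str = ""

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if len(self.concentrations) != len(self.inhibition):
            raise AssayError("concentration / inhibition length mismatch")
        if np.any(self.concentrations <= 0):
            raise AssayError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise AssayError("concentrations must be strictly increasing")

    @property
    def out_of_range(self) -> np.ndarray:
        """Mask of inhibition values outside [0, 100] (kept, but flagged)."""
        return (self.inhibition < 0) | (self.inhibition > 100)


def ic50(dr: DoseResponse) -> float:
    """IC50 by linear interpolation in inhibition vs log10(concentration).

    Uses the first adjacent pair bracketing 50 %.  Raises
    :class:`NotEstimableError` (with ``bound`` set to ``"> max"`` or
    ``"< min"``) when the curve never crosses 50 %.
    """
    c, y = dr.concentrations, dr.inhibition
    exact = np.flatnonzero(y == 50.0)
    if len(exact):
        return float(c[exact[0]])
    for i in range(len(c) - 1):
        if (y[i] - 50.0) * (y[i + 1] - 50.0) < 0:
            lo, hi = math.log10(c[i]), math.log10(c[i + 1])
            t = (50.0 - y[i]) / (y[i + 1] - y[i])
            return float(10 ** (lo + t * (hi - lo)))
    bound = "> max" if np.all(y < 50.0) else "< min"
    raise NotEstimableError(f"inhibition never crosses 50% ({bound})", bound=bound)


# ---------------------------------------------------------------- plate I/O --

PLATE_COLUMNS = ["analyte", "concentration", "absorbance"]


def read_plate_csv(path_or_buf) -> pd.DataFrame:
    """Plate CSV: analyte, concentration, absorbance; control rows have
    concentration 0."""
    df = pd.read_csv(path_or_buf)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineIOError("assay", f"plate CSV missing columns: {missing}")
    return df


def analyze_plate(df: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte inhibition table and IC50 from plate readings.

    For each analyte the mean absorbance of its concentration-0 rows is the
    control; every positive concentration becomes a % inhibition point, and
    IC50 is interpolated where estimable (otherwise reported as the bound).
    """
    out = []
    for analyte, grp in df.groupby("analyte", sort=False):
        controls = grp.loc[grp["concentration"] == 0, "absorbance"]
        if controls.empty:
            raise PipelineIOError("assay", f"analyte {analyte!r} has no control rows")
        a0 = float(controls.mean())
        doses = (
            grp[grp["concentration"] > 0]
            .groupby("concentration", sort=True)["absorbance"]
            .mean()
        )
        inhib = np.array([percent_inhibition(a0, b) for b in doses.to_numpy()])
        dr = DoseResponse(doses.index.to_numpy(), inhib, analyte=analyte)
        try:
            ic = ic50(dr)
            ic_text = f"{ic:.6g}"
        except NotEstimableError as err:
            ic, ic_text = float("nan"), err.bound
        for conc, pct, flag in zip(dr.concentrations, dr.inhibition, dr.out_of_range):
            out.append(
                {
                    "analyte": analyte,
                    "concentration": conc,
                    "inhibition_pct": pct,
                    "out_of_range": bool(flag),
                    "ic50": ic,
                    "ic50_label": ic_text,
                }
            )
    return pd.DataFrame(out)
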