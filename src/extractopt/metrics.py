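"""Model-comparison and optimum-validation statistics.

``compare`` produces the standard panel used to rank RSM against an ANN
surrogate: R^2, RMSE, absolute average deviation (AAD %, deviations taken
relative to the *predicted* values) and standard error of prediction
(SEP % = 100 * RMSE / mean observed response).

``validate_optimum`` quantifies agreement between a confirmatory experiment
and the model prediction at the optimum: relative standard error
RSE % = 100 * (actual - predicted) / predicted, and relative standard
deviation RSD % = 100 * SD(pair) / mean(pair) with the n-1 (sample) SD of a
two-value pair, |a - b| / sqrt(2).  Conventional pass thresholds are
RSD < 10 % and |RSE| < 5 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

RSD_PASS_PCT = 10.0
RSE_PASS_PCT = 5.0


@dataclass(frozen=True)
class ComparisonReport:
    label: str
    n: int
    r2: float
    rmse: float
    aad_pct: float
    sep_pct: float
    mean_observed: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "r2": self.r2,
            "rmse": self.rmse,
            "aad_pct": self.aad_pct,
            "sep_pct": self.sep_pct,
        }


@dataclass(frozen=True)
class ValidationReport:
    actual: float
    predicted: float
    rsd_pct: float
    rse_pct: float

    @property
    def rsd_pass(self) -> bool:
        return self.rsd_pct < RSD_PASS_PCT

    @property
    def rse_pass(self) -> bool:
        return abs(self.rse_pct) < RSE_PASS_PCT

    def to_dict(self) -> dict:
        return {
            "actual": self.actual,
            "predicted": self.predicted,
            "rsd_pct": self.rsd_pct,
            "rse_pct": self.rse_pct,
            "rsd_pass": self.rsd_pass,
            "rse_pass": self.rse_pass,
        }


def compare(observed, predicted, label: str = "") -> ComparisonReport:
    """Prediction-quality panel for paired observed/predicted vectors."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if len(obs) != len(pred):
        raise ValueError("observed and predicted lengths differ")
    n = len(obs)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    ym = float(obs.mean())
    if ym == 0:
        raise ValueError("mean observed response is zero; SEP undefined")
    sst = float(np.sum((obs - ym) ** 2))
    if sst == 0:
        raise ValueError("observed vector has zero variance; R^2 undefined")
    sse = float(np.sum((obs - pred) ** 2))
    rmse = math.sqrt(sse / n)
    aad = float(np.sum(np.abs(pred - obs) / pred)) / n * 100.0
    return ComparisonReport(
        label=label,
        n=n,
        r2=1.0 - sse / sst,
        rmse=rmse,
        aad_pct=aad,
        sep_pct=100.0 * rmse / ym,
        mean_observed=ym,
    )


def validate_optimum(actual: float, predicted: float) -> ValidationReport:
    """RSD/RSE agreement between a confirmatory run and the model prediction."""
    if predicted <= 0:
        raise ValidationError("predicted value must be positive")
    rse = 100.0 * (actual - predicted) / predicted
    mean = (actual + predicted) / 2.0
    sd = abs(actual - predicted) / math.sqrt(2.0)
    return ValidationReport(
        actual=float(actual),
        predicted=float(predicted),
        rsd_pct=100.0 * sd / mean,
        rse_pct=rse,
    )
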