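"""Seeded synthetic-data generators mirroring each pipeline stage's inputs.

* BBD responses: a true quadratic surface evaluated at the design points
  plus i.i.d. homoscedastic Gaussian noise (replicate scatter in the real
  study is roughly constant across runs), so pure error has expectation
  sigma^2 and lack of fit is null-true when the surface is quadratic.
* Peak lists: library masses perturbed by multiplicative ppm-scale normal
  error, optionally mixed with uniform decoy masses.
* Dose-response curves: four-parameter logistic inhibition with additive
  Gaussian noise.

All generators take either an integer seed or a ``numpy.random.Generator``
so multi-stage simulations can share one stream end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import DoseResponse
from .design import DATESEED_FACTORS, DesignTable, generate_bbd
from .mass import deprotonated_mz
from .rsm import quadratic_model_matrix


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class SurfaceSimSpec:
    """True quadratic surface + noise level for BBD response simulation."""

    coefficients: np.ndarray  # 10-vector in model-matrix term order
    noise_sd: float = 0.6
    center_points: int = 5
    seed: int = 0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (10,):
            raise ValueError("need 10 true coefficients")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.center_points < 2:
            raise ValueError("need >= 2 center replicates for pure error")


def simulate_bbd_responses(spec: SurfaceSimSpec, rng=None):
    """Design table plus noisy quadratic responses at its runs."""
    rng = _rng(spec.seed if rng is None else rng)
    design = generate_bbd(DATESEED_FACTORS, center_points=spec.center_points)
    mean = quadratic_model_matrix(design.coded) @ spec.coefficients
    y = mean + rng.normal(0.0, spec.noise_sd, size=len(mean))
    return design, y


@dataclass
class PeaklistSimSpec:
    """Perturbed library masses plus uniform decoys."""

    library: list  # CompoundRecord sequence
    ppm_sd: float = 2.0
    decoys: int = 0
    mz_range: tuple = (50.0, 1000.0)
    seed: int = 0

    def __post_init__(self):
        if self.ppm_sd < 0:
            raise ValueError("ppm SD must be >= 0")


def simulate_peaklist(spec: PeaklistSimSpec, rng=None) -> np.ndarray:
    """Peak m/z array: each library [M-H]- mass with multiplicative
    N(0, ppm_sd) relative error, then ``decoys`` uniform masses appended."""
    rng = _rng(spec.seed if rng is None else rng)
    calc = np.array([deprotonated_mz(r.formula) for r in spec.library])
    peaks = calc * (1.0 + rng.normal(0.0, spec.ppm_sd * 1e-6, size=len(calc)))
    if spec.decoys:
        lo, hi = spec.mz_range
        peaks = np.concatenate([peaks, rng.uniform(lo, hi, size=spec.decoys)])
    return peaks


def logistic_inhibition(conc, ic50: float, hill: float, bottom=0.0, top=100.0):
    """Four-parameter logistic: inhibition rising with concentration."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / conc) ** hill)


def simulate_dose_response(
    ic50_true: float,
    hill: float = 1.0,
    noise_sd: float = 0.0,
    concentrations=None,
    seed=0,
    analyte: str = "synthetic",
) -> DoseResponse:
    """Noisy 4PL dose-response points on a log-spaced concentration grid."""
    if ic50_true <= 0 or hill <= 0:
        raise ValueError("ic50 and hill must be positive")
    rng = _rng(seed)
    if concentrations is None:
        concentrations = ic50_true * np.logspace(-2, 2, 9)
    conc = np.asarray(concentrations, dtype=float)
    y = logistic_inhibition(conc, ic50_true, hill)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(conc))
    return DoseResponse(conc, y, analyte=analyte)
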