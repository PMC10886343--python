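"""Three-factor Box-Behnken designs with replicated center points.

A Box-Behnken design (BBD) for three factors places runs at the midpoints of
the edges of the factor cube — every pair of factors visits the four (+/-1,
+/-1) combinations while the third factor is held at its center — plus a
block of replicated center runs used to estimate pure error.  For three
factors this gives 12 edge runs plus ``c`` centers (17 runs for the usual
``c = 5``).

Factors are handled on two scales: *actual* units (percent ethanol, minutes,
degrees Celsius) and *coded* units in which low/center/high map to -1/0/+1.
Coded levels of design runs are stored as exact integers so column sums and
sums of squares are computed without float drift.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, PipelineIOError

#: Column layout of the design CSV interchange format.
DESIGN_CSV_COLUMNS = [
    "run",
    "ec_pct",
    "time_min",
    "temp_c",
    "coded_x1",
    "coded_x2",
    "coded_x3",
]


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its low / center / high actual levels."""

    name: str
    low: float
    center: float
    high: float

    def __post_init__(self):
        if not (self.low < self.center < self.high):
            raise DesignError(
                f"factor {self.name!r}: require low < center < high, "
                f"got {self.low}, {self.center}, {self.high}"
            )
        if abs(self.center - (self.low + self.high) / 2.0) > 1e-9 * self.half_range:
            raise DesignError(
                f"factor {self.name!r}: center must be the midpoint of low and high"
            )

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0


#: The date-seed extraction factors: ethanol %, sonication time, temperature.
DATESEED_FACTORS = (
    FactorSpec("ec_pct", 40.0, 60.0, 80.0),
    FactorSpec("time_min", 15.0, 30.0, 45.0),
    FactorSpec("temp_c", 40.0, 50.0, 60.0),
)

# Table-order coded rows of the 17-run fixture layout (centers interleaved),
# used when a caller asks for the published run order.
_PAPER_ORDER_CODED = [
    (1, -1, 0), (1, 0, -1), (0, 1, 1), (0, 0, 0), (0, 0, 0), (0, 0, 0),
    (1, 1, 0), (0, -1, 1), (0, 1, -1), (-1, -1, 0), (0, -1, -1),
    (-1, 0, 1), (-1, 1, 0), (0, 0, 0), (0, 0, 0), (-1, 0, -1), (1, 0, 1),
]


@dataclass
class DesignTable:
    """A BBD realization: factors plus runs on both scales.

    ``coded`` holds integer levels for design-generated runs; ``actual`` is
    derived from the factor specs.  ``center_replicates`` counts (0,0,0) runs.
    """

    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    coded: np.ndarray  # (n, 3) int or float
    run_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.coded = np.asarray(self.coded)
        if self.coded.ndim != 2 or self.coded.shape[1] != 3:
            raise DesignError("coded levels must be an (n, 3) array")
        if not self.run_ids:
            self.run_ids = list(range(1, len(self.coded) + 1))

    def __len__(self) -> int:
        return len(self.coded)

    @property
    def actual(self) -> np.ndarray:
        return decode_point(self.coded, self.factors)

    @property
    def center_replicates(self) -> int:
        return int(np.sum(np.all(self.coded == 0, axis=1)))

    @property
    def is_center(self) -> np.ndarray:
        return np.all(self.coded == 0, axis=1)

    def to_frame(self) -> pd.DataFrame:
        actual = self.actual
        return pd.DataFrame(
            {
                "run": self.run_ids,
                "ec_pct": actual[:, 0],
                "time_min": actual[:, 1],
                "temp_c": actual[:, 2],
                "coded_x1": self.coded[:, 0],
                "coded_x2": self.coded[:, 1],
                "coded_x3": self.coded[:, 2],
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def generate_bbd(
    factors,
    center_points: int = 5,
    paper_order: bool = False,
) -> DesignTable:
    """Generate a three-factor Box-Behnken design.

    Canonical ordering is pair-block: the (x1,x2), (x1,x3), (x2,x3) edge
    blocks of four runs each, centers last.  ``paper_order=True`` instead
    emits the published 17-run table order (requires ``center_points=5``)
    so fixtures diff cleanly against the printed table.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise DesignError(f"only 3-factor BBDs supported, got {len(factors)} factors")
    if center_points < 1:
        raise DesignError("center_points must be >= 1")

    if paper_order:
        if center_points != 5:
            raise DesignError("paper run order is defined for 5 center points")
        coded = np.array(_PAPER_ORDER_CODED, dtype=int)
    else:
        rows = []
        for i, j in ((0, 1), (0, 2), (1, 2)):
            for a in (-1, 1):
                for b in (-1, 1):
                    row = [0, 0, 0]
                    row[i], row[j] = a, b
                    rows.append(row)
        rows.extend([[0, 0, 0]] * center_points)
        coded = np.array(rows, dtype=int)
    return DesignTable(factors=factors, coded=coded)


def code_point(actual, factors):
    """Map actual factor levels to coded units: (actual - center)/half-range."""
    actual = np.asarray(actual, dtype=float)
    centers = np.array([f.center for f in factors])
    halves = np.array([f.half_range for f in factors])
    return (actual - centers) / halves


def decode_point(coded, factors):
    """Inverse of :func:`code_point`."""
    coded = np.asarray(coded, dtype=float)
    centers = np.array([f.center for f in factors])
    halves = np.array([f.half_range for f in factors])
    return coded * halves + centers


def is_extrapolated(coded, tol: float = 1e-9) -> bool:
    """True when a coded point lies outside the [-1, 1] cube."""
    return bool(np.any(np.abs(np.asarray(coded)) > 1 + tol))


def read_design_csv(path_or_buf, factors=DATESEED_FACTORS) -> DesignTable:
    """Read a design-table CSV written by :meth:`DesignTable.to_csv`."""
    try:
        df = pd.read_csv(path_or_buf)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PipelineIOError("design", f"cannot read design CSV: {exc}") from exc
    missing = [c for c in DESIGN_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineIOError("design", f"design CSV missing columns: {missing}")
    coded = df[["coded_x1", "coded_x2", "coded_x3"]].to_numpy()
    if np.allclose(coded, np.round(coded)):
        coded = np.round(coded).astype(int)
    table = DesignTable(factors=tuple(factors), coded=coded, run_ids=list(df["run"]))
    # cross-check the actual columns against the factor specs
    actual = df[["ec_pct", "time_min", "temp_c"]].to_numpy(dtype=float)
    if not np.allclose(actual, table.actual, atol=1e-6):
        raise PipelineIOError(
            "design", "actual levels in CSV are inconsistent with coded levels"
        )
    return table


def design_to_csv_string(table: DesignTable) -> str:
    buf = io.StringIO()
    table.to_csv(buf)
    return buf.getvalue()
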