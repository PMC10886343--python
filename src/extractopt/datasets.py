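"""Bundled fixtures: the 17-run date-seed extraction study.

``load_dateseed_design`` returns the published Box-Behnken table for
ultrasound-assisted extraction of date-seed polyphenols — three factors
(ethanol %, sonication time, temperature), 12 edge runs plus 5 center
replicates, with measured total phenolic (TPC, mg GAE/g) and total flavonoid
(TFC, mg CE/g) contents and the original RSM/ANN predicted columns.

``load_compound_library`` returns the 104-compound negative-mode annotation
table (name, class, elemental formula, observed [M-H]- m/z, MS/MS fragments,
identification confidence level) transcribed as printed, including its known
typographical anomalies; ``printed_calculated_mz`` preserves the published
calculated-mass column for cross-checking.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .design import DATESEED_FACTORS, DesignTable, code_point
from .mass import CompoundRecord

#: Library rows (1-based "no") whose printed calculated mass disagrees with
#: their printed formula by more than printing precision — table typos.
CM_ANOMALY_ROWS = frozenset({17, 79, 84, 94})


def _data_path(name: str):
    return importlib.resources.files("extractopt.data").joinpath(name)


def load_dateseed_frame() -> pd.DataFrame:
    """Raw fixture frame, one row per run."""
    with importlib.resources.as_file(_data_path("bbd_dateseed.csv")) as p:
        return pd.read_csv(p)


def load_dateseed_design() -> tuple[DesignTable, dict]:
    """The 17-run design plus responses.

    Returns ``(design, responses)`` where ``responses`` maps ``"TPC"`` and
    ``"TFC"`` to the experimental value arrays, aligned to the design rows.
    """
    df = load_dateseed_frame()
    coded = code_point(
        df[["ec_pct", "time_min", "temp_c"]].to_numpy(), DATESEED_FACTORS
    ).round().astype(int)
    design = DesignTable(
        factors=DATESEED_FACTORS, coded=coded, run_ids=list(df["run"])
    )
    responses = {
        "TPC": df["tpc_exp"].to_numpy(),
        "TFC": df["tfc_exp"].to_numpy(),
    }
    return design, responses


def load_compound_frame() -> pd.DataFrame:
    with importlib.resources.as_file(_data_path("compound_library.csv")) as p:
        return pd.read_csv(p)


def load_compound_library() -> list[CompoundRecord]:
    df = load_compound_frame()
    return [
        CompoundRecord(
            name=row["name"],
            compound_class=row["class"],
            formula=row["formula"],
            observed_mz=float(row["observed_mz"]),
            fragments=tuple(
                float(t) for t in str(row["fragments"]).split(";") if t.strip()
            ),
            confidence=int(row["confidence"]),
        )
        for _, row in df.iterrows()
    ]
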