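"""Formula-based mass annotation for negative-mode metabolomics.

Covers the desk arithmetic of [M-H]- annotation: parsing elemental formulas,
monoisotopic neutral masses, deprotonated-adduct m/z, ppm matching of
observed peaks against a compound library, and neutral-loss flagging of
MS/MS fragment lists (hexosyl 162 Da, sulfate 80 Da, ...).

Two adduct conventions are supported.  The default ``h_atom`` subtracts the
hydrogen *atom* mass (electron mass neglected), which is how calculated-mass
columns in annotation tables are conventionally printed; ``proton`` subtracts
the true proton mass, leaving the electron on the ion.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnnotationError, FormulaError

#: Monoisotopic atomic masses (u); extensible.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}

HYDROGEN_ATOM = MONOISOTOPIC_MASS["H"]
PROTON = 1.00727646

#: Common negative-mode neutral losses (Da) flagged in fragment lists.
NEUTRAL_LOSSES = {
    "hexosyl": 162.0528,
    "deoxyhexosyl": 146.0579,
    "galloyl": 152.0110,
    "sulfate": 79.9568,
    "CO2": 43.9898,
    "H2O": 18.0106,
}

#: Fragments in published tables are printed at 2 dp and often re-measured at
#: lower accuracy than the precursor; +/-0.05 Da covers that (e.g. a sulfate
#: loss printing as 80.00 against the exact 79.9568).
LOSS_TOLERANCE_DA = 0.05

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict:
    """Parse an elemental formula string into an element -> count map.

    Underscore-decorated subscripts ("C_15_H_10_O_5_") as they appear in
    typeset tables are tolerated.
    """
    clean = text.replace("_", "").strip()
    if not clean:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(clean):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at {clean[pos:]!r}")
        pos = m.end()
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(clean):
        raise FormulaError(f"cannot parse formula {text!r} at {clean[pos:]!r}")
    return counts


def format_formula(counts: dict) -> str:
    """Hill-order-ish canonical text: C, H, then other elements alphabetically."""
    order = ["C", "H"] + sorted(e for e in counts if e not in ("C", "H"))
    parts = []
    for e in order:
        if e in counts and counts[e] > 0:
            parts.append(e + (str(counts[e]) if counts[e] > 1 else ""))
    return "".join(parts)


def monoisotopic_mass(formula) -> float:
    """Neutral monoisotopic mass of a formula (string or count map)."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return float(sum(MONOISOTOPIC_MASS[e] * k for e, k in counts.items()))


def deprotonated_mz(formula, convention: str = "h_atom") -> float:
    """[M-H]- m/z of a neutral formula under the given subtraction convention."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    if counts.get("H", 0) < 1:
        raise FormulaError("formula has no hydrogen to remove")
    if convention == "h_atom":
        delta = HYDROGEN_ATOM
    elif convention == "proton":
        delta = PROTON
    else:
        raise ValueError(f"unknown adduct convention {convention!r}")
    return monoisotopic_mass(counts) - delta


def ppm_error(observed: float, calculated: float) -> float:
    """Relative mass error in parts per million."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be positive")
    return 1e6 * (observed - calculated) / calculated


@dataclass
class CompoundRecord:
    """One library entry: identity, formula and observed negative-mode data."""

    name: str
    compound_class: str
    formula: str
    observed_mz: float
    fragments: tuple = ()
    confidence: int = 2

    @property
    def calculated_mz(self) -> float:
        return deprotonated_mz(self.formula)


@dataclass
class AnnotationMatch:
    query_mz: float
    record: CompoundRecord
    ppm: float
    loss_flags: list = field(default_factory=list)


def annotate(peaks, library, tolerance_ppm: float = 5.0):
    """Match query m/z values against a compound library.

    Returns ``(matches, unmatched)`` where ``matches`` maps each matched peak
    to its library hits sorted by absolute ppm error, and ``unmatched`` lists
    peaks with no library entry inside the tolerance.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    library = list(library)
    if not library:
        raise AnnotationError("empty compound library")
    calc = np.array([rec.calculated_mz for rec in library])
    matches: dict[float, list[AnnotationMatch]] = {}
    unmatched = []
    for mz in np.atleast_1d(np.asarray(peaks, dtype=float)):
        ppm = 1e6 * (mz - calc) / calc
        idx = np.flatnonzero(np.abs(ppm) <= tolerance_ppm)
        if len(idx) == 0:
            unmatched.append(float(mz))
            continue
        hits = [
            AnnotationMatch(
                query_mz=float(mz),
                record=library[i],
                ppm=float(ppm[i]),
                loss_flags=neutral_loss_flags(mz, library[i].fragments),
            )
            for i in idx
        ]
        hits.sort(key=lambda h: abs(h.ppm))
        matches[float(mz)] = hits
    return matches, unmatched


def neutral_loss_flags(precursor_mz: float, fragments, tolerance: float = LOSS_TOLERANCE_DA):
    """Flag precursor->fragment (and fragment->fragment) neutral losses.

    Every ordered pair among {precursor} + fragments whose mass difference
    matches a known loss within ``tolerance`` is reported as
    ``(from_mz, to_mz, loss_name)``.
    """
    mzs = [float(precursor_mz)] + [float(f) for f in fragments]
    flags = []
    for i, hi in enumerate(mzs):
        for lo in mzs[i + 1 :]:
            diff = hi - lo
            if diff <= 0:
                continue
            for name, loss in NEUTRAL_LOSSES.items():
                if abs(diff - loss) <= tolerance:
                    flags.append((hi, lo, name))
    return flags


# ---------------------------------------------------------------- CSV I/O --

LIBRARY_COLUMNS = ["name", "class", "formula", "observed_mz", "fragments", "confidence"]


def read_library_csv(path_or_buf) -> list:
    """Read a compound-library CSV (fragments semicolon-separated)."""
    df = pd.read_csv(path_or_buf, dtype={"fragments": str})
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"library CSV missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        frag_text = "" if pd.isna(row["fragments"]) else str(row["fragments"])
        fragments = tuple(float(t) for t in frag_text.split(";") if t.strip())
        records.append(
            CompoundRecord(
                name=row["name"],
                compound_class=row["class"],
                formula=row["formula"],
                observed_mz=float(row["observed_mz"]),
                fragments=fragments,
                confidence=int(row["confidence"]),
            )
        )
    return records


def library_to_frame(library) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in library],
            "class": [r.compound_class for r in library],
            "formula": [r.formula for r in library],
            "observed_mz": [r.observed_mz for r in library],
            "fragments": [";".join(f"{f:g}" for f in r.fragments) for r in library],
            "confidence": [r.confidence for r in library],
        }
    )


def write_library_csv(library, path_or_buf) -> None:
    library_to_frame(library).to_csv(path_or_buf, index=False)


def annotation_frame(matches, unmatched) -> pd.DataFrame:
    """Flatten annotate() output into a tidy frame for CSV export."""
    rows = []
    for mz, hits in matches.items():
        for h in hits:
            rows.append(
                {
                    "query_mz": mz,
                    "name": h.record.name,
                    "class": h.record.compound_class,
                    "formula": h.record.formula,
                    "calculated_mz": h.record.calculated_mz,
                    "ppm_error": h.ppm,
                    "loss_flags": ";".join(f"{a:.4f}->{b:.4f}:{n}" for a, b, n in h.loss_flags),
                }
            )
    for mz in unmatched:
        rows.append(
            {
                "query_mz": mz, "name": "", "class": "", "formula": "",
                "calculated_mz": np.nan, "ppm_error": np.nan, "loss_flags": "",
            }
        )
    return pd.DataFrame(rows)


def read_peaklist(path_or_buf) -> np.ndarray:
    """Read a plain-text peak list: one or two whitespace/comma-separated
    columns (m/z [, intensity]); returns the m/z values."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    mzs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        mzs.append(float(re.split(r"[,\s]+", line)[0]))
    return np.array(mzs)
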