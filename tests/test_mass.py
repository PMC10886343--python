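import numpy as np
import pytest

from extractopt.datasets import CM_ANOMALY_ROWS, load_compound_frame
from extractopt.errors import AnnotationError, FormulaError
from extractopt.mass import (
    CompoundRecord,
    annotate,
    deprotonated_mz,
    format_formula,
    monoisotopic_mass,
    neutral_loss_flags,
    parse_formula,
    ppm_error,
)


class TestFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C15H10O5", {"C": 15, "H": 10, "O": 5}),
            ("C_21_H_20_O_14_S", {"C": 21, "H": 20, "O": 14, "S": 1}),
            ("H", {"H": 1}),
            ("C11H19NO9", {"C": 11, "H": 19, "N": 1, "O": 9}),
        ],
    )
    def test_parse(self, text, expected):
        assert parse_formula(text) == expected

    def test_unknown_element_rejected(self):
        with pytest.raises(FormulaError):
            parse_formula("C5Xx2")
        with pytest.raises(FormulaError):
            parse_formula("")

    def test_round_trip_on_all_library_formulas(self, library):
        for rec in library:
            counts = parse_formula(rec.formula)
            assert parse_formula(format_formula(counts)) == counts


class TestAdductMass:
    @pytest.mark.parametrize(
        "formula,printed",
        [
            ("C15H10O5", 269.045),    # apigenin
            ("C30H26O12", 577.1346),  # procyanidin B2
            ("C15H10O7", 301.0348),   # quercetin
        ],
    )
    def test_matches_printed_calculated_masses(self, formula, printed):
        assert deprotonated_mz(formula) == pytest.approx(printed, abs=5e-4)

    def test_proton_convention_differs_by_electron_mass(self):
        h_atom = deprotonated_mz("C15H10O5", "h_atom")
        proton = deprotonated_mz("C15H10O5", "proton")
        assert proton - h_atom == pytest.approx(0.00054857, abs=1e-6)

    def test_hydrogen_free_formula_rejected(self):
        with pytest.raises(FormulaError):
            deprotonated_mz("CO2")

    def test_calculated_mass_column_reproduced(self):
        # recomputed [M-H]- matches the printed calculated-mass column to
        # within printing precision for all but the known typo rows
        df = load_compound_frame()
        bad = [
            int(row["no"])
            for _, row in df.iterrows()
            if abs(deprotonated_mz(row["formula"]) - row["printed_calculated_mz"]) > 0.0015
        ]
        assert set(bad) == set(CM_ANOMALY_ROWS)
        assert len(df) - len(bad) >= 95


class TestPpm:
    def test_zero_for_equal_masses(self):
        assert ppm_error(269.045, 269.045) == 0.0

    def test_signed_arithmetic(self):
        assert ppm_error(269.0454, 269.0450) == pytest.approx(1.49, abs=0.01)
        # the tartaric-acid row's printed observed mass is a table typo
        assert ppm_error(148.9235, 149.0086) == pytest.approx(-571, abs=1)


class TestAnnotate:
    def test_calculated_masses_all_self_match(self, library):
        peaks = [rec.calculated_mz for rec in library]
        matches, unmatched = annotate(peaks, library, tolerance_ppm=0.1)
        assert unmatched == []
        assert len(matches) == len(set(peaks))

    def test_observed_masses_self_match_rate(self, library):
        # 12 of the 104 printed observed masses carry >10 ppm transcription
        # errors; the rest self-annotate
        hits = 0
        for rec in library:
            found, _ = annotate([rec.observed_mz], library, tolerance_ppm=10.0)
            if any(h.record.name == rec.name for hs in found.values() for h in hs):
                hits += 1
        assert hits == 92

    def test_isobaric_entries_both_returned_ranked(self):
        lib = [
            CompoundRecord("a", "other", "C6H12O6", 179.0561),
            CompoundRecord("b", "other", "C6H12O6", 179.0561),
            CompoundRecord("far", "other", "C5H10O5", 149.0455),
        ]
        matches, _ = annotate([179.0561], lib, tolerance_ppm=5.0)
        hits = matches[179.0561]
        assert {h.record.name for h in hits} == {"a", "b"}
        assert abs(hits[0].ppm) <= abs(hits[-1].ppm)

    def test_decoy_does_not_perturb_existing_matches(self, library):
        peaks = [library[0].calculated_mz]
        base, _ = annotate(peaks, library, tolerance_ppm=5.0)
        decoy = CompoundRecord("decoy", "other", "C40H80O2", 591.6)
        withd, _ = annotate(peaks, library + [decoy], tolerance_ppm=5.0)
        assert [h.record.name for h in base[peaks[0]]] == [
            h.record.name for h in withd[peaks[0]]
        ]

    def test_library_order_does_not_matter(self, library):
        peaks = [library[10].observed_mz, library[50].observed_mz]
        a, _ = annotate(peaks, library, 10.0)
        b, _ = annotate(peaks, list(reversed(library)), 10.0)
        for mz in peaks:
            assert {h.record.name for h in a.get(mz, [])} == {
                h.record.name for h in b.get(mz, [])
            }

    def test_empty_library_rejected(self):
        with pytest.raises(AnnotationError):
            annotate([100.0], [], 5.0)


class TestNeutralLoss:
    def test_glycosyl_loss_flagged(self):
        # lignan glycoside: 567.2084 -> 405.15 by hexosyl (162 Da) loss
        flags = neutral_loss_flags(567.2084, [405.15, 387.14])
        assert any(name == "hexosyl" for _, _, name in flags)

    def test_sulfate_loss_flagged(self):
        flags = neutral_loss_flags(527.0502, [447.05])
        assert any(name == "sulfate" for _, _, name in flags)

    def test_no_spurious_flags(self):
        assert neutral_loss_flags(500.0, [400.0, 300.0]) == []
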