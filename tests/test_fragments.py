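"""Fragment annotation: enumeration, loss paths, pairs, GliA flags, report."""

import pytest

from tkms import reference as R
from tkms.formula import monoisotopic_mass, parse_formula
from tkms.fragments import (
    FragmentAnnotation,
    STANDARD_LOSSES,
    annotate_loss_paths,
    build_fragmentation_report,
    enumerate_subformulas,
    find_complementary_pairs,
    flag_glia_fragments,
    report_to_text,
)
from tkms.spectra import Condition, Peak, PeakList

LOSS = {l.name: l for l in STANDARD_LOSSES}


def _pl(mzs, precursor=None):
    return PeakList(
        "frag",
        tuple(Peak(m, 100.0) for m in mzs),
        Condition(msms_precursor=precursor),
    )


class TestEnumerateSubformulas:
    PRECURSOR = parse_formula("C14H23N4O9P2S")

    @pytest.mark.parametrize(
        "target, expected",
        [
            (180.077, "C8H10N3O2"),   # aminopyrimidine + GliA
            (303.981, "C6H12NO7P2S"), # thiazole + diphosphate side
            (122.072, "C6H8N3"),      # aminopyrimidine
        ],
    )
    def test_recovers_printed_fragment_formulas(self, target, expected):
        result = enumerate_subformulas(self.PRECURSOR, target, tol_ppm=10)
        assert parse_formula(expected) in result
        assert result[0] == parse_formula(expected)

    def test_below_lightest_subformula_empty(self):
        assert enumerate_subformulas(self.PRECURSOR, 1.0, tol_ppm=10) == []

    def test_all_results_within_tolerance_and_inside_precursor(self):
        for f in enumerate_subformulas(self.PRECURSOR, 266.025, tol_ppm=10):
            assert f <= self.PRECURSOR
            m = monoisotopic_mass(f)
            assert abs(1e6 * (266.025 - m) / m) <= 10

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            enumerate_subformulas(self.PRECURSOR, 180.077, tol_ppm=0)


class TestLossPaths:
    @pytest.mark.parametrize(
        "precursor_name, fragment_mz, expected_losses",
        [
            ("ThDP+GliA", 307.122, ("H2O", "H2P2O6")),
            ("ThDP+GliA", 405.100, ("HPO3",)),
            ("ThDP+GliA", 467.055, ("H2O",)),
            ("ThDP+GliA", 425.045, ("GliA",)),
            ("ThDP+GliA-H2O", 449.045, ("H2O",)),
        ],
    )
    def test_paper_loss_paths(self, species, precursor_name, fragment_mz, expected_losses):
        prec = species[precursor_name]
        (ann,) = annotate_loss_paths(prec, _pl([fragment_mz]), tol_ppm=10)
        assert tuple(sorted(l.name for l in ann.path)) == tuple(sorted(expected_losses))

    def test_mass_conservation_along_path(self, species, fragment_peaklists):
        prec = species["ThDP+GliA"]
        anns = annotate_loss_paths(prec, fragment_peaklists["485"], tol_ppm=10)
        for a in anns:
            if a.path:
                lhs = monoisotopic_mass(prec.formula) - sum(l.mass for l in a.path)
                assert lhs == pytest.approx(monoisotopic_mass(a.formula), abs=1e-9)

    def test_water_loss_preferred_over_h2_plus_o(self, species):
        # -H2O and -H2 -O are mass-identical; the single-loss reading wins
        (ann,) = annotate_loss_paths(species["ThDP+GliA"], _pl([467.0555]), tol_ppm=5)
        assert [l.name for l in ann.path] == ["H2O"]

    def test_unexplained_peak_reported_not_dropped(self, species):
        anns = annotate_loss_paths(
            species["ThDP+GliA"], _pl([77.7]), tol_ppm=5, fallback_enumeration=False
        )
        assert anns[0].formula is None and anns[0].path == ()


class TestComplementaryPairs:
    def test_all_printed_pairs_found_with_stated_slack(self, species):
        prec = species["ThDP+GliA"]
        mzs = sorted({m for p in R.PRINTED_PAIRS for m in (p.mz_a, p.mz_b)})
        anns = [FragmentAnnotation(m, None, None) for m in mzs]
        pairs = find_complementary_pairs(prec, anns, slack_window=0.01)
        found = {
            (p.mz_a, p.mz_b, tuple(sorted(l.name for l in p.losses_restored)),
             p.hydrogen_slack)
            for p in pairs
        }
        for printed in R.PRINTED_PAIRS:
            assert (
                printed.mz_a, printed.mz_b, tuple(sorted(printed.restored)),
                printed.hydrogen_slack,
            ) in found

    def test_no_pairs_outside_printed_families(self, species):
        prec = species["ThDP+GliA"]
        mzs = sorted({m for p in R.PRINTED_PAIRS for m in (p.mz_a, p.mz_b)})
        anns = [FragmentAnnotation(m, None, None) for m in mzs]
        pairs = find_complementary_pairs(prec, anns, slack_window=0.01)
        printed = {(p.mz_a, p.mz_b) for p in R.PRINTED_PAIRS}
        assert {(p.mz_a, p.mz_b) for p in pairs} == printed

    def test_pair_closure(self, species):
        prec = species["ThDP+GliA"]
        mzs = sorted({m for p in R.PRINTED_PAIRS for m in (p.mz_a, p.mz_b)})
        anns = [FragmentAnnotation(m, None, None) for m in mzs]
        for p in find_complementary_pairs(prec, anns):
            assert p.reconstructed_mass == pytest.approx(
                prec.theoretical_mass, abs=0.01
            )

    def test_single_fragment_no_pairs(self, species):
        anns = [FragmentAnnotation(485.066, None, None)]
        assert find_complementary_pairs(species["ThDP+GliA"], anns) == []


class TestGliaFlags:
    @pytest.fixture()
    def flagged(self, species, fragment_peaklists):
        control = annotate_loss_paths(
            species["ThDP"], fragment_peaklists["425"], tol_ppm=10
        )
        anns = annotate_loss_paths(
            species["ThDP+GliA"], fragment_peaklists["485"], tol_ppm=10
        )
        anns += annotate_loss_paths(
            species["ThDP+GliA-H2O"], fragment_peaklists["467"], tol_ppm=10
        )
        return {a.observed_mz: a for a in flag_glia_fragments(anns, control)}

    def test_adduct_fragment_is_glia_containing(self, flagged):
        assert flagged[180.077].glia_flag == "glia_containing"

    def test_cofactor_fragment_is_glia_free(self, flagged):
        assert flagged[122.071].glia_flag == "glia_free"

    def test_deoxo_adduct_is_glia_containing(self, flagged):
        assert flagged[164.082].glia_flag == "glia_containing"

    def test_reference_asterisks_reproduced_for_main_intermediate(
        self, species, fragment_peaklists
    ):
        control = annotate_loss_paths(
            species["ThDP"], fragment_peaklists["425"], tol_ppm=10
        )
        anns = flag_glia_fragments(
            annotate_loss_paths(
                species["ThDP+GliA"], fragment_peaklists["485"], tol_ppm=10
            ),
            control,
        )
        truth = {
            row.observed["485"]: row.glia_marked
            for row in R.FRAGMENT_TABLE
            if "485" in row.observed
        }
        for a in anns:
            expected = "glia_containing" if truth[a.observed_mz] else "glia_free"
            assert a.glia_flag == expected, a.observed_mz


class TestReport:
    def test_cofactor_alone_gives_glia_free_rows(self, species, fragment_peaklists):
        df = build_fragmentation_report(
            [species["ThDP"]], [fragment_peaklists["425"]]
        )
        assert len(df) > 0
        assert not df["formula"].str.endswith("*").any()

    def test_empty_spectrum_gives_empty_section(self, species, fragment_peaklists):
        empty = PeakList("e", ())
        df = build_fragmentation_report(
            [species["ThDP"], species["ThDP+GliA"]],
            [fragment_peaklists["425"], empty],
        )
        assert df["ThDP+GliA"].isna().all()

    def test_precursor_without_spectrum_is_error(self, species, fragment_peaklists):
        with pytest.raises(ValueError, match="precursor"):
            build_fragmentation_report(
                [species["ThDP"], species["ThDP+GliA"]],
                [fragment_peaklists["425"]],
            )

    def test_report_is_deterministic_bytes(self, precursors, fragment_peaklists):
        precs = list(precursors.values())
        specs = [fragment_peaklists[k] for k in precursors]
        t1 = report_to_text(build_fragmentation_report(precs, specs))
        t2 = report_to_text(build_fragmentation_report(precs, specs))
        assert t1 == t2

    def test_trap_shift_annotated(self, precursors, fragment_peaklists):
        precs = list(precursors.values())
        specs = [fragment_peaklists[k] for k in precursors]
        df = build_fragmentation_report(precs, specs)
        row = df[df["formula"].str.startswith("C8H12N3O2")]
        assert len(row) == 1
        assert "+2.016" in row.iloc[0]["trap_shift"]
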