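"""Peak-list IO, control subtraction, assignment and trap-pair detection."""

import io

import pytest

from tkms.spectra import (
    Condition,
    Peak,
    PeakList,
    PeakListError,
    assign_peaks,
    detect_trap_pairs,
    read_peaklist,
    subtract_control,
    write_peaklist,
)


def _pl(mzs, spectrum_id="s", flags=None, **cond):
    return PeakList(
        spectrum_id,
        tuple(Peak(m, 100.0) for m in mzs),
        Condition(**cond),
        contaminant_flags=tuple(flags) if flags else (),
    )


class TestReadPeaklist:
    def test_reads_two_column_text(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("# comment\n485.066\t1000\n467.056,300\n")
        pl = read_peaklist(p)
        assert [pk.mz for pk in pl.peaks] == [467.056, 485.066]

    def test_unsorted_input_sorted_output(self):
        pl = read_peaklist(io.StringIO("500.0 1\n300.0 2\n400.0 3\n"))
        assert pl.mz == (300.0, 400.0, 500.0)

    def test_non_numeric_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("485.066\t1000\nhello\tworld\n")
        with pytest.raises(PeakListError, match="line 2"):
            read_peaklist(p)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(PeakListError, match="empty"):
            read_peaklist(io.StringIO("# nothing here\n"))

    def test_write_read_round_trip(self, tmp_path):
        pl = _pl([485.06610, 467.05553])
        path = tmp_path / "out.tsv"
        write_peaklist(pl, path)
        back = read_peaklist(path)
        assert back.mz == pytest.approx(pl.mz, abs=1e-5)

    def test_invalid_peaks_rejected(self):
        with pytest.raises(PeakListError):
            PeakList("s", (Peak(-1.0, 5.0),))
        with pytest.raises(PeakListError):
            PeakList("s", (Peak(100.0, -5.0),))


class TestSubtractControl:
    def test_shared_contaminant_flagged(self):
        sample = _pl([484.867, 485.066])
        control = _pl([484.867])
        flagged = subtract_control(sample, control)
        assert flagged.contaminant_flags == (True, False)
        assert len(flagged) == len(sample)  # nothing deleted

    def test_empty_overlap_no_flags(self):
        flagged = subtract_control(_pl([485.066]), _pl([300.0]))
        assert flagged.contaminant_flags == (False,)

    def test_window_is_absolute_da(self):
        flagged = subtract_control(_pl([485.066]), _pl([485.0655]), window=0.01)
        assert flagged.contaminant_flags == (True,)
        flagged = subtract_control(_pl([485.066]), _pl([485.03]), window=0.01)
        assert flagged.contaminant_flags == (False,)


class TestAssignPeaks:
    def test_assigns_within_tolerance(self, catalog):
        out = assign_peaks(_pl([485.0660]), catalog, tol_ppm=5)
        (a,) = out
        assert a.status == "assigned"
        assert a.candidate.name == "ThDP+GliA"
        assert abs(a.ppm) < 0.5

    def test_dihydride_assignment(self, catalog):
        # observed trapped-species mass reads one mDa below theory
        (a,) = assign_peaks(_pl([487.081]), catalog, tol_ppm=5)
        assert a.status == "assigned"
        assert a.candidate.name == "ThDP+GliA+H2"

    def test_contaminant_peak_gets_no_composition(self, catalog):
        (a,) = assign_peaks(_pl([484.867]), catalog, tol_ppm=5)
        assert a.status == "contaminant"
        assert a.candidate is None and a.ppm is None

    def test_control_flag_beats_assignment(self, catalog):
        pl = _pl([485.066], flags=[True])
        (a,) = assign_peaks(pl, catalog, tol_ppm=5)
        assert a.status == "contaminant"

    def test_far_peak_unassigned(self, catalog):
        (a,) = assign_peaks(_pl([250.123]), catalog, tol_ppm=5)
        assert a.status == "unassigned"

    def test_near_tie_is_ambiguous(self, species):
        pair = [species["ThDP+GliA"]]
        twin = type(pair[0])(
            name="twin",
            formula=None,
            theoretical_mass=pair[0].theoretical_mass + 1e-5,
            role="intermediate",
        )
        (a,) = assign_peaks(_pl([485.0661]), pair + [twin], tol_ppm=5)
        assert a.status == "ambiguous"
        assert len(a.alternatives) == 2

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            assign_peaks(_pl([485.066]), [], tol_ppm=5)

    def test_deterministic(self, catalog):
        pl = _pl([485.066, 467.056, 425.045])
        assert assign_peaks(pl, catalog) == assign_peaks(pl, catalog)


class TestDetectTrapPairs:
    def test_trap_specific_pair_found(self, catalog):
        without = assign_peaks(_pl([485.066]), catalog)
        with_red = assign_peaks(_pl([485.066, 487.082]), catalog)
        res = detect_trap_pairs(without, with_red)
        assert res.trap_pairs == ((485.066, 487.082),)
        assert res.not_trap_specific == ()

    def test_heavy_partner_in_both_conditions_not_trap_specific(self, catalog):
        without = assign_peaks(_pl([465.040, 467.056]), catalog)
        with_red = assign_peaks(_pl([465.040, 467.056]), catalog)
        res = detect_trap_pairs(without, with_red)
        assert res.trap_pairs == ()
        assert res.not_trap_specific == ((465.040, 467.056),)

    def test_empty_with_reductant_list(self, catalog):
        without = assign_peaks(_pl([485.066]), catalog)
        res = detect_trap_pairs(without, [])
        assert res.trap_pairs == () and res.not_trap_specific == ()
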