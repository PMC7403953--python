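"""Property-based invariants: mass additivity, parser round trips, ppm sign
convention, assignment monotonicity, enumeration oracle equivalence, and
noise-degradation monotonicity."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from tkms.formula import (
    ChemicalFormula,
    ELEMENTS,
    DEFAULT_MASS_TABLE,
    formula_add,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)
from tkms.fragments import UNCONSTRAINED, enumerate_subformulas
from tkms.simulate import recovery_experiment
from tkms.species import default_catalog
from tkms.spectra import Condition, Peak, PeakList, assign_peaks

formulas = st.builds(
    ChemicalFormula.from_counts,
    st.dictionaries(
        st.sampled_from(ELEMENTS), st.integers(min_value=0, max_value=30)
    ),
)
nonempty_formulas = formulas.filter(bool)


@settings(derandomize=True, max_examples=200)
@given(formulas, formulas)
def test_mass_additivity(a, b):
    assert monoisotopic_mass(a) + monoisotopic_mass(b) == pytest.approx(
        monoisotopic_mass(formula_add(a, b)), abs=1e-9
    )


@settings(derandomize=True, max_examples=200)
@given(nonempty_formulas, st.sampled_from(["plain", "underscore"]))
def test_parser_round_trip(f, dialect):
    assert parse_formula(f.format(dialect)) == f


@settings(derandomize=True, max_examples=200)
@given(
    st.floats(min_value=1.0, max_value=2000.0),
    st.floats(min_value=1.0, max_value=2000.0),
)
def test_ppm_antisymmetry_and_sign(a, b):
    # both sides equal 1e6·(a−b): scaled antisymmetry of the signed error
    assert ppm_error(a, b) * b == pytest.approx(-ppm_error(b, a) * a, rel=1e-9)
    if a > b:
        assert ppm_error(a, b) > 0


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    st.lists(
        st.floats(min_value=200.0, max_value=600.0), min_size=1, max_size=8
    ),
    st.floats(min_value=0.5, max_value=5.0),
    st.floats(min_value=1.0, max_value=20.0),
)
def test_tolerance_monotonicity(mzs, tol_small, extra):
    """Peaks assigned at a tight tolerance stay assigned at a looser one."""
    catalog = default_catalog()
    pl = PeakList("p", tuple(Peak(m, 1.0) for m in mzs), Condition())
    tight = assign_peaks(pl, catalog, tol_ppm=tol_small)
    loose = assign_peaks(pl, catalog, tol_ppm=tol_small + extra)
    assigned_tight = {a.mz for a in tight if a.status == "assigned"}
    assigned_or_ambiguous_loose = {
        a.mz for a in loose if a.status in ("assigned", "ambiguous")
    }
    # widening the window can at worst turn a unique winner ambiguous
    assert assigned_tight <= assigned_or_ambiguous_loose


def _brute_force_subformulas(precursor, target, tol_ppm):
    """Independent nested-loop oracle over the raw subformula lattice."""
    mass_mod = pytest.importorskip("pyteomics.mass")
    hits = set()
    ranges = [range(precursor[e] + 1) for e in ELEMENTS]
    for combo in itertools.product(*ranges):
        counts = {e: c for e, c in zip(ELEMENTS, combo) if c}
        if not counts:
            continue
        m = mass_mod.calculate_mass(
            formula="".join(f"{e}{c}" for e, c in counts.items())
        )
        if abs(1e6 * (target - m) / m) <= tol_ppm:
            hits.add(ChemicalFormula.from_counts(counts))
    return hits


@pytest.mark.parametrize(
    "precursor_text, target",
    [
        ("C10H20N5O8P2S", 303.981),
        ("C10H20N5O8P2S", 180.077),
        ("C6H10N2O4", 120.042),
        ("C8H15NO6PS", 266.025),
    ],
)
def test_enumeration_matches_brute_force_oracle(precursor_text, target):
    precursor = parse_formula(precursor_text)
    ours = set(
        enumerate_subformulas(precursor, target, 10.0, constraints=UNCONSTRAINED)
    )
    oracle = _brute_force_subformulas(precursor, target, 10.0)
    assert ours == oracle


def test_assignment_accuracy_degrades_with_noise():
    """Recovery is (weakly) monotone non-increasing in calibration noise."""
    rates = [
        recovery_experiment(n_replicates=40, ppm_sigma=s, seed=11)
        for s in (0.0, 1.5, 5.0, 20.0)
    ]
    assert rates[0] == 1.0
    assert all(a >= b for a, b in zip(rates, rates[1:]))
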