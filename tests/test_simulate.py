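"""Synthetic-spectrum generator: determinism, zero-noise limits, round trips."""

import pytest

from tkms.formula import monoisotopic_mass
from tkms.fragments import annotate_loss_paths
from tkms.simulate import (
    DEFAULT_SCISSION_PAIRS,
    SimulationSpec,
    simulate_ms1,
    simulate_msms,
)
from tkms.spectra import HYDROGEN2_DELTA, assign_peaks, detect_trap_pairs, subtract_control


@pytest.fixture(scope="module")
def planted(species):
    return tuple(species[n] for n in ("ThDP", "ThDP+GliA", "ThDP+GliA-H2O"))


def test_seeded_determinism(planted):
    spec = SimulationSpec(planted_species=planted, seed=42, contaminant_count=3)
    assert simulate_ms1(spec) == simulate_ms1(spec)
    prec = planted[1]
    assert simulate_msms(prec, spec) == simulate_msms(prec, spec)


def test_zero_noise_peaks_at_theoretical_masses(planted):
    spec = SimulationSpec(
        planted_species=planted, ppm_sigma=0.0, contaminant_count=0, seed=1
    )
    sample, _ = simulate_ms1(spec)
    assert list(sample.mz) == pytest.approx(
        sorted(s.theoretical_mass for s in planted), abs=1e-9
    )


def test_trap_condition_adds_and_removes_partners(planted, species):
    trapped = planted + (species["ThDP+GliA+H2"],)
    on = SimulationSpec(planted_species=trapped, ppm_sigma=0.0,
                        contaminant_count=0, trap_condition=True, seed=1)
    off = SimulationSpec(planted_species=trapped, ppm_sigma=0.0,
                         contaminant_count=0, trap_condition=False, seed=1)
    mz_on, _ = simulate_ms1(on)
    mz_off, _ = simulate_ms1(off)
    m485 = species["ThDP+GliA"].theoretical_mass
    assert any(abs(m - (m485 + HYDROGEN2_DELTA)) < 1e-6 for m in mz_on.mz)
    assert not any(abs(m - (m485 + HYDROGEN2_DELTA)) < 1e-6 for m in mz_off.mz)


def test_contaminants_shared_with_control(species):
    # no cofactor planted, so the only sample/control overlap is artifactual
    spec = SimulationSpec(
        planted_species=(species["ThDP+GliA"], species["ThDP+GliA-H2O"]),
        contaminant_count=4,
        seed=9,
    )
    sample, control = simulate_ms1(spec)
    flagged = subtract_control(sample, control)
    assert sum(flagged.contaminant_flags) == 4


def test_trap_pair_recovery_at_zero_noise(planted, catalog):
    on = SimulationSpec(planted_species=planted, ppm_sigma=0.0,
                        contaminant_count=0, trap_condition=True, seed=4)
    off = SimulationSpec(planted_species=planted, ppm_sigma=0.0,
                         contaminant_count=0, trap_condition=False, seed=4)
    a_off = assign_peaks(subtract_control(*simulate_ms1(off)), catalog)
    a_on = assign_peaks(subtract_control(*simulate_ms1(on)), catalog)
    res = detect_trap_pairs(a_off, a_on)
    adducts = sorted(
        s.theoretical_mass for s in planted
        if s.role in ("intermediate", "dehydrated_intermediate")
    )
    assert sorted(a for a, _ in res.trap_pairs) == pytest.approx(adducts, abs=1e-6)


def test_msms_depth_one_only_single_losses(species):
    prec = species["ThDP+GliA"]
    spec = SimulationSpec(planted_species=(prec,), ppm_sigma=0.0, seed=2)
    pl = simulate_msms(prec, spec, scission_pairs=(), max_depth=1)
    anns = annotate_loss_paths(prec, pl, tol_ppm=5)
    assert all(len(a.path) == 1 for a in anns)


def test_msms_zero_noise_round_trip(species):
    """Every simulated fragment is explained with its generating composition,
    and annotated loss paths are mass-equivalent to the generating ones."""
    prec = species["ThDP+GliA"]
    spec = SimulationSpec(planted_species=(prec,), ppm_sigma=0.0, seed=7)
    pl = simulate_msms(prec, spec)
    anns = {a.observed_mz: a for a in annotate_loss_paths(prec, pl, tol_ppm=5)}
    assert all(a.formula is not None for a in anns.values())
    # loss-generated peaks: exact composition identity
    scission_mzs = set()
    for fa, fb in DEFAULT_SCISSION_PAIRS:
        for f in (fa, fb):
            for slack in (-1.007825032, 0.0, 1.007825032):
                scission_mzs.add(round(monoisotopic_mass(f) + slack, 6))
    for mz, a in anns.items():
        if round(mz, 6) in scission_mzs:
            continue
        expected = monoisotopic_mass(prec.formula) - sum(l.mass for l in a.path)
        assert mz == pytest.approx(expected, abs=1e-6)
        assert mz == pytest.approx(monoisotopic_mass(a.formula), abs=1e-6)


def test_invalid_spec_rejected(planted):
    with pytest.raises(ValueError):
        SimulationSpec(planted_species=planted, ppm_sigma=-1.0)
    with pytest.raises(ValueError):
        SimulationSpec(planted_species=planted, contaminant_count=-1)
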