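"""CID fragment annotation for ThDP-intermediate precursors.

Three complementary lines of evidence are computed for each MS/MS spectrum:

* **neutral-loss paths** — fragments explained by sequential loss of small
  neutrals (water, metaphosphate HPO3, diphosphate-as-H2P2O6, O, H2, or the
  whole glycolaldehyde residue) from the precursor composition;
* **subformula enumeration** — exhaustive search of all compositions
  elementwise within the precursor for peaks no loss path explains;
* **complementary ring-scission pairs** — two fragments from one scission
  of the molecule between its rings whose masses, after restoring up to one
  water and one metaphosphate and allowing a hydrogen transfer of up to two
  mass units, reconstruct the precursor.

Fragments retaining the transferred glycolaldehyde (GliA) residue are
distinguished from bare-cofactor fragments by comparison against the
fragmentation of ThDP itself, whose structure is known.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations_with_replacement
from typing import Optional, Sequence

import pandas as pd

from . import reference
from .formula import (
    ChemicalFormula,
    CompositionError,
    ELEMENTS,
    DEFAULT_MASS_TABLE,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    round_half_up,
)
from .species import SpeciesCandidate
from .spectra import HYDROGEN2_DELTA, PeakList

__all__ = [
    "NeutralLoss",
    "STANDARD_LOSSES",
    "FragmentAnnotation",
    "ComplementaryPair",
    "FormulaConstraints",
    "DEFAULT_CONSTRAINTS",
    "UNCONSTRAINED",
    "enumerate_subformulas",
    "annotate_loss_paths",
    "find_complementary_pairs",
    "attach_partners",
    "flag_glia_fragments",
    "build_fragmentation_report",
    "report_to_text",
]

_H_MASS = 1.007825032


@dataclass(frozen=True)
class NeutralLoss:
    """A neutral moiety released during CID."""

    name: str
    formula: ChemicalFormula

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


def _loss(name: str, formula: str) -> NeutralLoss:
    return NeutralLoss(name, parse_formula(formula))


#: The loss library observed for this system. Note H2O is mass-identical to
#: the two-step H2 + O reading; both collapse onto the single H2O entry.
STANDARD_LOSSES: tuple[NeutralLoss, ...] = (
    _loss("H2O", "H2O"),
    _loss("HPO3", "HPO3"),
    _loss("H2P2O6", "H2P2O6"),
    _loss("O", "O"),
    _loss("H2", "H2"),
    _loss("GliA", "C2H4O2"),
)

_LOSS_BY_NAME = {l.name: l for l in STANDARD_LOSSES}


@dataclass(frozen=True)
class FragmentAnnotation:
    """An explained (or explicitly unexplained) MS/MS peak.

    ``path`` is the neutral-loss sequence from the precursor (empty when the
    formula came from subformula enumeration, or when no explanation was
    found and ``formula`` is None). ``scission_partner`` and
    ``hydrogen_slack`` are filled by :func:`find_complementary_pairs`;
    ``glia_flag`` by :func:`flag_glia_fragments`.
    """

    observed_mz: float
    formula: Optional[ChemicalFormula]
    ppm: Optional[float]
    path: tuple[NeutralLoss, ...] = ()
    scission_partner: Optional[float] = None
    hydrogen_slack: int = 0
    glia_flag: str = "undetermined"  # glia_containing | glia_free | undetermined


@dataclass(frozen=True)
class ComplementaryPair:
    """Two fragments that jointly reconstruct the precursor."""

    mz_a: float
    mz_b: float
    losses_restored: tuple[NeutralLoss, ...]
    hydrogen_slack: int
    reconstructed_mass: float


# ---------------------------------------------------------------------------
# subformula enumeration

@dataclass(frozen=True)
class FormulaConstraints:
    """Chemical-plausibility filter for enumerated fragment compositions.

    At 10 ppm and fragment masses of 100–500 Da a bare subformula search
    returns many isobaric compositions; mass alone cannot rank them. The
    default profile encodes standard composition heuristics plus two
    constraints specific to thiamine chemistry, where every fragment is a
    substructure of a thiazolium–aminopyrimidine diphosphate:

    * hydrogen saturation bounded (H/C ≤ 3.1, the usual small-molecule cap);
    * ring-plus-double-bond equivalents in a window wide enough for the
      doubly dehydrated species (−1 ≤ RDBE ≤ 9, half-integers allowed for
      open-shell/cationic fragments);
    * phosphorus only as (di)phosphate: O ≥ 3·P;
    * sulfur only in the thiazole ring, which carries nitrogen: S > 0 ⇒ N ≥ 1.
    """

    max_h_per_c: float = 3.1
    min_rdbe: float = -1.0
    max_rdbe: float = 9.0
    min_o_per_p: int = 3
    s_requires_n: bool = True

    def allows(self, f: ChemicalFormula) -> bool:
        c, h = f["C"], f["H"]
        n, o, p, s = f["N"], f["O"], f["P"], f["S"]
        if self.max_h_per_c != float("inf"):
            if c == 0 and h > 2:  # carbon-free polyhydrides
                return False
            if c and h / c > self.max_h_per_c:
                return False
        rdbe = c + 1 - h / 2 + n / 2 + p / 2
        if not (self.min_rdbe <= rdbe <= self.max_rdbe):
            return False
        if p and o < self.min_o_per_p * p:
            return False
        if self.s_requires_n and s and n < 1:
            return False
        return True


#: Permissive profile: every subformula allowed (for oracle comparisons).
UNCONSTRAINED = FormulaConstraints(
    max_h_per_c=float("inf"), min_rdbe=float("-inf"), max_rdbe=float("inf"),
    min_o_per_p=0, s_requires_n=False,
)

DEFAULT_CONSTRAINTS = FormulaConstraints()


def enumerate_subformulas(
    precursor: ChemicalFormula,
    target: float,
    tol_ppm: float = 10.0,
    table=DEFAULT_MASS_TABLE,
    constraints: FormulaConstraints = DEFAULT_CONSTRAINTS,
) -> list[ChemicalFormula]:
    """All compositions elementwise within ``precursor`` whose neutral mass
    lies within ``tol_ppm`` of ``target``, ranked by |ppm| (ties broken by
    formula string for determinism). Compositions failing ``constraints``
    are excluded; pass :data:`UNCONSTRAINED` for the raw search space.

    The search is exhaustive depth-first with mass-window pruning; precursor
    compositions in this system are small (≤ C14 H25 N4 O9 P2 S), so the
    full space is a few tens of thousands of candidates.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if target <= 0:
        raise ValueError("target m/z must be positive")
    tol_da = tol_ppm * 1e-6 * target
    lo, hi = target - tol_da, target + tol_da

    # heavy elements first so pruning bites early
    elements = sorted(
        (e for e in ELEMENTS if precursor[e] > 0), key=lambda e: -table[e]
    )
    max_counts = [precursor[e] for e in elements]
    masses = [table[e] for e in elements]
    # max mass attainable from elements[i:]
    suffix_max = [0.0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + max_counts[i] * masses[i]

    found: list[tuple[float, str, ChemicalFormula]] = []
    counts = [0] * len(elements)

    def rec(i: int, acc: float) -> None:
        if acc > hi:
            return
        if acc + suffix_max[i] < lo:
            return
        if i == len(elements):
            if lo <= acc <= hi:
                f = ChemicalFormula.from_counts(
                    {e: c for e, c in zip(elements, counts) if c}
                )
                if constraints.allows(f):
                    found.append(
                        (abs(ppm_error(acc, target)) if acc else 0.0, f.format(), f)
                    )
            return
        for c in range(max_counts[i] + 1):
            counts[i] = c
            rec(i + 1, acc + c * masses[i])
        counts[i] = 0

    rec(0, 0.0)
    found.sort(key=lambda t: (t[0], t[1]))
    return [f for _, _, f in found]


# ---------------------------------------------------------------------------
# neutral-loss paths

def _loss_path_catalog(
    precursor: ChemicalFormula,
    losses: Sequence[NeutralLoss],
    max_depth: int,
) -> dict[ChemicalFormula, tuple[NeutralLoss, ...]]:
    """Formula → canonical loss path, for all loss multisets up to
    ``max_depth``. Canonical = fewest losses, then lexicographic loss-name
    order; mass-equivalent multisets (e.g. 2×HPO3 vs H2P2O6) collapse onto
    the canonical representative."""
    catalog: dict[ChemicalFormula, tuple[NeutralLoss, ...]] = {}
    for depth in range(1, max_depth + 1):
        for combo in combinations_with_replacement(
            sorted(losses, key=lambda l: l.name), depth
        ):
            f = precursor
            try:
                for loss in combo:
                    f = f - loss.formula
            except CompositionError:
                continue
            if f not in catalog:
                catalog[f] = combo
    return catalog


def annotate_loss_paths(
    precursor: SpeciesCandidate,
    fragments: PeakList,
    losses: Sequence[NeutralLoss] = STANDARD_LOSSES,
    max_depth: int = 3,
    tol_ppm: float = 10.0,
    fallback_enumeration: bool = True,
) -> list[FragmentAnnotation]:
    """Explain each fragment peak by the shortest neutral-loss path from the
    precursor whose resulting composition matches within ``tol_ppm``.

    Peaks no path explains fall back to exhaustive subformula enumeration
    (empty path); peaks that even enumeration cannot explain are reported
    with ``formula=None`` rather than dropped.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if precursor.formula is None:
        raise ValueError("precursor must have a composition")
    pf = precursor.formula
    catalog = _loss_path_catalog(pf, losses, max_depth)
    entries = sorted(
        (
            (monoisotopic_mass(f), f, path)
            for f, path in catalog.items()
        ),
        key=lambda t: t[0],
    )

    out: list[FragmentAnnotation] = []
    for peak in fragments.peaks:
        best: Optional[tuple[int, float, ChemicalFormula, tuple]] = None
        precursor_ppm = ppm_error(peak.mz, monoisotopic_mass(pf))
        if abs(precursor_ppm) <= tol_ppm:
            # the surviving precursor ion itself
            out.append(FragmentAnnotation(peak.mz, pf, precursor_ppm, ()))
            continue
        for mass, f, path in entries:
            ppm = ppm_error(peak.mz, mass)
            if abs(ppm) <= tol_ppm:
                key = (len(path), abs(ppm))
                if best is None or key < (best[0], abs(best[1])):
                    best = (len(path), ppm, f, path)
        if best is not None:
            _, ppm, f, path = best
            out.append(FragmentAnnotation(peak.mz, f, ppm, tuple(path)))
            continue
        if fallback_enumeration:
            cands = enumerate_subformulas(pf, peak.mz, tol_ppm)
            if cands:
                f = cands[0]
                out.append(
                    FragmentAnnotation(
                        peak.mz, f, ppm_error(peak.mz, monoisotopic_mass(f)), ()
                    )
                )
                continue
        out.append(FragmentAnnotation(peak.mz, None, None, ()))
    return out


# ---------------------------------------------------------------------------
# complementary pairs

_RESTORABLE = ("H2O", "HPO3")


def find_complementary_pairs(
    precursor: SpeciesCandidate,
    annotations: Sequence[FragmentAnnotation],
    slack_window: float = 0.01,
    max_hydrogen_slack: int = 2,
) -> list[ComplementaryPair]:
    """Detect fragment pairs that reconstruct the precursor mass.

    For each unordered pair (a, b) of annotated peaks, each subset of
    restorable losses {H2O, HPO3} and each hydrogen transfer
    n ∈ [-max_hydrogen_slack, +max_hydrogen_slack], the pair is reported
    when ``|a + b + restored - M - n·1.00783| <= slack_window`` (M the
    precursor mass). At the default window the (n, restored) explanation is
    unique per pair because candidate explanations differ by ≥ 1 Da.
    """
    M = precursor.theoretical_mass
    restore_options: list[tuple[NeutralLoss, ...]] = [()]
    for r in range(1, len(_RESTORABLE) + 1):
        for names in combinations_with_replacement(_RESTORABLE, r):
            if len(set(names)) == len(names):  # each loss at most once
                restore_options.append(tuple(_LOSS_BY_NAME[n] for n in names))

    mzs = sorted({a.observed_mz for a in annotations})
    pairs: list[ComplementaryPair] = []
    for i, a in enumerate(mzs):
        for b in mzs[i:]:
            for restored in restore_options:
                total = a + b + sum(l.mass for l in restored)
                n_float = (total - M) / _H_MASS
                n = round(n_float)
                if abs(n) > max_hydrogen_slack:
                    continue
                if abs(total - M - n * _H_MASS) <= slack_window:
                    pairs.append(
                        ComplementaryPair(
                            mz_a=a,
                            mz_b=b,
                            losses_restored=restored,
                            hydrogen_slack=int(n),
                            reconstructed_mass=total - n * _H_MASS,
                        )
                    )
    pairs.sort(key=lambda p: (p.mz_a, p.mz_b, [l.name for l in p.losses_restored]))
    return pairs


def attach_partners(
    annotations: Sequence[FragmentAnnotation],
    pairs: Sequence[ComplementaryPair],
) -> list[FragmentAnnotation]:
    """Return annotations with scission partner and hydrogen slack filled
    from the first pair each peak participates in."""
    by_mz: dict[float, ComplementaryPair] = {}
    for p in pairs:
        by_mz.setdefault(p.mz_a, p)
        by_mz.setdefault(p.mz_b, p)
    out = []
    for a in annotations:
        p = by_mz.get(a.observed_mz)
        if p is None:
            out.append(a)
        else:
            partner = p.mz_b if a.observed_mz == p.mz_a else p.mz_a
            out.append(
                replace(a, scission_partner=partner, hydrogen_slack=p.hydrogen_slack)
            )
    return out


# ---------------------------------------------------------------------------
# GliA-retention flagging

_H2F = parse_formula("H2")
#: GliA remnants a fragment may retain: the residue itself, its dehydrate,
#: dehydrogenated and deoxo forms, and the reductively trapped dihydride.
_GLIA_VARIANTS: tuple[ChemicalFormula, ...] = (
    parse_formula("C2H4O2"),   # GliA
    parse_formula("C2H2O2"),   # GliA - H2
    parse_formula("C2H2O"),    # GliA - H2O
    parse_formula("C2H4O"),    # GliA - O
    parse_formula("C2H6O2"),   # GliA + H2 (trapped)
)


def flag_glia_fragments(
    intermediate_annotations: Sequence[FragmentAnnotation],
    cofactor_control_annotations: Sequence[FragmentAnnotation],
    window: float = 0.01,
    cofactor: ChemicalFormula = reference.THDP_FORMULA,
) -> list[FragmentAnnotation]:
    """Classify fragments as GliA-containing / GliA-free / undetermined.

    A fragment matching a bare-cofactor control fragment within ``window``
    Da is GliA-free; so is one whose mass minus the +2H trap shift matches a
    control fragment (a trap-shifted cofactor fragment). Otherwise a
    fragment with a known composition is GliA-containing when removing some
    GliA remnant (GliA or its ±H2/−H2O/−O forms) leaves a composition that
    fits inside the cofactor — i.e. the fragment is cofactor material plus
    adduct. Everything else stays undetermined.
    """
    control_mz = sorted(a.observed_mz for a in cofactor_control_annotations)

    def near_control(mz: float) -> bool:
        return any(abs(mz - c) <= window for c in control_mz)

    out = []
    for a in intermediate_annotations:
        if near_control(a.observed_mz) or near_control(a.observed_mz - HYDROGEN2_DELTA):
            out.append(replace(a, glia_flag="glia_free"))
            continue
        flag = "undetermined"
        if a.formula is not None:
            for g in _GLIA_VARIANTS:
                try:
                    remainder = a.formula - g
                except CompositionError:
                    continue
                if remainder <= cofactor:
                    flag = "glia_containing"
                    break
        out.append(replace(a, glia_flag=flag))
    return out


# ---------------------------------------------------------------------------
# the fragmentation report

def build_fragmentation_report(
    precursors: Sequence[SpeciesCandidate],
    spectra: Sequence[PeakList],
    control_index: Optional[int] = None,
    tol_ppm: float = 10.0,
    max_depth: int = 3,
    base_precursor_mass: Optional[float] = None,
) -> pd.DataFrame:
    """Annotate one MS/MS spectrum per precursor into a fragment matrix.

    Rows are assigned fragment compositions with their calculated mass;
    columns hold the observed m/z under each precursor (empty where absent).
    GliA-containing rows are starred. When a trapped precursor (mass ≈ base
    + 2.016) is present, fragments that retain the trap hydrogens — i.e.
    whose composition minus H2 appears as a fragment of the untrapped
    precursor — are noted in a trap-shift column.

    ``control_index`` selects which spectrum is the bare-cofactor control
    for GliA flagging; by default the precursor with role ``cofactor`` is
    used if present.
    """
    if len(precursors) != len(spectra):
        raise ValueError(
            f"{len(precursors)} precursors but {len(spectra)} spectra; "
            "each precursor needs exactly one MS/MS peak list"
        )
    if control_index is None:
        for i, p in enumerate(precursors):
            if p.role == "cofactor":
                control_index = i
                break

    per_precursor: list[list[FragmentAnnotation]] = []
    for prec, spec in zip(precursors, spectra):
        per_precursor.append(
            annotate_loss_paths(prec, spec, max_depth=max_depth, tol_ppm=tol_ppm)
            if len(spec)
            else []
        )

    control_anns = per_precursor[control_index] if control_index is not None else []
    flagged: list[list[FragmentAnnotation]] = []
    for i, anns in enumerate(per_precursor):
        if control_index is not None and i != control_index:
            flagged.append(flag_glia_fragments(anns, control_anns))
        else:
            flagged.append([replace(a, glia_flag="glia_free") for a in anns])

    # rows keyed by composition
    rows: dict[ChemicalFormula, dict] = {}
    labels = [p.name for p in precursors]
    for label, anns in zip(labels, flagged):
        for a in anns:
            if a.formula is None:
                continue
            row = rows.setdefault(
                a.formula,
                {
                    "formula": a.formula.format(),
                    "calculated": round_half_up(monoisotopic_mass(a.formula), 3),
                    "glia": False,
                    **{lab: None for lab in labels},
                },
            )
            row[label] = a.observed_mz
            if a.glia_flag == "glia_containing":
                row["glia"] = True

    # trap-shift annotation
    trapped_label = None
    base_mass = base_precursor_mass
    for p in precursors:
        for q in precursors:
            if abs(p.theoretical_mass - q.theoretical_mass - HYDROGEN2_DELTA) < 0.005:
                trapped_label, base_mass = p.name, q.theoretical_mass
    for f, row in rows.items():
        note = ""
        if trapped_label and row.get(trapped_label) is not None:
            try:
                lighter = f - _H2F
            except CompositionError:
                lighter = None
            if lighter is not None and lighter in rows:
                note = f"+{HYDROGEN2_DELTA:.3f} vs {rows[lighter]['calculated']:.3f}"
        row["trap_shift"] = note

    df = pd.DataFrame(
        [
            {
                "formula": r["formula"] + ("*" if r["glia"] else ""),
                "calculated": r["calculated"],
                **{lab: r[lab] for lab in labels},
                "trap_shift": r["trap_shift"],
            }
            for r in rows.values()
        ],
        columns=["formula", "calculated", *labels, "trap_shift"],
    )
    return df.sort_values("calculated", ascending=False).reset_index(drop=True)


def report_to_text(report: pd.DataFrame) -> str:
    """Deterministic delimited-text rendering of the report matrix."""
    df = report.copy()
    for col in df.columns:
        if col in ("formula", "trap_shift"):
            continue
        df[col] = df[col].map(
            lambda v: "" if v is None or (isinstance(v, float) and pd.isna(v))
            else f"{v:.4f}".rstrip("0").rstrip(".")
        )
    return df.to_csv(sep="\t", index=False)
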