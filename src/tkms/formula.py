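"""Chemical-formula arithmetic over the CHNOPS element universe.

Every downstream operation — candidate catalogs, peak assignment, neutral-loss
bookkeeping, subformula enumeration — reduces to integer element counts and
monoisotopic masses computed here.

Masses are neutral-atom sums: no electron-mass correction is applied even for
singly protonated/cationic species. At the three-decimal precision of the
reference mass tables for this system the neutral-atom sum is the convention
that reproduces every printed value (e.g. thiamine diphosphate,
C12H19N4O7P2S, is quoted as 425.045, the neutral sum, not the 425.044 cation
mass).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ELEMENTS",
    "AtomicMassTable",
    "ChemicalFormula",
    "CompositionError",
    "FormulaParseError",
    "DEFAULT_MASS_TABLE",
    "parse_formula",
    "monoisotopic_mass",
    "formula_add",
    "formula_subtract",
    "ppm_error",
    "round_half_up",
    "printed_sum",
]

#: Canonical element order used for formatting (organic "Hill-like" order).
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "P", "S")


class FormulaParseError(ValueError):
    """A formula string could not be interpreted."""


class CompositionError(ValueError):
    """A formula operation would produce a negative element count."""


class AtomicMassTable(Mapping[str, float]):
    """Immutable element → monoisotopic mass (Da) lookup.

    By default restricted to exactly the CHNOPS universe; a table with extra
    elements may be constructed explicitly (``allow_extended=True``) for
    non-standard adduct work, but none of the bundled catalogs need it.
    """

    def __init__(self, masses: Mapping[str, float], *, allow_extended: bool = False):
        missing = set(ELEMENTS) - set(masses)
        if missing:
            raise ValueError(f"mass table missing elements: {sorted(missing)}")
        extra = set(masses) - set(ELEMENTS)
        if extra and not allow_extended:
            raise ValueError(
                f"elements outside CHNOPS not enabled: {sorted(extra)}"
            )
        self._masses = dict(masses)

    def __getitem__(self, element: str) -> float:
        return self._masses[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._masses)

    def __len__(self) -> int:
        return len(self._masses)

    @classmethod
    def from_tsv(cls, text: str, *, allow_extended: bool = False) -> "AtomicMassTable":
        """Parse an ``element<TAB>mass`` table; ``#`` lines are comments."""
        masses: dict[str, float] = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                element, value = line.split("\t")
                masses[element.strip()] = float(value)
            except ValueError as exc:
                raise ValueError(f"bad mass-table line: {line!r}") from exc
        return cls(masses, allow_extended=allow_extended)


def _load_default_table() -> AtomicMassTable:
    text = resources.files("tkms.data").joinpath("atomic_masses.tsv").read_text()
    return AtomicMassTable.from_tsv(text)


DEFAULT_MASS_TABLE = _load_default_table()


@dataclass(frozen=True)
class ChemicalFormula:
    """An integer element-count composition over CHNOPS.

    Counts are non-negative; an absent element means count zero. Two formulas
    compare equal iff all counts agree. Instances are immutable and hashable,
    so they key dictionaries and dedupe sets throughout the package.
    """

    counts: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for element, n in dict(self.counts).items():
            if element not in ELEMENTS:
                raise FormulaParseError(f"unknown element symbol: {element!r}")
            if not isinstance(n, int) or isinstance(n, bool):
                raise FormulaParseError(f"count for {element} is not an integer: {n!r}")
            if n < 0:
                raise CompositionError(f"negative count for {element}: {n}")
            if n > 0:
                cleaned[element] = n
        object.__setattr__(
            self, "counts", tuple((e, cleaned[e]) for e in ELEMENTS if e in cleaned)
        )

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ChemicalFormula":
        return cls(tuple(counts.items()))

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        return formula_add(self, other)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        return formula_subtract(self, other)

    def __le__(self, other: "ChemicalFormula") -> bool:
        """Elementwise subformula test: self fits inside other."""
        return all(self[e] <= other[e] for e in ELEMENTS)

    def mass(self, table: AtomicMassTable = DEFAULT_MASS_TABLE) -> float:
        return monoisotopic_mass(self, table)

    def format(self, dialect: str = "plain") -> str:
        """Render in ``plain`` (C12H19N4O7P2S) or ``underscore``
        (C_12_H_19_N_4_O_7_P_2_S_1_) notation."""
        if not self.counts:
            return ""
        if dialect == "plain":
            return "".join(
                f"{e}{n}" if n != 1 else e for e, n in self.counts
            )
        if dialect == "underscore":
            return "".join(f"{e}_{n}_" for e, n in self.counts)
        raise ValueError(f"unknown dialect: {dialect!r}")

    def __str__(self) -> str:
        return self.format()

    def __repr__(self) -> str:
        return f"ChemicalFormula({self.format() or 'empty'})"


EMPTY = ChemicalFormula()

# One token: element symbol followed by an optional count, with optional
# underscore delimiters around the count (C12, C_12_, S_1_, S).
_TOKEN = re.compile(r"([A-Z][a-z]?)(?:_(\d+)_|(\d+))?")


def parse_formula(text: str, table: AtomicMassTable = DEFAULT_MASS_TABLE) -> ChemicalFormula:
    """Parse a formula string in either plain (``C12H19N4O7P2S``) or
    underscore (``C_12_O_7_H_19_S_1_N_4_P_2_``) notation.

    A trailing ``*`` (the adduct-retention marker used in fragment tables) is
    stripped. Element order is free; repeated elements accumulate. Unknown
    symbols raise :class:`FormulaParseError` naming the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaParseError("empty formula string")
    body = text.strip().rstrip("*").strip()
    # tolerate stray underscores/asterisks embedded by transcription
    # (e.g. "C_12_O_7_H_21_S_1_N_4_P*_2_")
    body = body.replace("*", "")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        if body[pos] == "_":
            pos += 1
            continue
        m = _TOKEN.match(body, pos)
        if not m:
            raise FormulaParseError(
                f"cannot parse formula {text!r} at {body[pos:]!r}"
            )
        element = m.group(1)
        if element not in table:
            raise FormulaParseError(f"unknown element symbol: {element!r} in {text!r}")
        count = int(m.group(2) or m.group(3) or 1)
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    if not counts:
        raise FormulaParseError(f"no elements found in {text!r}")
    return ChemicalFormula.from_counts(counts)


def monoisotopic_mass(
    f: ChemicalFormula, table: AtomicMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Neutral-atom monoisotopic mass in Da, at full floating precision.

    Display rounding is the caller's concern (see :func:`round_half_up`);
    no electron-mass correction is applied for ionic species.
    """
    return sum(n * table[e] for e, n in f.counts)


def formula_add(a: ChemicalFormula, b: ChemicalFormula) -> ChemicalFormula:
    return ChemicalFormula.from_counts(
        {e: a[e] + b[e] for e in ELEMENTS if a[e] + b[e]}
    )


def formula_subtract(a: ChemicalFormula, b: ChemicalFormula) -> ChemicalFormula:
    out: dict[str, int] = {}
    for e in ELEMENTS:
        d = a[e] - b[e]
        if d < 0:
            raise CompositionError(
                f"subtraction drives {e} negative ({a[e]} - {b[e]})"
            )
        if d:
            out[e] = d
    return ChemicalFormula.from_counts(out)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million.

    Positive when the observed m/z is heavier than theory.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def round_half_up(value: float | Decimal, ndigits: int) -> float:
    """Decimal round-half-up (0.0005 at 3 d.p. rounds away from zero).

    Python's builtin ``round`` is banker's rounding; the printed mass tables
    this package reproduces round half up, and at three decimals the
    difference is visible.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def printed_sum(terms: Iterable[str | float | Decimal], ndigits: int = 3) -> float:
    """Sum already-rounded (printed) components exactly as written.

    Mass identities in the experimental literature for this system are often
    stated on pre-rounded values (e.g. 60.0211 + 425.0449 = 485.0660, whereas
    the full-precision sum is 485.06611). This helper reproduces that
    "rounded-component" arithmetic without binary floating dust: terms given
    as strings are taken digit-for-digit; the result is rounded half-up to
    ``ndigits``. Use full-precision masses plus :func:`round_half_up` for the
    other verification mode.
    """
    total = Decimal(0)
    for t in terms:
        total += Decimal(t) if isinstance(t, (str, Decimal)) else Decimal(repr(t))
    return float(total.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))
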