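"""Peak-list handling and precursor assignment.

Spectra are singly charged positive-ion peak lists (the instrument regime
for this system: FT analyzer, z = 1+, calibration error a few ppm). The
workflow mirrors the experimental reasoning: read a peak list, flag peaks
shared with the cofactor-only control spectrum as contaminants (absolute-Da
window, since control artifacts have unknown composition), assign the
remaining peaks to catalog species by minimum |ppm|, and compare paired
conditions with/without the NaCNBH3 reductive trap for +2H partner peaks.

Peaks are never deleted, only flagged: the full audit trail is part of the
assignment report.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .formula import ppm_error
from .species import SpeciesCandidate

__all__ = [
    "Peak",
    "Condition",
    "PeakList",
    "PeakListError",
    "read_peaklist",
    "write_peaklist",
    "subtract_control",
    "PeakAssignment",
    "assign_peaks",
    "assignments_to_table",
    "TrapPairResult",
    "detect_trap_pairs",
    "HYDROGEN2_DELTA",
]

#: Mass of two hydrogen atoms, the reductive-trap shift.
HYDROGEN2_DELTA = 2 * 1.007825032


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class Condition:
    """Experimental condition flags for one spectrum."""

    substrate_present: bool = False
    reductant_present: bool = False
    msms_precursor: Optional[float] = None


class PeakListError(ValueError):
    pass


@dataclass(frozen=True)
class PeakList:
    """One spectrum: metadata plus (m/z, intensity) pairs sorted by m/z.

    ``contaminant_flags`` parallels ``peaks``; it is all-False until
    :func:`subtract_control` produces a flagged copy.
    """

    spectrum_id: str
    peaks: tuple[Peak, ...]
    condition: Condition = field(default_factory=Condition)
    contaminant_flags: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        pk = tuple(sorted((Peak(float(m), float(i)) for m, i in self.peaks)))
        for p in pk:
            if not (p.mz > 0):
                raise PeakListError(f"non-positive m/z: {p.mz}")
            if p.intensity < 0:
                raise PeakListError(f"negative intensity at m/z {p.mz}")
        object.__setattr__(self, "peaks", pk)
        flags = self.contaminant_flags or tuple(False for _ in pk)
        if len(flags) != len(pk):
            raise PeakListError("contaminant_flags length mismatch")
        object.__setattr__(self, "contaminant_flags", tuple(flags))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)


def read_peaklist(
    source: Union[str, Path, io.TextIOBase],
    spectrum_id: Optional[str] = None,
    condition: Optional[Condition] = None,
    fmt: Optional[str] = None,
    mzml_scan: str = "first",
) -> PeakList:
    """Read a peak list from two-column delimited text or (optionally) mzML.

    Text format: one peak per line, ``m/z<sep>intensity`` with tab, comma or
    whitespace separators; ``#`` lines and blank lines are skipped.
    Non-numeric rows raise :class:`PeakListError` naming the line. For mzML,
    the first MS1 scan is used (``mzml_scan='first'``) or all MS1 scans are
    averaged onto the centroid grid of the first (``'average'``).
    """
    if fmt is None:
        fmt = "mzml" if (
            isinstance(source, (str, Path)) and str(source).lower().endswith(".mzml")
        ) else "text"
    if fmt == "mzml":
        return _read_mzml(source, spectrum_id, condition, mzml_scan)

    if isinstance(source, (str, Path)):
        name = spectrum_id or Path(source).stem
        lines = Path(source).read_text().splitlines()
    else:
        name = spectrum_id or "spectrum"
        lines = source.read().splitlines()

    peaks = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise PeakListError(f"line {lineno}: expected 'm/z intensity', got {raw!r}")
        try:
            mz, inten = float(parts[0]), float(parts[1])
        except ValueError:
            raise PeakListError(f"line {lineno}: non-numeric value in {raw!r}") from None
        peaks.append(Peak(mz, inten))
    if not peaks:
        raise PeakListError("empty spectrum")
    return PeakList(name, tuple(peaks), condition or Condition())


def _read_mzml(source, spectrum_id, condition, mzml_scan) -> PeakList:
    from pyteomics import mzml  # optional dependency

    peaks: list[Peak] = []
    with mzml.read(str(source)) as reader:
        for scan in reader:
            if scan.get("ms level") != 1:
                continue
            pk = list(zip(scan["m/z array"], scan["intensity array"]))
            if mzml_scan == "first":
                peaks = [Peak(float(m), float(i)) for m, i in pk]
                break
            peaks.extend(Peak(float(m), float(i)) for m, i in pk)
    if not peaks:
        raise PeakListError("no MS1 scans in mzML input")
    return PeakList(
        spectrum_id or Path(str(source)).stem, tuple(peaks), condition or Condition()
    )


def write_peaklist(peaklist: PeakList, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spectrum_id: {peaklist.spectrum_id}\n")
        for p in peaklist.peaks:
            fh.write(f"{p.mz:.5f}\t{p.intensity:.1f}\n")


def subtract_control(
    sample: PeakList, control: PeakList, window: float = 0.01
) -> PeakList:
    """Flag sample peaks that coincide with a control peak within ``window``
    Da as contaminants. Nothing is deleted."""
    if window <= 0:
        raise ValueError("window must be positive")
    control_mz = control.mz
    flags = tuple(
        any(abs(p.mz - c) <= window for c in control_mz) for p in sample.peaks
    )
    return replace(sample, contaminant_flags=flags)


@dataclass(frozen=True)
class PeakAssignment:
    """One peak's assignment outcome.

    ``alternatives`` ranks every in-tolerance candidate as (name, ppm),
    best first; for status ``assigned`` the winner is strictly better than
    any runner-up by at least the ambiguity margin.
    """

    mz: float
    intensity: float
    candidate: Optional[SpeciesCandidate]
    ppm: Optional[float]
    status: str  # assigned | ambiguous | contaminant | unassigned
    alternatives: tuple[tuple[str, float], ...] = ()


def assign_peaks(
    spectrum: PeakList,
    catalog: Sequence[SpeciesCandidate],
    tol_ppm: float = 5.0,
    ambiguity_margin_ppm: float = 0.5,
    contaminant_window: float = 0.01,
) -> list[PeakAssignment]:
    """Assign each peak to the in-tolerance catalog species of smallest |ppm|.

    Contaminant handling is presence-based: peaks flagged by
    :func:`subtract_control`, or matching a mass-only contaminant catalog
    entry within ``contaminant_window`` Da, get status ``contaminant`` and no
    composition. Two candidates within tolerance whose |ppm| differ by less
    than ``ambiguity_margin_ppm`` give status ``ambiguous`` with all
    in-tolerance candidates listed.
    """
    if not catalog:
        raise ValueError("empty candidate catalog")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    compositional = [c for c in catalog if c.role != "contaminant"]
    contaminants = [c for c in catalog if c.role == "contaminant"]

    out: list[PeakAssignment] = []
    for peak, flagged in zip(spectrum.peaks, spectrum.contaminant_flags):
        is_contaminant = flagged or any(
            abs(peak.mz - c.theoretical_mass) <= contaminant_window
            for c in contaminants
        )
        if is_contaminant:
            out.append(PeakAssignment(peak.mz, peak.intensity, None, None, "contaminant"))
            continue
        hits = []
        for cand in compositional:
            ppm = ppm_error(peak.mz, cand.theoretical_mass)
            if abs(ppm) <= tol_ppm:
                hits.append((cand, ppm))
        hits.sort(key=lambda t: (abs(t[1]), t[0].name))
        alternatives = tuple((c.name, p) for c, p in hits)
        if not hits:
            out.append(PeakAssignment(peak.mz, peak.intensity, None, None, "unassigned"))
        elif (
            len(hits) > 1
            and abs(hits[1][1]) - abs(hits[0][1]) < ambiguity_margin_ppm
        ):
            out.append(
                PeakAssignment(
                    peak.mz, peak.intensity, None, None, "ambiguous", alternatives
                )
            )
        else:
            cand, ppm = hits[0]
            out.append(
                PeakAssignment(peak.mz, peak.intensity, cand, ppm, "assigned", alternatives)
            )
    return out


def assignments_to_table(assignments: Iterable[PeakAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append(
            {
                "mz": a.mz,
                "intensity": a.intensity,
                "candidate": a.candidate.name if a.candidate else "",
                "formula": (
                    a.candidate.formula.format()
                    if a.candidate and a.candidate.formula
                    else ""
                ),
                "theoretical_mz": a.candidate.theoretical_mass if a.candidate else "",
                "ppm": a.ppm if a.ppm is not None else "",
                "status": a.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mz", "intensity", "candidate", "formula", "theoretical_mz", "ppm", "status"],
    )


@dataclass(frozen=True)
class TrapPairResult:
    """Reductive-trapping comparison across paired conditions.

    ``trap_pairs`` holds (m, m+Δ) where the heavier partner appears only
    with the reductant present — the signature of a trapped labile
    intermediate. Pairs whose heavy partner also occurs without reductant
    are reported separately as not trap-specific.
    """

    trap_pairs: tuple[tuple[float, float], ...]
    not_trap_specific: tuple[tuple[float, float], ...]


def detect_trap_pairs(
    without_reductant: Sequence[PeakAssignment],
    with_reductant: Sequence[PeakAssignment],
    delta: float = HYDROGEN2_DELTA,
    tol_ppm: float = 5.0,
) -> TrapPairResult:
    """Find +2H partner peaks appearing upon reductive trapping.

    Matching windows scale with ppm at the relevant mass. Contaminant-status
    peaks are ignored on both sides.
    """
    def usable(assignments):
        return sorted(
            a.mz for a in assignments if a.status != "contaminant"
        )

    mz_without = usable(without_reductant)
    mz_with = usable(with_reductant)

    def present(mzs, target):
        window = tol_ppm * 1e-6 * target
        return any(abs(m - target) <= window for m in mzs)

    pairs, unspecific = [], []
    for m in mz_without:
        target = m + delta
        matches = [x for x in mz_with if abs(x - target) <= tol_ppm * 1e-6 * target]
        if not matches:
            continue
        partner = min(matches, key=lambda x: abs(x - target))
        if present(mz_without, target):
            unspecific.append((m, partner))
        else:
            pairs.append((m, partner))
    return TrapPairResult(tuple(pairs), tuple(unspecific))
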