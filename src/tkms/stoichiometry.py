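"""One-substrate reaction stoichiometry.

Without an acceptor aldose, transketolase condenses two transferred
glycolaldehyde residues into one erythrulose:

    2 ketose -> 2 aldose residues + erythrulose

so the erythrulose yield should equal half the consumed donor substrate
(hydroxypyruvate). This module checks measured yields against that 2:1
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .formula import round_half_up

__all__ = ["StoichiometryRecord", "erythrulose_check", "batch_check"]


@dataclass(frozen=True)
class StoichiometryRecord:
    substrate_load: float       # mM hydroxypyruvate consumed
    expected_product: float     # mM erythrulose at exact 2:1 stoichiometry
    measured_product: float     # mM erythrulose found
    percent_of_expected: float  # full precision; display rounds to integer

    @property
    def percent_rounded(self) -> int:
        return int(round_half_up(self.percent_of_expected, 0))


def erythrulose_check(load: float, measured: float) -> StoichiometryRecord:
    """Compare a measured erythrulose yield with the half-load expectation.

    Percent of expected is kept at full precision; values above 100
    (over-recovery) are legal and reported as-is.
    """
    if load <= 0:
        raise ValueError(f"substrate load must be positive, got {load}")
    if measured < 0:
        raise ValueError(f"measured product cannot be negative, got {measured}")
    expected = load / 2.0
    return StoichiometryRecord(
        substrate_load=load,
        expected_product=expected,
        measured_product=measured,
        percent_of_expected=100.0 * measured / expected,
    )


def batch_check(rows: Iterable[tuple[float, float]]) -> pd.DataFrame:
    """Run :func:`erythrulose_check` over (load, measured) pairs."""
    records = [erythrulose_check(load, measured) for load, measured in rows]
    return pd.DataFrame(
        {
            "substrate_load_mM": [r.substrate_load for r in records],
            "expected_mM": [r.expected_product for r in records],
            "measured_mM": [r.measured_product for r in records],
            "percent_of_expected": [r.percent_rounded for r in records],
        }
    )
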