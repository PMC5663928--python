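"""Thermodynamic-cycle closure and two-temperature enthalpy-entropy split.

Relative binding free energies of the three linker transformations
(phosphodiester -> carbamate, phosphodiester -> triazole, carbamate ->
triazole) form a closed cycle whose signed sum should vanish; the residual
is the cycle-closure error.  Running the same transformation at two
temperatures allows a finite-difference van't Hoff decomposition:

    ddS = -(ddG(T2) - ddG(T1)) / (T2 - T1)
    ddH = ddG(T2) + T2 * ddS

so that ``ddH - T2*ddS == ddG(T2)`` holds exactly.  SEMs propagate linearly
treating the two temperature legs as independent.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import constants

__all__ = [
    "CycleLeg",
    "CycleClosure",
    "ThermoDecomposition",
    "cycle_closure",
    "vant_hoff_decompose",
    "round_to_nearest",
]


@dataclass
class CycleLeg:
    """One transformation edge of a thermodynamic cycle.

    ``start``/``end`` are ligand-state labels; ``orientation`` is +1 when
    the leg is traversed start -> end in the cycle, -1 when reversed.
    """

    label: str
    start: str
    end: str
    ddG: float  # kcal/mol
    sem: float = 0.0
    orientation: int = 1

    def __post_init__(self) -> None:
        if self.orientation not in (1, -1):
            raise ValueError("orientation must be +1 or -1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


@dataclass
class CycleClosure:
    closure: float  # kcal/mol
    sem: float
    legs: List[CycleLeg]


def cycle_closure(legs: Sequence[CycleLeg]) -> CycleClosure:
    """Signed sum of ddG around a closed loop, with quadrature SEM.

    Validates that the oriented legs form a closed loop: every state must
    be entered exactly as often as it is left.
    """
    if len(legs) < 2:
        raise ValueError("a cycle needs at least 2 legs")
    balance: dict = defaultdict(int)
    for leg in legs:
        a, b = (leg.start, leg.end) if leg.orientation == 1 else (leg.end, leg.start)
        balance[a] -= 1  # leaving a
        balance[b] += 1  # entering b
    unmatched = sorted(state for state, k in balance.items() if k != 0)
    if unmatched:
        raise ValueError(
            f"legs do not form a closed cycle; unmatched state(s): {unmatched}"
        )
    closure = sum(leg.orientation * leg.ddG for leg in legs)
    sem = math.sqrt(sum(leg.sem**2 for leg in legs))
    return CycleClosure(closure=float(closure), sem=sem, legs=list(legs))


@dataclass
class ThermoDecomposition:
    """Finite-temperature-difference decomposition of ddG into ddH, -T*ddS."""

    T1: float
    T2: float
    ddG_T1: float
    ddG_T2: float
    sem_T1: float
    sem_T2: float
    ddS: float  # kcal/mol/K
    ddS_sem: float
    ddH: float  # kcal/mol, anchored at T2
    ddH_sem: float
    minus_T_ddS: float  # kcal/mol at report_T
    minus_T_ddS_sem: float
    report_T: float


def vant_hoff_decompose(
    ddG_T1: float,
    ddG_T2: float,
    T1: float = constants.TEMPERATURE_LOW_K,
    T2: float = constants.TEMPERATURE_HIGH_K,
    sem_T1: float = 0.0,
    sem_T2: float = 0.0,
    report_T: Optional[float] = None,
) -> ThermoDecomposition:
    """Decompose two-temperature ddG values into ddS, ddH and -T*ddS.

    ``ddH`` is anchored at T2 so the identity ``ddH - T2*ddS == ddG_T2``
    holds exactly; ``report_T`` (default T2) sets the temperature of the
    reported entropic term.
    """
    if T1 == T2:
        raise ValueError("T1 and T2 must differ")
    if sem_T1 < 0 or sem_T2 < 0:
        raise ValueError("SEMs must be >= 0")
    if report_T is None:
        report_T = T2
    dT = T2 - T1
    ddS = -(ddG_T2 - ddG_T1) / dT
    ddH = ddG_T2 + T2 * ddS
    ddS_sem = math.sqrt(sem_T1**2 + sem_T2**2) / abs(dT)
    ddH_sem = math.sqrt((T2 * sem_T1) ** 2 + (T1 * sem_T2) ** 2) / abs(dT)
    return ThermoDecomposition(
        T1=T1,
        T2=T2,
        ddG_T1=ddG_T1,
        ddG_T2=ddG_T2,
        sem_T1=sem_T1,
        sem_T2=sem_T2,
        ddS=ddS,
        ddS_sem=ddS_sem,
        ddH=ddH,
        ddH_sem=ddH_sem,
        minus_T_ddS=-report_T * ddS,
        minus_T_ddS_sem=report_T * ddS_sem,
        report_T=report_T,
    )


def round_to_nearest(value: float, step: float) -> float:
    """Round to the nearest multiple of ``step`` (report-precision helper)."""
    return step * round(value / step)


def decomposition_table_row(d: ThermoDecomposition) -> dict:
    """Report-precision view: ddG to 1 decimal, ddH and -T*ddS to nearest 10.

    Raw values are kept alongside so machine-readable output loses nothing.
    """
    return {
        "ddG_T1": round(d.ddG_T1, 1),
        "ddG_T2": round(d.ddG_T2, 1),
        "ddH_rounded": round_to_nearest(d.ddH, 10.0),
        "minus_T_ddS_rounded": round_to_nearest(d.minus_T_ddS, 10.0),
        "ddH_raw": d.ddH,
        "minus_T_ddS_raw": d.minus_T_ddS,
        "ddS_raw": d.ddS,
        "ddH_sem": d.ddH_sem,
        "minus_T_ddS_sem": d.minus_T_ddS_sem,
    }
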