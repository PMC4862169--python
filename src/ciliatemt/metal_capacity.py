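"""Theoretical metal-binding capacity from Cys counts.

All Cys thiolates are assumed to coordinate metal with the vertebrate-MT
stoichiometries Cd7(Cys)20 and Cu12(Cys)20, i.e. 7/20 Cd or 12/20 Cu ions
per Cys residue.  Ion counts are rounded half away from zero, the rule
that reproduces every worked example in the source data (54 Cys -> 19 Cd,
24 -> 8, 25 -> 9, 32 -> 19 Cu, 48 -> 17 Cd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

IONS_PER_CYS = {"Cd": 7 / 20, "Cu": 12 / 20}


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class CapacityEstimate:
    seq_id: str
    metal: str
    n_cys: int
    raw: float
    rounded: int


def theoretical_capacity(n_cys: int, metal: str,
                         seq_id: str = "") -> CapacityEstimate:
    """Ions per molecule for a protein with ``n_cys`` cysteines."""
    if metal not in IONS_PER_CYS:
        raise ValueError(f"unknown metal {metal!r} (expected Cd or Cu)")
    if n_cys < 0:
        raise ValueError("n_cys must be non-negative")
    raw = n_cys * IONS_PER_CYS[metal]
    return CapacityEstimate(seq_id, metal, n_cys, raw, _round_half_away(raw))


@dataclass
class CapacitySummary:
    estimates: list
    mean_raw: float
    mean_rounded: int


def capacity_summary(profiles: list, metal: str) -> CapacitySummary:
    """Per-sequence capacities plus the cohort mean (raw and rounded)."""
    if not profiles:
        raise ValueError("need at least one profile")
    estimates = [
        theoretical_capacity(p.total_cys, metal, seq_id=p.seq_id)
        for p in profiles
    ]
    mean_raw = sum(e.raw for e in estimates) / len(estimates)
    return CapacitySummary(estimates, mean_raw, _round_half_away(mean_raw))
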