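"""Selectivity-score analytics for multi-target screening profiles.

The selectivity score S of a compound screened against a protein panel is
the fraction of proteins whose predicted docking score exceeds an activity
cutoff.  The default cutoff, 5.52 pKd, is the negative log10 of the 3 µM
dissociation-constant threshold conventionally used to call a kinase
interaction active; a looser tolerance cutoff of 4.52 pKd admits
borderline interactions.  Low S means a selective compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log10
from typing import Iterable, Sequence

#: pKd equivalent of the 3 µM activity threshold, stored at the 2 d.p.
#: precision it is conventionally quoted at.
DEFAULT_CUTOFF_PKD: float = 5.52
#: Relaxed cutoff used when a tolerance is granted.
DEFAULT_TOLERANCE_CUTOFF_PKD: float = 4.52


def pkd_from_kd(kd_molar: float) -> float:
    """Convert a dissociation constant (molar) to the pKd scale: -log10(Kd)."""
    if not kd_molar > 0:
        raise ValueError(f"Kd must be positive, got {kd_molar!r}")
    return -log10(kd_molar)


def selectivity_score(scores: Sequence[float], cutoff: float = DEFAULT_CUTOFF_PKD) -> float:
    """Fraction of per-protein scores strictly greater than the cutoff.

    E.g. 45 of 100 proteins above 5.52 pKd gives S = 0.45.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("selectivity score needs at least one per-protein score")
    return sum(1 for s in scores if s > cutoff) / len(scores)


@dataclass
class SelectivityProfile:
    """One compound's per-protein scores plus the derived selectivity calls."""

    compound_id: str
    scores: dict[str, float]  # protein id -> final score, pKd scale
    cutoff: float = DEFAULT_CUTOFF_PKD
    tolerance_cutoff: float = DEFAULT_TOLERANCE_CUTOFF_PKD
    S: float = field(init=False)
    hits: list[str] = field(init=False)
    tolerance_hits: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if self.tolerance_cutoff > self.cutoff:
            raise ValueError("tolerance cutoff must not exceed the primary cutoff")
        self.S = selectivity_score(list(self.scores.values()), self.cutoff)
        self.hits = [p for p, s in self.scores.items() if s > self.cutoff]
        self.tolerance_hits = [p for p, s in self.scores.items() if s > self.tolerance_cutoff]


@dataclass
class TargetCalls:
    """Partition of a profile's proteins relative to a known primary-target set."""

    primary_found: list[str]
    off_targets_found: list[str]
    tolerance_only: list[str]


def call_targets(profile: SelectivityProfile, known_primary: Iterable[str]) -> TargetCalls:
    """Split hits into primary targets, off-targets, and tolerance-only calls.

    Primary/off-target status uses the strict cutoff; scores in
    (tolerance_cutoff, cutoff] land in the tolerance-only bucket.
    """
    primary = set(known_primary)
    return TargetCalls(
        primary_found=[p for p in profile.hits if p in primary],
        off_targets_found=[p for p in profile.hits if p not in primary],
        tolerance_only=[p for p in profile.tolerance_hits if p not in profile.hits],
    )
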