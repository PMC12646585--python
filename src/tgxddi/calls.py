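"""Viability-based validity rules and the call hierarchy.

Sample-level classifier calls are rolled up to concentration-level and then
chemical-level calls, gated by the MTT cytotoxicity rules: a concentration
with overt cytotoxicity (viability < 40%) is excluded outright, and a
negative (non-DDI) chemical call requires a *valid test* — the top
concentration must have induced 55% +/- 5% cytotoxicity (40-50% viability,
inclusive) or have reached at least the 1 mM limit concentration.  A
positive DDI call stands regardless of validity; the paradigm is
deliberately conservative, so ties always break toward the more
hazard-conservative call (DDI over inconclusive over non-DDI).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .classify import DDI, INCONCLUSIVE, NON_DDI
from .errors import (
    DegenerateAssayError,
    InsufficientReplicatesError,
    NoCallError,
)

# Exclusion / validity reasons
OVERT_CYTOTOXICITY = "OVERT_CYTOTOXICITY"
QC = "QC"
NONE = "NONE"
TARGET_CYTOTOXICITY_MET = "TARGET_CYTOTOXICITY_MET"
LIMIT_CONCENTRATION = "LIMIT_CONCENTRATION"
NOT_VALID = "NOT_VALID"

#: Hazard-conservatism order used for every tie-break.
_CONSERVATIVE_ORDER = {DDI: 0, INCONCLUSIVE: 1, NON_DDI: 2}


@dataclass(frozen=True)
class ValidityPolicy:
    """Cytotoxicity thresholds (percent viability and mM)."""

    exclusion_viability_max: float = 40.0
    negative_call_viability_range: tuple[float, float] = (40.0, 50.0)
    limit_concentration_mM: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.negative_call_viability_range
        if lo > hi:
            raise ValueError("negative_call_viability_range bounds must be ordered")
        if min(self.exclusion_viability_max, lo, self.limit_concentration_mM) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class ConcentrationCall:
    compound: str
    lab: str
    concentration_rank: int
    call: str | None  # None when excluded
    n_samples: int
    excluded: bool = False
    reason: str = NONE


@dataclass(frozen=True)
class ChemicalCall:
    compound: str
    lab: str
    call: str
    valid_test: bool
    validity_reason: str


def viability_from_mtt(a_treated: float, a_control: float, a_blank: float) -> float:
    """Percent viability from MTT absorbances (570 nm), clipped to [0, 100].

    Raises
    ------
    DegenerateAssayError
        If the solvent-control absorbance does not exceed the blank.
    """
    if a_control <= a_blank:
        raise DegenerateAssayError(
            f"control absorbance {a_control} does not exceed blank {a_blank}"
        )
    pct = 100.0 * (a_treated - a_blank) / (a_control - a_blank)
    return float(min(100.0, max(0.0, pct)))


def screen_concentrations(
    viability: pd.DataFrame, policy: ValidityPolicy | None = None
) -> pd.DataFrame:
    """Flag overtly cytotoxic concentrations (viability strictly below 40%).

    ``viability`` needs columns lab, compound, concentration_rank,
    viability_pct; the result adds ``excluded`` and ``reason``.
    """
    policy = policy or ValidityPolicy()
    out = viability.copy()
    out["excluded"] = out["viability_pct"] < policy.exclusion_viability_max
    out["reason"] = out["excluded"].map({True: OVERT_CYTOTOXICITY, False: NONE})
    return out


def test_validity(
    viability: pd.DataFrame, policy: ValidityPolicy | None = None
) -> tuple[bool, str]:
    """Whether one (lab, compound) test supports a negative call.

    ``viability`` holds that test's rows; the top concentration is the one
    with the highest rank.  Valid iff top-concentration viability lies in
    the closed 40-50% window, or the top concentration reached the 1 mM
    limit ("reached or exceeded", hence inclusive).
    """
    policy = policy or ValidityPolicy()
    top = viability.loc[viability["concentration_rank"].idxmax()]
    lo, hi = policy.negative_call_viability_range
    if lo <= top["viability_pct"] <= hi:
        return True, TARGET_CYTOTOXICITY_MET
    conc = top.get("concentration_mM")
    if conc is not None and pd.notna(conc) and conc >= policy.limit_concentration_mM:
        return True, LIMIT_CONCENTRATION
    return False, NOT_VALID


def _plurality(calls: Sequence[str]) -> str:
    """Plurality vote with ties broken toward the hazard-conservative call."""
    counts = {c: 0 for c in _CONSERVATIVE_ORDER}
    for c in calls:
        counts[c] += 1
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return min(winners, key=_CONSERVATIVE_ORDER.__getitem__)


def concentration_call(
    sample_calls: Sequence[str],
    compound: str = "",
    lab: str = "",
    concentration_rank: int = 0,
) -> ConcentrationCall:
    """Majority call over the replicate sample calls at one concentration.

    Raises
    ------
    InsufficientReplicatesError
        With fewer than two replicate calls.
    """
    if len(sample_calls) < 2:
        raise InsufficientReplicatesError(
            f"{lab}/{compound} rank {concentration_rank}: "
            f"{len(sample_calls)} replicate call(s), need >= 2"
        )
    return ConcentrationCall(
        compound=compound,
        lab=lab,
        concentration_rank=concentration_rank,
        call=_plurality(sample_calls),
        n_samples=len(sample_calls),
    )


def chemical_call(
    conc_calls: Sequence[ConcentrationCall],
    validity: tuple[bool, str],
    compound: str = "",
    lab: str = "",
) -> ChemicalCall:
    """Overall call for one (lab, compound) test.

    DDI if any non-excluded concentration is DDI (validity does not gate
    positives); otherwise non-DDI only when the test is valid and the
    majority of remaining concentration calls are non-DDI; otherwise
    inconclusive.

    Raises
    ------
    NoCallError
        If every concentration was excluded.
    """
    active = [cc for cc in conc_calls if not cc.excluded and cc.call is not None]
    if not active:
        raise NoCallError(f"{lab}/{compound}: all concentrations excluded")
    valid, reason = validity
    compound = compound or active[0].compound
    lab = lab or active[0].lab
    calls = [cc.call for cc in active]
    if DDI in calls:
        overall = DDI
    elif valid and _plurality(calls) == NON_DDI:
        overall = NON_DDI
    else:
        overall = INCONCLUSIVE
    return ChemicalCall(
        compound=compound, lab=lab, call=overall, valid_test=valid, validity_reason=reason
    )
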