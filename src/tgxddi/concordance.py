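"""Interlaboratory agreement and reference-RNA reproducibility.

Chemical calls from pairs of laboratories are compiled into 2x2 agreement
tables over the compounds both labs called conclusively, and three
chance-corrected coefficients are computed: Cohen's kappa (marginal-based
chance agreement), PABAK (prevalence- and bias-adjusted kappa; for two
categories simply 2*Po - 1), and Gwet's AC1 (chance term 2*pi*(1-pi) with
pi the average of the two labs' DDI marginals, robust at extreme
prevalence).  Coefficients are interpreted on the conventional band scale
poor / fair / moderate / good / very good.

Technical reproducibility across sites is assessed on the shared reference
RNA: counts are scaled to each laboratory's total, log2 transformed, and
compared by pairwise Pearson and Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .calls import ChemicalCall
from .classify import DDI, NON_DDI
from .errors import InsufficientDataError, NoOverlapError, UndefinedCoefficientError


@dataclass(frozen=True)
class AgreementTable:
    """2x2 agreement counts for a lab pair (category 1 = DDI).

    ``n11``: both DDI; ``n10``: lab A DDI, lab B non-DDI; ``n01``: the
    reverse; ``n00``: both non-DDI.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total < 1:
            raise ValueError("agreement table must contain at least one pair")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def po(self) -> float:
        """Observed agreement."""
        return (self.n11 + self.n00) / self.total

    @property
    def marginals(self) -> tuple[float, float]:
        """Each lab's DDI-call proportion (lab A, lab B)."""
        return (
            (self.n11 + self.n10) / self.total,
            (self.n11 + self.n01) / self.total,
        )


@dataclass(frozen=True)
class ConcordanceStats:
    kappa: float
    pabak: float
    ac1: float
    kappa_band: str
    pabak_band: str
    ac1_band: str


def _calls_to_map(calls) -> dict[str, str]:
    if isinstance(calls, Mapping):
        return dict(calls)
    out = {}
    for item in calls:
        if isinstance(item, ChemicalCall):
            # Only conclusive calls enter agreement analysis; a non-DDI
            # call additionally requires a valid test.
            if item.call == DDI or (item.call == NON_DDI and item.valid_test):
                out[item.compound] = item.call
        else:
            compound, call = item
            out[compound] = call
    return out


def agreement_table(calls_a, calls_b) -> AgreementTable:
    """Build the 2x2 table over compounds conclusively called by both labs.

    Inconclusive calls are dropped pairwise.  ``calls_a``/``calls_b`` may be
    mappings compound -> call, iterables of (compound, call) pairs, or
    :class:`ChemicalCall` sequences (where only valid conclusive calls count).

    Raises
    ------
    NoOverlapError
        If no compound remains in the intersection.
    """
    a = {k: v for k, v in _calls_to_map(calls_a).items() if v in (DDI, NON_DDI)}
    b = {k: v for k, v in _calls_to_map(calls_b).items() if v in (DDI, NON_DDI)}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise NoOverlapError("no commonly tested, conclusively called compounds")
    n11 = sum(a[c] == DDI and b[c] == DDI for c in shared)
    n10 = sum(a[c] == DDI and b[c] == NON_DDI for c in shared)
    n01 = sum(a[c] == NON_DDI and b[c] == DDI for c in shared)
    n00 = sum(a[c] == NON_DDI and b[c] == NON_DDI for c in shared)
    return AgreementTable(n11=n11, n10=n10, n01=n01, n00=n00)


def cohen_kappa(table: AgreementTable) -> float:
    """kappa = (Po - Pe) / (1 - Pe) with Pe from the row/column marginals."""
    pa, pb = table.marginals
    pe = pa * pb + (1.0 - pa) * (1.0 - pb)
    if pe >= 1.0:
        raise UndefinedCoefficientError("both raters constant; kappa undefined")
    return (table.po - pe) / (1.0 - pe)


def pabak(table: AgreementTable) -> float:
    """Prevalence- and bias-adjusted kappa; for two categories 2*Po - 1."""
    return 2.0 * table.po - 1.0


def gwet_ac1(table: AgreementTable) -> float:
    """AC1 = (Po - Pe) / (1 - Pe) with Pe = 2*pi*(1-pi), pi the mean of the
    two labs' DDI marginals."""
    pa, pb = table.marginals
    pi = 0.5 * (pa + pb)
    pe = 2.0 * pi * (1.0 - pi)
    if pe >= 1.0:
        raise UndefinedCoefficientError("chance agreement is 1; AC1 undefined")
    return (table.po - pe) / (1.0 - pe)


#: Interpretation bands.  The printed scale (poor < 0.2, fair 0.21-0.4,
#: moderate 0.41-0.6, good 0.61-0.8, very good 0.81-1) leaves micro-gaps
#: between bands; each printed lower bound is treated as inclusive and a
#: value inside a gap maps to the band below it, so e.g. 0.205 is "fair".
_BANDS = (
    (0.81, "very good"),
    (0.61, "good"),
    (0.41, "moderate"),
    (0.20, "fair"),
)


def interpret_agreement(coefficient: float) -> str:
    """Band label for an agreement coefficient in [-1, 1]."""
    if not (-1.0 <= coefficient <= 1.0):
        raise ValueError(f"coefficient must be in [-1, 1], got {coefficient}")
    for cut, label in _BANDS:
        if coefficient >= cut:
            return label
    return "poor"


def concordance_stats(table: AgreementTable) -> ConcordanceStats:
    """All three coefficients with their interpretation bands."""
    k = cohen_kappa(table)
    p = pabak(table)
    a = gwet_ac1(table)
    return ConcordanceStats(
        kappa=k,
        pabak=p,
        ac1=a,
        kappa_band=interpret_agreement(k),
        pabak_band=interpret_agreement(p),
        ac1_band=interpret_agreement(a),
    )


def pairwise_concordance(calls_by_lab: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    """Coefficient table for every lab pair (tidy rows lab_a, lab_b,
    kappa, pabak, ac1, bands).

    A coefficient that is undefined for a pair (e.g. kappa when both labs
    call every compound identically one way) is reported as NaN with band
    "undefined" instead of aborting the whole table.
    """

    def _safe(fn, table):
        try:
            value = fn(table)
        except UndefinedCoefficientError:
            return float("nan"), "undefined"
        return value, interpret_agreement(value)

    labs = sorted(calls_by_lab)
    rows = []
    for i, la in enumerate(labs):
        for lb in labs[i + 1:]:
            table = agreement_table(calls_by_lab[la], calls_by_lab[lb])
            k, k_band = _safe(cohen_kappa, table)
            p, p_band = _safe(pabak, table)
            a, a_band = _safe(gwet_ac1, table)
            rows.append(
                {
                    "lab_a": la,
                    "lab_b": lb,
                    "n": table.total,
                    "kappa": k,
                    "pabak": p,
                    "ac1": a,
                    "kappa_band": k_band,
                    "pabak_band": p_band,
                    "ac1_band": a_band,
                }
            )
    return pd.DataFrame(rows)


def reference_rna_correlations(
    counts: pd.DataFrame, pseudocount: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson and Spearman matrices of reference-RNA counts.

    ``counts`` is genes x labs.  Counts are scaled relative to each lab's
    total, log2 transformed (with a pseudocount guard), and correlated.

    Raises
    ------
    InsufficientDataError
        With fewer than 2 labs or fewer than 3 shared genes.
    """
    if counts.shape[1] < 2:
        raise InsufficientDataError("need counts from at least 2 labs")
    counts = counts.dropna()
    if counts.shape[0] < 3:
        raise InsufficientDataError("need at least 3 shared genes")
    totals = counts.sum(axis=0)
    scaled = np.log2((counts + pseudocount) / totals)
    pearson = scaled.corr(method="pearson")
    spearman = scaled.corr(method="spearman")
    return pearson, spearman
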