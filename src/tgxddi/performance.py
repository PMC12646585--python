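"""Scoring chemical calls against the truth standard.

Confusion tables (rows: assay call, columns: truth standard), sensitivity /
specificity / accuracy with Clopper-Pearson exact binomial confidence
intervals, and within-laboratory replicate concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import beta

from .calls import ChemicalCall
from .classify import DDI, INCONCLUSIVE, NON_DDI
from .errors import LabelingError


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts against the truth standard; inconclusive calls are
    tallied separately, never inside the table."""

    tp: int  # call DDI, truth DDI
    fn: int  # call nonDDI, truth DDI
    fp: int  # call DDI, truth nonDDI
    tn: int  # call nonDDI, truth nonDDI
    n_inconclusive: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn, self.n_inconclusive) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one call")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class BinomialCI:
    """An exact (Clopper-Pearson) binomial confidence interval."""

    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "clopper-pearson"

    def as_percent(self) -> tuple[int, int, int]:
        """(estimate, lower, upper) rounded half-up to whole percent,
        the display convention used for published assay summaries."""
        return (
            round_half_up_pct(self.estimate),
            round_half_up_pct(self.lower),
            round_half_up_pct(self.upper),
        )


@dataclass(frozen=True)
class PerformanceSummary:
    """Sensitivity, specificity, and accuracy with exact CIs.

    Any statistic with a zero denominator is ``None`` (unavailable),
    never fabricated.
    """

    table: ConfusionTable
    sensitivity: BinomialCI | None
    specificity: BinomialCI | None
    accuracy: BinomialCI | None


def round_half_up_pct(proportion: float) -> int:
    """Round a proportion to a whole percent, halves away from zero."""
    return int(math.floor(proportion * 100.0 + 0.5))


def confusion_table(
    calls: Iterable[ChemicalCall] | Iterable[tuple[str, str]],
    truth: Mapping[str, str],
    include_inconclusive: str = "exclude",
) -> ConfusionTable:
    """Tally chemical calls against truth labels.

    ``calls`` may be :class:`ChemicalCall` objects or ``(compound, call)``
    pairs.  Inconclusive calls are excluded from the 2x2 (and counted in
    ``n_inconclusive``) under the default policy; ``include_inconclusive=
    "as_error"`` counts them against the truth label instead.

    Raises
    ------
    LabelingError
        If a called compound has no truth label.
    """
    if include_inconclusive not in ("exclude", "as_error"):
        raise ValueError("include_inconclusive must be 'exclude' or 'as_error'")
    tp = fn = fp = tn = n_inc = 0
    for item in calls:
        if isinstance(item, ChemicalCall):
            compound, call = item.compound, item.call
        else:
            compound, call = item
        if compound not in truth:
            raise LabelingError(f"no truth label for compound {compound!r}")
        label = truth[compound]
        if call == INCONCLUSIVE:
            if include_inconclusive == "exclude":
                n_inc += 1
                continue
            # An inconclusive counted as an error is an FN for a DDI truth
            # and an FP for a non-DDI truth.
            call = NON_DDI if label == DDI else DDI
        if label == DDI:
            tp += call == DDI
            fn += call == NON_DDI
        else:
            fp += call == DDI
            tn += call == NON_DDI
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn, n_inconclusive=n_inc)


def clopper_pearson(x: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact binomial confidence interval via beta quantiles.

    The lower bound is 0 when ``x == 0`` and the upper bound 1 when
    ``x == n``.
    """
    if not (0 <= x <= n) or n < 1:
        raise ValueError(f"invalid counts x={x}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return BinomialCI(estimate=x / n, lower=lower, upper=upper, level=level)


def summarize_performance(table: ConfusionTable, level: float = 0.95) -> PerformanceSummary:
    """Sensitivity tp/(tp+fn), specificity tn/(tn+fp), accuracy
    (tp+tn)/total, each with its exact CI."""

    def _stat(x: int, n: int) -> BinomialCI | None:
        return clopper_pearson(x, n, level) if n > 0 else None

    return PerformanceSummary(
        table=table,
        sensitivity=_stat(table.tp, table.tp + table.fn),
        specificity=_stat(table.tn, table.tn + table.fp),
        accuracy=_stat(table.tp + table.tn, table.total),
    )


def within_lab_concordance(sample_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-lab proportion of tests whose replicate calls all agree.

    ``sample_calls`` needs columns lab, compound, call and (optionally)
    concentration_rank; one *test* is a (lab, compound) pair, and it is
    concordant iff within every concentration the replicate calls are
    identical.  The caller restricts the input to valid tests with control
    compounds removed.  Labs with zero tests report a missing rate.
    """
    required = {"lab", "compound", "call"}
    missing = required - set(sample_calls.columns)
    if missing:
        raise ValueError(f"sample_calls missing columns {sorted(missing)}")
    df = sample_calls.copy()
    if "concentration_rank" not in df.columns:
        df["concentration_rank"] = 1

    rows = []
    for lab, lab_df in df.groupby("lab"):
        n_tests = n_concordant = 0
        for _, comp_df in lab_df.groupby("compound"):
            n_tests += 1
            concordant = all(
                grp["call"].nunique() == 1
                for _, grp in comp_df.groupby("concentration_rank")
            )
            n_concordant += concordant
        rows.append(
            {
                "lab": lab,
                "n_tests": n_tests,
                "n_concordant": n_concordant,
                "concordance": n_concordant / n_tests if n_tests else None,
            }
        )
    return pd.DataFrame(rows)


def concordance_rate(n_concordant: int, n_tests: int) -> float | None:
    """Plain proportion of concordant tests; ``None`` when no test was run."""
    if n_tests == 0:
        return None
    return n_concordant / n_tests
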