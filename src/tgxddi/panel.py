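"""Probe panel definition for the TGx-DDI NanoString codeset.

The assay measures a fixed 64-gene biomarker panel in p53-competent TK6
cells, alongside housekeeping genes used for mRNA-content normalization and
the platform's synthetic positive/negative control probes.  The positive
control probes are spiked at six known input amounts spanning a ~1000-fold
range, which lets QC verify count linearity per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_BIOMARKER_GENES = 64

#: Nominal spike-in amounts (fM) of the six positive-control probes,
#: following the platform's standard serial dilution.
POS_CONTROL_NOMINAL_FM = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)

# A few canonical p53-responsive stress-response transcripts anchor the
# panel; the remainder are synthetic placeholder identifiers.
_ANCHOR_GENES = ("ATF3", "CDKN1A", "GADD45A", "MDM2", "BTG2", "PLK3")


@dataclass(frozen=True)
class PanelSpec:
    """Immutable description of the probe panel.

    Attributes
    ----------
    biomarker_genes:
        Exactly 64 endogenous classifier genes, in panel order.
    housekeeping_genes:
        Stably expressed genes used for content normalization.
    pos_control_probes:
        ``(probe_name, nominal_fM)`` pairs for the six spike-in levels.
    neg_control_probes:
        Background probes with no target.
    """

    biomarker_genes: tuple[str, ...]
    housekeeping_genes: tuple[str, ...]
    pos_control_probes: tuple[tuple[str, float], ...]
    neg_control_probes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.biomarker_genes) != N_BIOMARKER_GENES:
            raise ValueError(
                f"biomarker panel must contain exactly {N_BIOMARKER_GENES} genes, "
                f"got {len(self.biomarker_genes)}"
            )
        all_ids = list(self.all_genes)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("probe identifiers must be unique across categories")

    @property
    def pos_control_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.pos_control_probes)

    @property
    def all_genes(self) -> tuple[str, ...]:
        """All probe identifiers in canonical order (biomarker, HK, pos, neg)."""
        return (
            self.biomarker_genes
            + self.housekeeping_genes
            + self.pos_control_names
            + self.neg_control_probes
        )

    def code_class(self, gene: str) -> str:
        """RCC ``CodeClass`` of a probe (Endogenous/Housekeeping/Positive/Negative)."""
        if gene in self.biomarker_genes:
            return "Endogenous"
        if gene in self.housekeeping_genes:
            return "Housekeeping"
        if gene in self.pos_control_names:
            return "Positive"
        if gene in self.neg_control_probes:
            return "Negative"
        raise KeyError(f"unknown probe {gene!r}")


def make_panel(n_housekeeping: int = 10, seed: int = 0) -> PanelSpec:
    """Build a synthetic :class:`PanelSpec` with 64 biomarker genes.

    The gene order is shuffled deterministically from ``seed`` so that
    downstream code cannot rely on a sorted panel.

    Parameters
    ----------
    n_housekeeping:
        Number of housekeeping probes (>= 1).
    seed:
        Seed for the deterministic ordering.
    """
    if n_housekeeping < 1:
        raise ValueError("n_housekeeping must be >= 1")
    rng = np.random.default_rng(seed)
    biomarker = list(_ANCHOR_GENES) + [
        f"DDIG{i:03d}" for i in range(1, N_BIOMARKER_GENES - len(_ANCHOR_GENES) + 1)
    ]
    rng.shuffle(biomarker)
    housekeeping = tuple(f"HK{i:02d}" for i in range(1, n_housekeeping + 1))
    pos = tuple(
        (f"POS_{chr(ord('A') + i)}", conc)
        for i, conc in enumerate(POS_CONTROL_NOMINAL_FM)
    )
    neg = tuple(f"NEG_{chr(ord('A') + i)}" for i in range(8))
    return PanelSpec(
        biomarker_genes=tuple(biomarker),
        housekeeping_genes=housekeeping,
        pos_control_probes=pos,
        neg_control_probes=neg,
    )
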