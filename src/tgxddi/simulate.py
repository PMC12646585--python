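"""Synthetic ring-trial data generator.

Generates every input the analysis pipeline consumes: a probe panel, a
labeled reference-agent training set, multi-laboratory count data with lab
effects and concentration-dependent treatment effects, and MTT viability
tables driven by Hill curves.

The statistical model is a deliberately simple stand-in for the biomarker's
documented structure, not an estimate of the real signature: a fixed subset
of the 64 classifier genes ("responsive" genes) shifts upward under
DNA-damage-inducing exposure on the log2 scale; counts are
negative-binomial around log-linear means combining a gene baseline, a
per-laboratory multiplicative library-size effect, and the treatment effect
scaled by concentration rank (1/3, 2/3, 1).  The default experimental
design mirrors the ring trial: four laboratories, fourteen blinded test
compounds at three concentrations in triplicate, positive/negative control
compounds, per-batch solvent controls, and a shared universal reference RNA
sample per laboratory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import DDI, NON_DDI, LabeledProfileSet
from .io import CountMatrix
from .panel import N_BIOMARKER_GENES, PanelSpec, make_panel  # noqa: F401  (re-export)


@dataclass(frozen=True)
class EffectModel:
    """Generative parameters for the biomarker's response to exposure.

    ``ddi_effect_mean``/``ddi_effect_sd`` describe the log2 fold-change of
    responsive biomarker genes under a DDI exposure at the top
    concentration; ``nonddi_effect_sd`` is the spread of null log2
    fold-changes; ``fraction_responsive`` is the fraction of the 64 genes
    that respond; ``dispersion`` is the negative-binomial dispersion of
    probe counts (var = mu + dispersion * mu^2); ``lab_effect_sd`` is the
    spread of per-lab multiplicative library-size effects on the natural
    log scale.
    """

    ddi_effect_mean: float = 2.0
    ddi_effect_sd: float = 0.5
    nonddi_effect_sd: float = 0.25
    fraction_responsive: float = 0.75
    dispersion: float = 0.05
    lab_effect_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("ddi_effect_sd", "nonddi_effect_sd", "dispersion", "lab_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.fraction_responsive <= 1.0):
            raise ValueError("fraction_responsive must be in [0, 1]")

    def responsive_genes(self, panel: PanelSpec) -> tuple[str, ...]:
        """The deterministic subset of biomarker genes that respond to DDI
        exposure: the first ceil(64 * fraction) genes in panel order."""
        k = math.ceil(N_BIOMARKER_GENES * self.fraction_responsive)
        return panel.biomarker_genes[:k]


@dataclass(frozen=True)
class ViabilityCurve:
    """Hill-shaped concentration-viability curve for the MTT assay."""

    ec50: float
    hill: float = 2.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if not (0.0 <= self.floor < 100.0):
            raise ValueError("floor must be in [0, 100)")


def viability_at(curve: ViabilityCurve, concentration: float) -> float:
    """Percent viability at a concentration; 100 at zero, ``floor`` at infinity,
    and (floor + 100)/2 at the EC50."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0:
        return 100.0
    v = curve.floor + (100.0 - curve.floor) / (1.0 + (concentration / curve.ec50) ** curve.hill)
    return float(min(100.0, max(curve.floor, v)))


@dataclass(frozen=True)
class CompoundSpec:
    """One test or control compound in the design.

    Concentrations are stored in mM (strictly increasing); ``display_units``
    only affects reporting.
    """

    code: str
    name: str
    truth: str  # DDI | nonDDI
    requires_activation: bool
    concentrations_mM: tuple[float, ...]
    display_units: str = "mM"
    role: str = "test"  # test | positive_control | negative_control

    def __post_init__(self) -> None:
        if self.truth not in (DDI, NON_DDI):
            raise ValueError(f"truth must be DDI or nonDDI, got {self.truth!r}")
        concs = self.concentrations_mM
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError(f"{self.code}: concentrations must be strictly increasing")

    @property
    def top_concentration_mM(self) -> float:
        return self.concentrations_mM[-1]


@dataclass(frozen=True)
class SimDesign:
    """Ring-trial experimental design."""

    labs: tuple[str, ...]
    compounds: tuple[CompoundSpec, ...]
    controls: tuple[CompoundSpec, ...] = ()
    n_replicates: int = 3
    n_solvent_controls: int = 3
    include_controls: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if len(self.labs) < 1:
            raise ValueError("at least one lab required")

    @property
    def all_compounds(self) -> tuple[CompoundSpec, ...]:
        return self.compounds + (self.controls if self.include_controls else ())

    @property
    def truth(self) -> dict[str, str]:
        return {c.code: c.truth for c in self.all_compounds}


def _uM(x: float) -> float:
    return x / 1000.0


def _nM(x: float) -> float:
    return x / 1e6


def ring_trial_design(
    n_labs: int = 4,
    n_replicates: int = 3,
    include_controls: bool = True,
    seed: int = 0,
) -> SimDesign:
    """The default four-lab, fourteen-compound design.

    Six DDI agents (two requiring metabolic activation), eight non-DDI
    agents, and three control compounds (a DDI positive without activation,
    a DDI positive with activation, and a non-DDI negative), each tested at
    three increasing concentrations in triplicate.
    """
    c = CompoundSpec
    compounds = (
        c("A", "etoposide", DDI, False, (_nM(22.22), _nM(66.67), _nM(200))),
        c("B", "ethyl methanesulfonate", DDI, False, (0.22, 0.67, 2.0)),
        c("D", "chlorambucil", DDI, False, (_uM(0.44), _uM(1.33), _uM(4))),
        c("E", "N-nitroso-N-ethylurea", DDI, False, (0.056, 0.167, 0.5)),
        c("F", "D-mannitol", NON_DDI, False, (0.11, 0.33, 1.0)),
        c("G", "ampicillin", NON_DDI, False, (0.11, 0.33, 1.0)),
        c("I", "sunitinib malate", NON_DDI, False, (_uM(2.22), _uM(6.67), _uM(20))),
        c("J", "2,4-dinitrophenol", NON_DDI, False, (0.11, 0.33, 1.0)),
        c("K", "dexamethasone", NON_DDI, False, (0.11, 0.33, 1.0)),
        c("N", "staurosporine", NON_DDI, False, (_nM(3.33), _nM(10), _nM(30))),
        c("O", "cycloheximide", NON_DDI, False, (_uM(1.11), _uM(3.33), _uM(10))),
        c("P", "phenobarbital sodium", NON_DDI, True, (0.11, 0.33, 1.0)),
        c("Q", "cyclophosphamide", DDI, True, (_uM(2.22), _uM(6.67), _uM(20))),
        c("R", "2-aminoanthracene", DDI, True, (_uM(1.14), _uM(3.47), _uM(10.3))),
    )
    controls = (
        c("CA", "bleomycin", DDI, False, (_uM(3.5),), role="positive_control"),
        c("CB", "caffeine", NON_DDI, False, (2.0,), role="negative_control"),
        c("CC", "benzo[a]pyrene", DDI, True, (_uM(39.6),), role="positive_control"),
    )
    labs = tuple(f"Lab{i}" for i in range(1, n_labs + 1))
    return SimDesign(
        labs=labs,
        compounds=compounds,
        controls=controls,
        n_replicates=n_replicates,
        include_controls=include_controls,
        seed=seed,
    )


def default_viability_curves(
    design: SimDesign,
    target_top_viability: float = 45.0,
    limit_compound_viability: float = 75.0,
    hill: float = 2.0,
    floor: float = 5.0,
) -> dict[str, ViabilityCurve]:
    """Hill curves placing the top concentration at the target viability.

    Compounds whose top concentration reaches the 1 mM limit are given a
    gentler curve (``limit_compound_viability`` at the top) since their test
    validity rests on the limit concentration, not on cytotoxicity.
    """

    def _ec50(top: float, v_top: float) -> float:
        ratio = (100.0 - floor) / (v_top - floor) - 1.0
        return top / ratio ** (1.0 / hill)

    curves = {}
    for comp in design.all_compounds:
        top = comp.top_concentration_mM
        target = limit_compound_viability if top >= 1.0 else target_top_viability
        curves[comp.code] = ViabilityCurve(ec50=_ec50(top, target), hill=hill, floor=floor)
    return curves


# ---------------------------------------------------------------------------
# Training profiles
# ---------------------------------------------------------------------------

def simulate_training_set(
    panel: PanelSpec,
    effect: EffectModel,
    n_ddi: int = 14,
    n_nonddi: int = 14,
    seed: int = 0,
) -> LabeledProfileSet:
    """Reference-agent training profiles (one 64-gene log2-ratio per agent).

    DDI agents draw their responsive genes from N(ddi_effect_mean,
    ddi_effect_sd) and the rest from N(0, nonddi_effect_sd); non-DDI agents
    draw every gene from the null spread.  The default 14 + 14 = 28 agents
    echoes the size of the compendium the biomarker was derived from.
    """
    if n_ddi < 2 or n_nonddi < 2:
        raise ValueError("need >= 2 agents per class")
    rng = np.random.default_rng(seed)
    genes = list(panel.biomarker_genes)
    responsive = set(effect.responsive_genes(panel))
    resp_mask = np.array([g in responsive for g in genes])

    cols, labels = {}, {}
    for i in range(n_ddi):
        profile = rng.normal(0.0, effect.nonddi_effect_sd, size=len(genes))
        profile[resp_mask] = rng.normal(
            effect.ddi_effect_mean, effect.ddi_effect_sd, size=int(resp_mask.sum())
        )
        name = f"DDI_agent_{i + 1:02d}"
        cols[name] = profile
        labels[name] = DDI
    for i in range(n_nonddi):
        name = f"nonDDI_agent_{i + 1:02d}"
        cols[name] = rng.normal(0.0, effect.nonddi_effect_sd, size=len(genes))
        labels[name] = NON_DDI
    profiles = pd.DataFrame(cols, index=genes)
    return LabeledProfileSet(profiles=profiles, labels=pd.Series(labels))


# ---------------------------------------------------------------------------
# Ring-trial experiment
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws via gamma-Poisson mixing; Poisson when
    dispersion is zero."""
    mu = np.clip(mu, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_experiment(
    design: SimDesign,
    panel: PanelSpec,
    effect: EffectModel,
    curves: Mapping[str, ViabilityCurve],
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the full ring-trial dataset.

    Returns the count matrix, the sample sheet (including per-sample RIN and
    instrument QC metrics), and the viability table.  Each laboratory
    contributes test samples for every compound and concentration,
    ``n_solvent_controls`` solvent-control replicates, control compounds
    when enabled, and one shared reference-RNA sample; all counts for a lab
    carry that lab's library-size effect.

    Raises
    ------
    ValueError
        If a compound in the design has no viability curve.
    """
    for comp in design.all_compounds:
        if comp.code not in curves:
            raise ValueError(f"no viability curve for compound {comp.code!r}")

    rng = np.random.default_rng(design.seed)
    genes = list(panel.all_genes)
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    # Gene baselines: lognormal around ~600 counts for endogenous and
    # housekeeping probes; spike probes scale with nominal input; negative
    # probes sit at background.
    base = np.empty(n_genes)
    n_endo = len(panel.biomarker_genes) + len(panel.housekeeping_genes)
    base[:n_endo] = np.exp(rng.normal(math.log(600.0), 0.5, size=n_endo))
    for name, nominal in panel.pos_control_probes:
        base[gene_index[name]] = 25.0 * nominal
    for name in panel.neg_control_probes:
        base[gene_index[name]] = 2.0
    # Reference RNA has its own fixed expression vector, shared by all labs.
    ref_base = base.copy()
    ref_base[:n_endo] = np.exp(rng.normal(math.log(600.0), 0.5, size=n_endo))

    lab_effects = {lab: rng.normal(0.0, effect.lab_effect_sd) for lab in design.labs}

    # Per-compound gene signature (log2 scale at the top concentration),
    # shared across labs — it is a property of the compound.
    responsive = set(effect.responsive_genes(panel))
    resp_mask = np.array([g in responsive for g in genes])
    bio_mask = np.array([g in set(panel.biomarker_genes) for g in genes])
    signatures: dict[str, np.ndarray] = {}
    for comp in design.all_compounds:
        sig = np.zeros(n_genes)
        sig[bio_mask] = rng.normal(0.0, effect.nonddi_effect_sd, size=int(bio_mask.sum()))
        if comp.truth == DDI:
            sig[resp_mask] = rng.normal(
                effect.ddi_effect_mean, effect.ddi_effect_sd, size=int(resp_mask.sum())
            )
        signatures[comp.code] = sig

    columns: dict[str, np.ndarray] = {}
    sheet_rows: list[dict] = []

    def _add_sample(sid: str, mu: np.ndarray, lab: str, meta: dict) -> None:
        columns[sid] = _nb_counts(rng, mu, effect.dispersion)
        row = {
            "sample_id": sid,
            "lab": lab,
            "batch": f"{lab}-B1",
            "rin": round(float(rng.uniform(8.2, 9.9)), 1),
            "imaging_fov_pct": round(float(rng.uniform(92.0, 99.5)), 1),
            "binding_density": round(float(rng.uniform(0.5, 1.6)), 2),
        }
        row.update(meta)
        sheet_rows.append(row)

    level_names = {1: "low", 2: "medium", 3: "high"}
    for lab in design.labs:
        lab_scale = math.exp(lab_effects[lab])
        # Solvent controls.
        for r in range(1, design.n_solvent_controls + 1):
            _add_sample(
                f"{lab}_SC_r{r}",
                base * lab_scale,
                lab,
                {
                    "compound": "SC",
                    "concentration_level": "control",
                    "concentration_mM": 0.0,
                    "concentration_rank": 0,
                    "replicate": r,
                    "role": "solvent_control",
                },
            )
        # Reference RNA (one per lab).
        _add_sample(
            f"{lab}_REF",
            ref_base * lab_scale,
            lab,
            {
                "compound": "REF",
                "concentration_level": "control",
                "concentration_mM": 0.0,
                "concentration_rank": 0,
                "replicate": 1,
                "role": "reference_rna",
            },
        )
        # Test and control compounds.
        for comp in design.all_compounds:
            n_conc = len(comp.concentrations_mM)
            for rank, conc in enumerate(comp.concentrations_mM, start=1):
                # Concentration scaling by rank within the compound's series.
                scale = rank / n_conc
                mu = base * lab_scale * np.exp2(signatures[comp.code] * scale)
                level = level_names.get(rank, "high") if comp.role == "test" else "control"
                for r in range(1, design.n_replicates + 1):
                    _add_sample(
                        f"{lab}_{comp.code}_c{rank}_r{r}",
                        mu,
                        lab,
                        {
                            "compound": comp.code,
                            "concentration_level": level,
                            "concentration_mM": conc,
                            "concentration_rank": rank,
                            "replicate": r,
                            "role": comp.role,
                        },
                    )

    counts = CountMatrix(pd.DataFrame(columns, index=genes))
    sheet = pd.DataFrame(sheet_rows)

    via_rows = []
    for lab in design.labs:
        for comp in design.all_compounds:
            for rank, conc in enumerate(comp.concentrations_mM, start=1):
                via_rows.append(
                    {
                        "lab": lab,
                        "compound": comp.code,
                        "concentration_rank": rank,
                        "concentration_mM": conc,
                        "viability_pct": viability_at(curves[comp.code], conc),
                    }
                )
    viability = pd.DataFrame(via_rows)
    return counts, sheet, viability


def with_seed(design: SimDesign, seed: int) -> SimDesign:
    """A copy of the design with a different seed."""
    return replace(design, seed=seed)
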