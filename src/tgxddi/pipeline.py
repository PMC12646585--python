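"""End-to-end pipeline: simulate -> QC/normalize -> classify -> call -> score.

:func:`run_pipeline` runs the whole ring-trial analysis from a single
:class:`RunConfig` (one seed governs every stochastic stage; per-stage seeds
are derived deterministically from it) and returns a :class:`RunReport`
holding every intermediate table plus sample accounting.  All tabular
artifacts can be written out as tidy CSV.

:func:`replay_published_tables` recomputes the published pooled performance
summaries from the embedded 2x2 counts of both ring-trial phases, and the
perfect-agreement coefficient triple; it exists so the printed summary
statistics can be reproduced without any dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calls as agg
from .calls import ChemicalCall, ValidityPolicy
from .classify import DDI, ThreeProngedClassifier
from .concordance import (
    AgreementTable,
    concordance_stats,
    pairwise_concordance,
    reference_rna_correlations,
)
from .errors import NoCallError
from .io import QcPolicy, log2_ratios, normalize, qc_evaluate
from .panel import make_panel
from .performance import (
    ConfusionTable,
    PerformanceSummary,
    confusion_table,
    summarize_performance,
    within_lab_concordance,
)
from .simulate import (
    EffectModel,
    default_viability_curves,
    ring_trial_design,
    simulate_experiment,
    simulate_training_set,
)

#: Pooled 2x2 tables of the two ring-trial phases (rows: assay call,
#: columns: truth standard), as published.
RESULT1_POOLED = ConfusionTable(tp=17, fn=0, fp=4, tn=21)
RESULT2_POOLED = ConfusionTable(tp=19, fn=0, fp=4, tn=24)

#: Published within-laboratory concordance: 11 of 12 tests concordant.
WITHIN_LAB_CONCORDANT = (11, 12)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Round-trips losslessly through YAML (:meth:`to_yaml` /
    :meth:`from_yaml`).
    """

    seed: int = 0
    n_labs: int = 4
    n_replicates: int = 3
    n_housekeeping: int = 10
    n_ddi_train: int = 14
    n_nonddi_train: int = 14
    include_controls: bool = True
    effect: EffectModel = field(default_factory=EffectModel)
    #: Effect model for the blinded exposure experiment; defaults to the
    #: training effect.  Setting it separately models a shift between the
    #: training chemicals and the ring-trial exposures (e.g. a null
    #: exposure against a normally trained classifier).
    exposure_effect: EffectModel | None = None
    qc_policy: QcPolicy = field(default_factory=QcPolicy)
    validity_policy: ValidityPolicy = field(default_factory=ValidityPolicy)
    shrinkage: float = 0.0
    band_fraction: float = 0.1
    hca_metric: str = "euclidean"
    hca_linkage: str = "average"
    purity_threshold: float = 0.5
    pa_threshold: float = 0.9
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # Tuples do not survive YAML round-trips; normalize to lists.
        d["qc_policy"]["binding_density_range"] = list(
            d["qc_policy"]["binding_density_range"]
        )
        d["qc_policy"]["content_factor_range"] = list(
            d["qc_policy"]["content_factor_range"]
        )
        d["validity_policy"]["negative_call_viability_range"] = list(
            d["validity_policy"]["negative_call_viability_range"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "effect" in d and isinstance(d["effect"], dict):
            d["effect"] = EffectModel(**d["effect"])
        if isinstance(d.get("exposure_effect"), dict):
            d["exposure_effect"] = EffectModel(**d["exposure_effect"])
        if "qc_policy" in d and isinstance(d["qc_policy"], dict):
            q = dict(d["qc_policy"])
            for key in ("binding_density_range", "content_factor_range"):
                if key in q:
                    q[key] = tuple(q[key])
            d["qc_policy"] = QcPolicy(**q)
        if "validity_policy" in d and isinstance(d["validity_policy"], dict):
            v = dict(d["validity_policy"])
            if "negative_call_viability_range" in v:
                v["negative_call_viability_range"] = tuple(
                    v["negative_call_viability_range"]
                )
            d["validity_policy"] = ValidityPolicy(**v)
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class RunReport:
    """All pipeline outputs plus per-stage sample accounting."""

    config: RunConfig
    sample_sheet: pd.DataFrame
    qc_metrics: pd.DataFrame
    qc_excluded: tuple[str, ...]
    viability: pd.DataFrame
    sample_calls: pd.DataFrame
    concentration_calls: pd.DataFrame
    chemical_calls: list[ChemicalCall]
    performance: PerformanceSummary
    pooled_table: ConfusionTable
    within_lab: pd.DataFrame
    cross_site: pd.DataFrame
    reference_pearson: pd.DataFrame
    reference_spearman: pd.DataFrame
    accounting: dict[str, int]

    @property
    def chemical_calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lab": c.lab,
                    "compound": c.compound,
                    "call": c.call,
                    "valid_test": c.valid_test,
                    "validity_reason": c.validity_reason,
                }
                for c in self.chemical_calls
            ]
        )

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(self.config.to_yaml(), encoding="utf-8")
        self.sample_sheet.to_csv(out / "sample_sheet.csv", index=False)
        self.qc_metrics.to_csv(out / "qc_metrics.csv")
        self.viability.to_csv(out / "viability.csv", index=False)
        self.sample_calls.to_csv(out / "sample_calls.csv", index=False)
        self.concentration_calls.to_csv(out / "concentration_calls.csv", index=False)
        self.chemical_calls_frame.to_csv(out / "chemical_calls.csv", index=False)
        self.within_lab.to_csv(out / "within_lab_concordance.csv", index=False)
        self.cross_site.to_csv(out / "cross_site_concordance.csv", index=False)
        self.reference_pearson.to_csv(out / "reference_rna_pearson.csv")
        self.reference_spearman.to_csv(out / "reference_rna_spearman.csv")


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the whole synthetic ring-trial analysis for one configuration."""
    seed_panel, seed_train, seed_exp = _derive_seeds(config.seed, 3)

    panel = make_panel(n_housekeeping=config.n_housekeeping, seed=seed_panel)
    training = simulate_training_set(
        panel,
        config.effect,
        n_ddi=config.n_ddi_train,
        n_nonddi=config.n_nonddi_train,
        seed=seed_train,
    )
    design = ring_trial_design(
        n_labs=config.n_labs,
        n_replicates=config.n_replicates,
        include_controls=config.include_controls,
        seed=seed_exp,
    )
    curves = default_viability_curves(design)
    exposure = config.exposure_effect or config.effect
    counts, sheet, viability = simulate_experiment(design, panel, exposure, curves)

    qc = qc_evaluate(counts, sheet, panel, config.qc_policy)
    norm = normalize(counts, sheet, qc, panel)
    ratios = log2_ratios(norm, sheet)

    clf = ThreeProngedClassifier(
        shrinkage=config.shrinkage,
        band_fraction=config.band_fraction,
        metric=config.hca_metric,
        linkage=config.hca_linkage,
        purity_threshold=config.purity_threshold,
        pa_threshold=config.pa_threshold,
    ).fit(training)

    # Classify each treated sample on the biomarker genes.
    profiles = ratios.loc[list(panel.biomarker_genes)].T  # samples x genes
    sample_call_objs = clf.classify(profiles, sample_ids=list(profiles.index))
    meta = sheet.set_index("sample_id")
    sample_calls = pd.DataFrame(
        [
            {
                "sample_id": sc.sample_id,
                "lab": meta.loc[sc.sample_id, "lab"],
                "compound": meta.loc[sc.sample_id, "compound"],
                "role": meta.loc[sc.sample_id, "role"],
                "concentration_rank": int(meta.loc[sc.sample_id, "concentration_rank"]),
                "replicate": int(meta.loc[sc.sample_id, "replicate"]),
                "pa_call": sc.pa.call,
                "pa_posterior_ddi": sc.pa.score,
                "pca_call": sc.pca.call,
                "pc1_score": sc.pca.score,
                "hca_call": sc.hca.call,
                "hca_purity": sc.hca.score,
                "call": sc.call,
            }
            for sc in sample_call_objs
        ]
    )

    # Viability screening and the call hierarchy.
    screened = agg.screen_concentrations(viability, config.validity_policy)
    truth = design.truth
    conc_rows = []
    chem_calls: list[ChemicalCall] = []
    for (lab, compound), group in sample_calls.groupby(["lab", "compound"]):
        via = screened[(screened["lab"] == lab) & (screened["compound"] == compound)]
        if via.empty:
            continue
        validity = agg.test_validity(via, config.validity_policy)
        conc_calls = []
        for rank, conc_group in group.groupby("concentration_rank"):
            row = via[via["concentration_rank"] == rank]
            excluded = bool(row["excluded"].iloc[0]) if len(row) else False
            if excluded or len(conc_group) < 2:
                # Overt cytotoxicity, or too few replicates survived QC to
                # support a concentration-level call.
                cc = agg.ConcentrationCall(
                    compound=compound,
                    lab=lab,
                    concentration_rank=int(rank),
                    call=None,
                    n_samples=len(conc_group),
                    excluded=True,
                    reason=agg.OVERT_CYTOTOXICITY if excluded else agg.QC,
                )
            else:
                cc = agg.concentration_call(
                    list(conc_group["call"]),
                    compound=compound,
                    lab=lab,
                    concentration_rank=int(rank),
                )
            conc_calls.append(cc)
            conc_rows.append(dataclasses.asdict(cc))
        try:
            chem_calls.append(
                agg.chemical_call(conc_calls, validity, compound=compound, lab=lab)
            )
        except NoCallError:
            pass  # every concentration overtly cytotoxic: no chemical call

    concentration_calls = pd.DataFrame(conc_rows)

    # Performance vs truth (blinded test compounds only, inconclusives
    # excluded from the 2x2; invalid tests cannot contribute negatives by
    # construction of chemical_call).
    test_codes = {c.code for c in design.compounds}
    scored = [c for c in chem_calls if c.compound in test_codes]
    pooled = confusion_table(scored, truth)
    performance = summarize_performance(pooled)

    # Within-lab concordance: valid tests only, controls excluded.
    valid_tests = {
        (c.lab, c.compound) for c in chem_calls if c.valid_test and c.compound in test_codes
    }
    wl_input = sample_calls[
        sample_calls.apply(
            lambda r: (r["lab"], r["compound"]) in valid_tests, axis=1
        )
    ]
    within_lab = within_lab_concordance(
        wl_input[["lab", "compound", "concentration_rank", "call"]]
    )

    # Cross-site concordance over conclusive, valid chemical calls.
    calls_by_lab: dict[str, dict[str, str]] = {}
    for c in scored:
        if c.call == DDI or (c.call == "nonDDI" and c.valid_test):
            calls_by_lab.setdefault(c.lab, {})[c.compound] = c.call
    cross = pairwise_concordance(calls_by_lab) if len(calls_by_lab) >= 2 else pd.DataFrame()

    # Reference RNA correlations.
    ref_ids = sheet.loc[sheet["role"] == "reference_rna", ["sample_id", "lab"]]
    ref_counts = counts.counts[list(ref_ids["sample_id"])]
    ref_counts.columns = list(ref_ids["lab"])
    pearson, spearman = reference_rna_correlations(ref_counts)

    accounting = {
        "n_samples": int(counts.counts.shape[1]),
        "n_qc_excluded": len(qc.excluded),
        "n_samples_retained": int(counts.counts.shape[1]) - len(qc.excluded),
        "n_classified": len(sample_calls),
        "n_concentrations_excluded": int(screened["excluded"].sum()),
        "n_chemical_calls": len(chem_calls),
        "n_invalid_tests": sum(not c.valid_test for c in chem_calls),
    }

    report = RunReport(
        config=config,
        sample_sheet=sheet,
        qc_metrics=qc.metrics,
        qc_excluded=qc.excluded,
        viability=screened,
        sample_calls=sample_calls,
        concentration_calls=concentration_calls,
        chemical_calls=chem_calls,
        performance=performance,
        pooled_table=pooled,
        within_lab=within_lab,
        cross_site=cross,
        reference_pearson=pearson,
        reference_spearman=spearman,
        accounting=accounting,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


def replay_published_tables() -> dict:
    """Recompute the published pooled summaries and the perfect-agreement
    coefficients from embedded counts."""
    perfect = concordance_stats(AgreementTable(n11=10, n10=0, n01=0, n00=4))
    return {
        "result1": summarize_performance(RESULT1_POOLED),
        "result2": summarize_performance(RESULT2_POOLED),
        "within_lab_concordance": WITHIN_LAB_CONCORDANT[0] / WITHIN_LAB_CONCORDANT[1],
        "perfect_agreement": perfect,
    }
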