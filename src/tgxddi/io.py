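"""Count-data IO, QA/QC flagging, normalization, and log2 ratios.

This module handles the computational side of the NanoString workflow: it
reads and writes count matrices (tidy CSV or single-sample RCC files),
evaluates per-sample QC metrics against a configurable policy, normalizes
counts with the standard two-step positive-control / housekeeping-content
scaling, and expresses treated samples as log2 ratios against the mean of
their concurrent solvent controls — the representation the TGx-DDI
classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSampleError,
    FormatError,
    PairingError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .panel import PanelSpec

ROLES = ("test", "solvent_control", "positive_control", "negative_control", "reference_rna")

#: Mandatory sample-sheet columns.  Optional columns (concentration,
#: concentration_mM, concentration_rank, rin, imaging_fov_pct,
#: binding_density) are consumed when present.
SHEET_REQUIRED_COLUMNS = (
    "sample_id",
    "lab",
    "batch",
    "compound",
    "concentration_level",
    "replicate",
    "role",
)

QC_FLAGS = (
    "IMAGING",
    "BINDING_DENSITY",
    "POS_CONTROL_LINEARITY",
    "CONTENT_NORMALIZATION",
    "LOW_RIN",
)


@dataclass
class CountMatrix:
    """Probe-level counts: genes as rows, samples as columns.

    Counts are validated to be nonnegative integers with unique gene and
    sample identifiers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier {dup!r}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(arr != np.round(arr))[0]
            raise FormatError(
                f"non-integer count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        self.counts = c.astype(np.int64)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


def validate_sample_sheet(sheet: pd.DataFrame, counts: CountMatrix | None = None) -> None:
    """Check sheet structure and the solvent-control pairing invariant."""
    missing = [c for c in SHEET_REQUIRED_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r} in sample sheet")
    bad_roles = set(sheet["role"]) - set(ROLES)
    if bad_roles:
        raise FormatError(f"unknown sample roles: {sorted(bad_roles)}")
    if counts is not None:
        sheet_ids = set(sheet["sample_id"])
        matrix_ids = set(counts.samples)
        if sheet_ids != matrix_ids:
            raise FormatError(
                "sample sheet and count matrix disagree: "
                f"only-in-sheet={sorted(sheet_ids - matrix_ids)[:3]}, "
                f"only-in-matrix={sorted(matrix_ids - sheet_ids)[:3]}"
            )
    controls = sheet[sheet["role"] == "solvent_control"]
    control_groups = set(map(tuple, controls[["lab", "batch"]].itertuples(index=False)))
    treated = sheet[sheet["role"] == "test"]
    for lab, batch in set(map(tuple, treated[["lab", "batch"]].itertuples(index=False))):
        if (lab, batch) not in control_groups:
            raise FormatError(
                f"no solvent control for test samples in lab {lab!r}, batch {batch!r}"
            )


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def write_counts_csv(
    counts: CountMatrix, sheet: pd.DataFrame, counts_path: str | Path, sheet_path: str | Path
) -> None:
    """Write the count matrix (genes x samples, gene IDs in column ``gene``)
    and the sample sheet as UTF-8 comma-separated files."""
    out = counts.counts.copy()
    out.index.name = "gene"
    out.to_csv(counts_path)
    sheet.to_csv(sheet_path, index=False)


def read_counts_csv(
    counts_path: str | Path, sheet_path: str | Path
) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a count matrix and sample sheet written by :func:`write_counts_csv`.

    Raises
    ------
    FormatError
        On duplicate identifiers, negative or non-integer counts, missing
        columns, or a test sample without a concurrent solvent control.
    """
    with open(counts_path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    sample_header = header[1:]
    if len(set(sample_header)) != len(sample_header):
        dupes = sorted({s for s in sample_header if sample_header.count(s) > 1})
        raise FormatError(f"{counts_path}: duplicate sample column(s) {dupes}")
    df = pd.read_csv(counts_path, index_col=0)
    df.index.name = None  # the 'gene' label is a file artifact, not data
    try:
        cm = CountMatrix(df)
    except FormatError as exc:
        raise FormatError(f"{counts_path}: {exc}") from exc
    sheet = pd.read_csv(sheet_path)
    validate_sample_sheet(sheet, cm)
    return cm, sheet


def write_viability_csv(viability: pd.DataFrame, path: str | Path) -> None:
    viability.to_csv(path, index=False)


def read_viability_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"lab", "compound", "concentration_rank", "viability_pct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: viability table missing columns {sorted(missing)}")
    bad = df[(df["viability_pct"] < 0) | (df["viability_pct"] > 100)]
    if len(bad):
        row = bad.iloc[0]
        raise FormatError(
            f"{path}: viability_pct out of [0, 100] for lab {row['lab']!r}, "
            f"compound {row['compound']!r}"
        )
    return df


# ---------------------------------------------------------------------------
# RCC single-sample files
# ---------------------------------------------------------------------------

@dataclass
class RccSample:
    """One sample parsed from an RCC file.

    ``counts`` is indexed by probe name; ``code_class`` maps probe name to
    panel category; all non-``Code_Summary`` sections are preserved verbatim
    in ``attributes``.
    """

    sample_id: str
    counts: pd.Series
    code_class: pd.Series
    attributes: dict[str, str] = field(default_factory=dict)


_CODECLASS_TO_CATEGORY = {
    "Endogenous": "biomarker",
    "Housekeeping": "housekeeping",
    "Positive": "positive_control",
    "Negative": "negative_control",
}


def write_rcc(
    path: str | Path,
    sample_id: str,
    counts: Mapping[str, int] | pd.Series,
    panel: "PanelSpec",
    lane_attributes: Mapping[str, object] | None = None,
) -> None:
    """Emit a single-sample RCC file (bracketed sections, Code_Summary CSV)."""
    counts = pd.Series(counts)
    lines = [
        "<Header>",
        "FileVersion,1.7",
        "SoftwareVersion,4.0",
        "</Header>",
        "",
        "<Sample_Attributes>",
        f"ID,{sample_id}",
        "</Sample_Attributes>",
        "",
        "<Lane_Attributes>",
    ]
    for key, value in (lane_attributes or {}).items():
        lines.append(f"{key},{value}")
    lines += ["</Lane_Attributes>", "", "<Code_Summary>", "CodeClass,Name,Accession,Count"]
    for gene in counts.index:
        cls = panel.code_class(gene)
        lines.append(f"{cls},{gene},NM_{gene},{int(counts[gene])}")
    lines += ["</Code_Summary>", ""]
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_rcc(path: str | Path) -> RccSample:
    """Parse an RCC file; only the ``Code_Summary`` section is interpreted."""
    text = Path(path).read_text(encoding="utf-8")
    sections: dict[str, str] = {}
    name = None
    buf: list[str] = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("<") and stripped.endswith(">"):
            if stripped.startswith("</"):
                if name is not None:
                    sections[name] = "\n".join(buf)
                name, buf = None, []
            else:
                name = stripped[1:-1]
                buf = []
        elif name is not None:
            buf.append(line)
    if "Code_Summary" not in sections:
        raise FormatError(f"{path}: missing Code_Summary section")
    rows = [r for r in sections["Code_Summary"].splitlines() if r.strip()]
    header = rows[0].split(",")
    if header[:4] != ["CodeClass", "Name", "Accession", "Count"]:
        raise FormatError(f"{path}: unexpected Code_Summary header {header}")
    names, classes, counts = [], [], []
    for row in rows[1:]:
        cls, gene, _accession, count = row.split(",")[:4]
        try:
            value = int(count)
        except ValueError:
            raise FormatError(
                f"{path}: non-integer count {count!r} for probe {gene!r}"
            ) from None
        if value < 0:
            raise FormatError(f"{path}: negative count for probe {gene!r}")
        names.append(gene)
        classes.append(_CODECLASS_TO_CATEGORY.get(cls, cls))
        counts.append(value)
    sample_id = Path(path).stem
    for line in sections.get("Sample_Attributes", "").splitlines():
        if line.startswith("ID,"):
            sample_id = line.split(",", 1)[1]
    attrs = {k: v for k, v in sections.items() if k != "Code_Summary"}
    return RccSample(
        sample_id=sample_id,
        counts=pd.Series(counts, index=names, name=sample_id),
        code_class=pd.Series(classes, index=names),
        attributes=attrs,
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QcPolicy:
    """Per-sample QC thresholds (platform-conventional defaults, configurable)."""

    min_imaging_fov_pct: float = 75.0
    binding_density_range: tuple[float, float] = (0.1, 2.25)
    min_poscontrol_r2: float = 0.95
    content_factor_range: tuple[float, float] = (0.1, 10.0)
    min_rin: float = 7.0  # samples must exceed this RIN
    exclude_flagged: bool = True  # hard exclusion; False records flags only


@dataclass
class QcReport:
    """Per-sample QC metrics and flags.

    ``metrics`` is indexed by sample id with columns imaging_fov_pct,
    binding_density, poscontrol_r2, content_factor and ``flags`` (a
    semicolon-joined string, empty when clean).  ``excluded`` lists the
    samples removed under the policy in force.
    """

    metrics: pd.DataFrame
    excluded: tuple[str, ...]

    def flags_for(self, sample_id: str) -> frozenset[str]:
        raw = self.metrics.loc[sample_id, "flags"]
        return frozenset(raw.split(";")) if raw else frozenset()


def _geometric_mean(values: np.ndarray, pseudocount: float) -> float:
    return float(np.exp(np.mean(np.log(values + pseudocount))))


def qc_evaluate(
    counts: CountMatrix,
    sheet: pd.DataFrame,
    panel: "PanelSpec",
    policy: QcPolicy | None = None,
    pseudocount: float = 0.5,
) -> QcReport:
    """Compute QC metrics and flags for every sample.

    Instrument metrics (imaging FOV, binding density) and RIN are read from
    the sample sheet when present; a missing metric yields its flag rather
    than an error, mirroring a conservative review policy.  Positive-control
    linearity is the R^2 of log2 spike counts against log2 nominal input;
    the content factor compares each sample's housekeeping geometric mean
    with its (lab, batch) cohort.
    """
    policy = policy or QcPolicy()
    validate_sample_sheet(sheet, counts)
    sheet = sheet.set_index("sample_id", drop=False)
    pos_names = [g for g in panel.pos_control_names if g in counts.genes]
    pos_nominal = np.array(
        [dict(panel.pos_control_probes)[g] for g in pos_names], dtype=float
    )
    hk = [g for g in panel.housekeeping_genes if g in counts.genes]

    records: dict[str, dict] = {}
    hk_gm: dict[str, float] = {}
    for sid in counts.samples:
        col = counts.counts[sid]
        rec: dict[str, object] = {}
        flags: set[str] = set()

        fov = sheet.loc[sid].get("imaging_fov_pct", np.nan) if sid in sheet.index else np.nan
        rec["imaging_fov_pct"] = fov
        if not (fov >= policy.min_imaging_fov_pct):  # NaN fails comparison -> flag
            flags.add("IMAGING")

        bd = sheet.loc[sid].get("binding_density", np.nan) if sid in sheet.index else np.nan
        rec["binding_density"] = bd
        lo, hi = policy.binding_density_range
        if not (lo <= bd <= hi):
            flags.add("BINDING_DENSITY")

        if len(pos_names) >= 3:
            y = np.log2(col[pos_names].to_numpy(dtype=float) + pseudocount)
            x = np.log2(pos_nominal)
            r = np.corrcoef(x, y)[0, 1]
            r2 = float(r * r) if np.isfinite(r) else 0.0
        else:
            r2 = np.nan
        rec["poscontrol_r2"] = r2
        if not (r2 >= policy.min_poscontrol_r2):
            flags.add("POS_CONTROL_LINEARITY")

        rin = sheet.loc[sid].get("rin", np.nan) if sid in sheet.index else np.nan
        if not (rin > policy.min_rin):
            flags.add("LOW_RIN")

        hk_gm[sid] = _geometric_mean(col[hk].to_numpy(dtype=float), pseudocount) if hk else np.nan
        records[sid] = rec
        records[sid]["_flags"] = flags

    # Content factor: cohort = all samples of the same (lab, batch).
    cohorts = sheet.groupby(["lab", "batch"])["sample_id"].apply(list)
    for members in cohorts:
        gms = np.array([hk_gm[s] for s in members])
        cohort_gm = float(np.exp(np.nanmean(np.log(gms)))) if np.isfinite(gms).any() else np.nan
        for sid in members:
            factor = cohort_gm / hk_gm[sid] if hk_gm[sid] and np.isfinite(hk_gm[sid]) else np.nan
            records[sid]["content_factor"] = factor
            lo, hi = policy.content_factor_range
            if not (lo <= factor <= hi):
                records[sid]["_flags"].add("CONTENT_NORMALIZATION")

    rows = []
    for sid in counts.samples:
        rec = records[sid]
        flags = rec.pop("_flags")
        rec["flags"] = ";".join(sorted(flags))
        rec["sample_id"] = sid
        rows.append(rec)
    metrics = pd.DataFrame(rows).set_index("sample_id")
    excluded = (
        tuple(metrics.index[metrics["flags"] != ""]) if policy.exclude_flagged else ()
    )
    return QcReport(metrics=metrics, excluded=excluded)


# ---------------------------------------------------------------------------
# Normalization and log2 ratios
# ---------------------------------------------------------------------------

def normalize(
    counts: CountMatrix,
    sheet: pd.DataFrame,
    qc: QcReport | None,
    panel: "PanelSpec",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-step scaling of counts within each (lab, batch) cohort.

    Step 1 scales each sample by its positive-control factor (cohort
    geometric mean of spike-probe geometric means over the sample's own);
    step 2 applies the housekeeping content factor the same way.  QC-excluded
    samples are dropped first.  The result is strictly positive because the
    pseudocount is added before scaling.

    Raises
    ------
    DegenerateSampleError
        If a sample's housekeeping counts are all zero.
    """
    validate_sample_sheet(sheet, counts)
    excluded = set(qc.excluded) if qc is not None else set()
    keep = [s for s in counts.samples if s not in excluded]
    mat = counts.counts[keep].astype(float) + pseudocount
    sheet = sheet.set_index("sample_id")

    pos = [g for g in panel.pos_control_names if g in counts.genes]
    hk = [g for g in panel.housekeeping_genes if g in counts.genes]

    cohorts: dict[tuple, list[str]] = {}
    for sid in keep:
        key = (sheet.loc[sid, "lab"], sheet.loc[sid, "batch"])
        cohorts.setdefault(key, []).append(sid)

    out = mat.copy()
    for members in cohorts.values():
        if pos:
            gms = np.array(
                [np.exp(np.mean(np.log(mat.loc[pos, s]))) for s in members]
            )
            cohort_gm = float(np.exp(np.mean(np.log(gms))))
            factors = cohort_gm / gms
            out[members] = out[members] * factors
        if hk:
            for s in members:
                if (counts.counts.loc[hk, s] == 0).all():
                    raise DegenerateSampleError(
                        f"sample {s!r}: all housekeeping counts are zero"
                    )
            gms = np.array(
                [np.exp(np.mean(np.log(out.loc[hk, s]))) for s in members]
            )
            cohort_gm = float(np.exp(np.mean(np.log(gms))))
            factors = cohort_gm / gms
            out[members] = out[members] * factors
    return out


def log2_ratios(
    normalized: pd.DataFrame,
    sheet: pd.DataFrame,
    treated_roles: Iterable[str] = ("test", "positive_control", "negative_control"),
) -> pd.DataFrame:
    """log2 of each treated sample over the mean of its concurrent solvent controls.

    Concurrent means same lab and batch.  Columns are treated samples only.

    Raises
    ------
    PairingError
        If a treated sample has no concurrent solvent control in ``normalized``.
    """
    sheet = sheet.set_index("sample_id")
    sheet = sheet.loc[[s for s in normalized.columns if s in sheet.index]]
    roles = set(treated_roles)
    control_cols: dict[tuple, list[str]] = {}
    for sid in normalized.columns:
        if sheet.loc[sid, "role"] == "solvent_control":
            key = (sheet.loc[sid, "lab"], sheet.loc[sid, "batch"])
            control_cols.setdefault(key, []).append(sid)

    out = {}
    for sid in normalized.columns:
        if sheet.loc[sid, "role"] not in roles:
            continue
        key = (sheet.loc[sid, "lab"], sheet.loc[sid, "batch"])
        controls = control_cols.get(key)
        if not controls:
            raise PairingError(
                f"sample {sid!r}: no concurrent solvent control in lab "
                f"{key[0]!r}, batch {key[1]!r}"
            )
        baseline = normalized[controls].mean(axis=1)
        out[sid] = np.log2(normalized[sid] / baseline)
    result = pd.DataFrame(out, index=normalized.index)
    if not np.isfinite(result.to_numpy()).all():
        raise FormatError("log2 ratio matrix contains non-finite values")
    return result
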