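"""CSV schemas, result writing and the run manifest.

Two delimited-text schemas are exchanged with the outside world:

* region-read CSV - one row per patient x reader x region with the four
  fibrosis extent columns and the LAA percentage;
* cohort CSV - one row per patient with scores, covariates, follow-up time,
  event indicator and censoring reason.

``write_results`` drops tables (CSV) and figures (PNG) into an output
directory together with a JSON manifest listing each artifact's SHA-256 and
the hash of the resolved configuration, so a run can be verified byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .scoring import (
    FibrosisCategory,
    LAARead,
    PatientScore,
    ReaderAssessment,
    RegionRead,
    snap_to_grid,
)
from .survival import CENSOR_REASONS

__all__ = [
    "read_region_csv",
    "read_cohort_csv",
    "scores_to_frame",
    "write_results",
    "fmt_percent",
    "fmt_hr",
    "fmt_ci",
]

REGION_CSV_COLUMNS = (
    "patient_id",
    "reader_id",
    "region_id",
    "pct_normal",
    "pct_reticular",
    "pct_reticular_tb",
    "pct_honeycomb",
    "laa_percent",
)

COHORT_CSV_COLUMNS = (
    "patient_id",
    "hfs",
    "gs",
    "age",
    "sex",
    "ecog_ps",
    "smoking",
    "histology",
    "stage",
    "gene_abnormality",
    "operation",
    "radiation",
    "time_days",
    "event",
    "censor_reason",
)

_EXTENT_COLS = {
    "pct_normal": FibrosisCategory.NORMAL,
    "pct_reticular": FibrosisCategory.RETICULAR,
    "pct_reticular_tb": FibrosisCategory.RETICULAR_TB,
    "pct_honeycomb": FibrosisCategory.HONEYCOMB,
}


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_region_csv(path, allow_offgrid: bool = False) -> list[ReaderAssessment]:
    """Load region-level reads into per-(patient, reader) assessments.

    With ``allow_offgrid`` extents are snapped to the nearest 5% step (ties
    away from normal); otherwise off-grid extents are a validation error.
    """
    return assessments_from_frame(pd.read_csv(path), allow_offgrid=allow_offgrid, path=path)


def assessments_from_frame(
    df: pd.DataFrame, allow_offgrid: bool = False, path="<frame>"
) -> list[ReaderAssessment]:
    """Group an in-memory region-read table into reader assessments."""
    _require_columns(df, [c for c in REGION_CSV_COLUMNS if c != "laa_percent"], path)
    has_laa = "laa_percent" in df.columns
    assessments = []
    for (patient_id, reader_id), group in df.groupby(
        ["patient_id", "reader_id"], sort=False
    ):
        fibrosis, emphysema = [], []
        for _, row in group.iterrows():
            extents = {cat: float(row[col]) for col, cat in _EXTENT_COLS.items()}
            if allow_offgrid:
                extents = snap_to_grid(extents)
            fibrosis.append(RegionRead(region_id=row["region_id"], extents=extents))
            if has_laa and pd.notna(row["laa_percent"]):
                emphysema.append(
                    LAARead(region_id=row["region_id"], laa_percent=float(row["laa_percent"]))
                )
        assessments.append(
            ReaderAssessment(
                reader_id=str(reader_id),
                patient_id=str(patient_id),
                fibrosis=tuple(fibrosis),
                emphysema=tuple(emphysema),
            )
        )
    return assessments


def read_cohort_csv(path) -> pd.DataFrame:
    """Load and validate a patient-level cohort table."""
    df = pd.read_csv(path)
    _require_columns(df, COHORT_CSV_COLUMNS, path)
    bad_reason = ~df["censor_reason"].isin(CENSOR_REASONS)
    if bad_reason.any():
        rows = [int(i) + 2 for i in df.index[bad_reason][:5]]  # +2: header + 1-basing
        raise ValidationError(
            f"{path}: unknown censor_reason token(s)"
            f" {sorted(df.loc[bad_reason, 'censor_reason'].unique())} at row(s) {rows}"
        )
    df["event"] = df["event"].astype(bool)
    inconsistent = df["event"] & (df["censor_reason"] != "none")
    if inconsistent.any():
        rows = [int(i) + 2 for i in df.index[inconsistent][:5]]
        raise ValidationError(
            f"{path}: event rows must carry censor_reason 'none' (row(s) {rows})"
        )
    if (df["time_days"] <= 0).any():
        rows = [int(i) + 2 for i in df.index[df["time_days"] <= 0][:5]]
        raise ValidationError(f"{path}: non-positive time_days at row(s) {rows}")
    return df


def scores_to_frame(scores: list[PatientScore]) -> pd.DataFrame:
    """Patient-score CSV layout for a list of scored patients."""
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in scores],
            "hfs": [s.hfs for s in scores],
            "gs": [s.gs for s in scores],
            "ild_severity": [s.ild_severity for s in scores],
            "emphysema_severity": [s.emphysema_severity for s in scores],
            "hfs_stratum": [s.hfs_stratum for s in scores],
        }
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(
    outdir,
    tables: dict[str, pd.DataFrame] | None = None,
    figures: dict | None = None,
    config: dict | None = None,
) -> dict:
    """Write tables/figures plus a manifest of hashes; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    for name, table in (tables or {}).items():
        p = outdir / f"{name}.csv"
        table.to_csv(p, index=isinstance(table.index, pd.MultiIndex) or table.index.name is not None)
        artifacts[p.name] = _sha256(p)
    for name, fig in (figures or {}).items():
        p = outdir / f"{name}.png"
        fig.savefig(p, dpi=150)
        artifacts[p.name] = _sha256(p)
    config = config or {}
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {"config": config, "config_sha256": config_hash, "artifacts": artifacts}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def fmt_percent(x: float) -> str:
    return f"{x:.1f}"


def fmt_hr(x: float) -> str:
    return f"{x:.2f}"


def fmt_ci(lo: float, hi: float, fmt=fmt_hr) -> str:
    return f"{fmt(lo)}–{fmt(hi)}"
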