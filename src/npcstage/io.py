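"""Delimited-text readers and writers for the pipeline's record tables.

Tables are comma-separated with a header row; tab-separated input is
accepted transparently. Readers validate every row against the domain
invariants and report the first offending row by number (1-based, header
excluded). Writers are deterministic: fixed column order, no index, so the
same results always serialise to byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .types import (
    DecisionRecord,
    DoseCategory,
    Field,
    Laterality,
    Level,
    NodeRecord,
    NStage,
    Pathology,
    PatientStagingRecord,
    TStage,
    ValidationError,
)

NODE_COLUMNS = [
    "node_id",
    "patient_id",
    "level",
    "pathology",
    "mri_score",
    "pet_score",
    "laterality",
    "short_axis_mm",
]

STAGING_COLUMNS = ["patient_id", "mri_n", "pet_n", "true_n", "t_stage"]

DECISION_COLUMNS = [
    "patient_id",
    "oncologist_id",
    "node_id",
    "node_pathology",
    "dose_before",
    "dose_after",
    "field_before",
    "field_after",
]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sep=None lets the csv sniffer accept comma or tab
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def _parse_enum(enum_cls, token: str, row: int, column: str):
    try:
        return enum_cls(token)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise ValidationError(
            f"row {row}: {column}={token!r} not one of [{valid}]"
        ) from None


def _parse_int(token: str, row: int, column: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ValidationError(f"row {row}: {column}={token!r} is not an integer") from None


def _optional(token: str) -> Optional[str]:
    return None if token.strip() == "" else token


def read_node_table(path: str | Path) -> list[NodeRecord]:
    """Read a node-level table into validated :class:`NodeRecord` objects.

    Row order is preserved. Unknown extra columns are ignored; missing
    required columns or invalid values raise :class:`ValidationError`
    naming the row.
    """
    df = _read_delimited(path)
    required = set(NODE_COLUMNS) - {"laterality", "short_axis_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing required columns: {sorted(missing)}")
    records: list[NodeRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sax = _optional(getattr(row, "short_axis_mm", "") or "")
        try:
            rec = NodeRecord(
                node_id=row.node_id,
                patient_id=row.patient_id,
                level=_parse_enum(Level, row.level, i, "level"),
                pathology=_parse_enum(Pathology, row.pathology, i, "pathology"),
                mri_score=_parse_int(row.mri_score, i, "mri_score"),
                pet_score=_parse_int(row.pet_score, i, "pet_score"),
                laterality=_parse_enum(
                    Laterality, getattr(row, "laterality", "unknown") or "unknown",
                    i, "laterality",
                ),
                short_axis_mm=float(sax) if sax is not None else None,
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
        records.append(rec)
    return records


def read_staging_table(path: str | Path) -> list[PatientStagingRecord]:
    """Read a patient-level staging table (N categories per modality + truth)."""
    df = _read_delimited(path)
    missing = {"patient_id", "mri_n", "pet_n", "true_n"} - set(df.columns)
    if missing:
        raise ValidationError(f"missing required columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        true_tok = _optional(row.true_n)
        t_tok = _optional(getattr(row, "t_stage", "") or "")
        records.append(
            PatientStagingRecord(
                patient_id=row.patient_id,
                mri_n=_parse_enum(NStage, row.mri_n, i, "mri_n"),
                pet_n=_parse_enum(NStage, row.pet_n, i, "pet_n"),
                true_n=_parse_enum(NStage, true_tok, i, "true_n") if true_tok else None,
                t_stage=_parse_enum(TStage, t_tok, i, "t_stage") if t_tok else None,
            )
        )
    return records


def read_decision_table(path: str | Path) -> list[DecisionRecord]:
    """Read a Cohort-C style decision table (before/after dose and field)."""
    df = _read_delimited(path)
    missing = set(DECISION_COLUMNS) - {"node_id"} - set(df.columns)
    if missing:
        raise ValidationError(f"missing required columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        records.append(
            DecisionRecord(
                patient_id=row.patient_id,
                oncologist_id=_parse_int(row.oncologist_id, i, "oncologist_id"),
                node_id=_optional(getattr(row, "node_id", "") or ""),
                node_pathology=_parse_enum(Pathology, row.node_pathology, i, "node_pathology"),
                dose_before=_parse_enum(DoseCategory, row.dose_before, i, "dose_before"),
                dose_after=_parse_enum(DoseCategory, row.dose_after, i, "dose_after"),
                field_before=_parse_enum(Field, row.field_before, i, "field_before"),
                field_after=_parse_enum(Field, row.field_after, i, "field_after"),
            )
        )
    return records


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and math.isnan(value):
        return ""
    if hasattr(value, "value"):  # enum
        return value.value
    return str(value)


def nodes_to_frame(records: Iterable[NodeRecord]) -> pd.DataFrame:
    rows = [
        {c: _cell(getattr(r, c)) for c in NODE_COLUMNS}
        for r in records
    ]
    return pd.DataFrame(rows, columns=NODE_COLUMNS)


def staging_to_frame(records: Iterable[PatientStagingRecord]) -> pd.DataFrame:
    rows = [{c: _cell(getattr(r, c)) for c in STAGING_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=STAGING_COLUMNS)


def decisions_to_frame(records: Iterable[DecisionRecord]) -> pd.DataFrame:
    rows = [{c: _cell(getattr(r, c)) for c in DECISION_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=DECISION_COLUMNS)


def write_node_table(records: Sequence[NodeRecord], path: str | Path) -> None:
    nodes_to_frame(records).to_csv(path, index=False)


def write_staging_table(records: Sequence[PatientStagingRecord], path: str | Path) -> None:
    staging_to_frame(records).to_csv(path, index=False)


def write_decision_table(records: Sequence[DecisionRecord], path: str | Path) -> None:
    decisions_to_frame(records).to_csv(path, index=False)


def config_hash(config: Mapping | object) -> str:
    """Stable short hash of a configuration (dict or dataclass)."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    if isinstance(config, dict):
        # the artifact's destination is not semantic configuration
        config = {k: v for k, v in config.items() if k != "output_dir"}
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_result_tables(
    results: Mapping[str, pd.DataFrame],
    output_dir: str | Path,
    *,
    seed: int | None = None,
    config: Mapping | object | None = None,
) -> list[str]:
    """Write each result frame as ``<name>.csv`` plus a run-metadata JSON.

    Returns the manifest: sorted list of every file written (relative
    names). The metadata file embeds the seed, config hash and package
    version so any artifact can be traced back to its run.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for name in sorted(results):
        fname = f"{name}.csv"
        results[name].to_csv(out / fname, index=False)
        manifest.append(fname)
    meta = {
        "package": "npcstage",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "tables": manifest,
    }
    meta_name = "run_metadata.json"
    (out / meta_name).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    manifest.append(meta_name)
    return sorted(manifest)
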