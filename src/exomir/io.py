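"""File formats, parsing and schema validation.

Three plain-text table formats are supported:

* alteration matrix — CSV/TSV, columns ``patient_id, stage, <gene>...`` with
  0/1 entries;
* annotation table — TSV with columns ``symbol, exosomal,
  dir_pancreatitis_vs_healthy, dir_pdac_vs_pancreatitis, mature_arms``
  (mature arms comma-joined);
* Cq table — long-format CSV ``sample_id, cell_line, biological_replicate,
  technical_replicate, assay, cq`` where a non-detect well is an empty field
  or the instrument dialect ``Undetermined``; a wide per-plate layout (one
  column per assay) is also accepted.

The ``validate_*`` functions re-read files line by line and return
line-numbered findings instead of raising, for pre-flight checks.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import DIRECTIONS, AnnotationTable, GeneAnnotation
from .errors import ValidationError
from .panel import VALID_STAGE_LABELS, AlterationMatrix
from .qpcr import CqTable

NON_DETECT_TOKENS = ("", "Undetermined", "undetermined", "UNDETERMINED", "NA")

_CQ_ID_COLUMNS = (
    "sample_id",
    "cell_line",
    "biological_replicate",
    "technical_replicate",
)


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_alteration_matrix(path: str | Path) -> AlterationMatrix:
    frame = pd.read_csv(path, sep=_sep(path), dtype={0: str})
    if list(frame.columns[:2]) != ["patient_id", "stage"]:
        raise ValidationError(
            f"{path}: first two columns must be 'patient_id', 'stage', "
            f"got {list(frame.columns[:2])}"
        )
    data = frame.set_index("patient_id").drop(columns=["stage"])
    return AlterationMatrix(data=data, stage=frame.set_index("patient_id")["stage"])


def write_alteration_matrix(matrix: AlterationMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.insert(0, "stage", matrix.stage)
    out.index.name = "patient_id"
    out.to_csv(path, sep=_sep(path))


def read_annotations(path: str | Path) -> AnnotationTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "symbol",
        "exosomal",
        "dir_pancreatitis_vs_healthy",
        "dir_pdac_vs_pancreatitis",
        "mature_arms",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing annotation columns {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        arms = row["mature_arms"]
        records.append(
            GeneAnnotation(
                symbol=row["symbol"],
                exosomal=bool(int(row["exosomal"])),
                dir_pancreatitis_vs_healthy=row["dir_pancreatitis_vs_healthy"],
                dir_pdac_vs_pancreatitis=row["dir_pdac_vs_pancreatitis"],
                mature_arms=tuple(arms.split(",")) if pd.notna(arms) and arms else (),
            )
        )
    return AnnotationTable(records)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    rows = [
        {
            "symbol": a.symbol,
            "exosomal": int(a.exosomal),
            "dir_pancreatitis_vs_healthy": a.dir_pancreatitis_vs_healthy,
            "dir_pdac_vs_pancreatitis": a.dir_pdac_vs_pancreatitis,
            "mature_arms": ",".join(a.mature_arms),
        }
        for a in table.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cq_long(path: str | Path, **table_kwargs) -> CqTable:
    frame = pd.read_csv(
        path,
        sep=_sep(path),
        na_values=list(NON_DETECT_TOKENS),
        keep_default_na=True,
        dtype={"sample_id": str, "cell_line": str, "assay": str},
    )
    return CqTable(data=frame, **table_kwargs)


def read_cq_wide(path: str | Path, **table_kwargs) -> CqTable:
    """Wide per-plate layout: id columns then one Cq column per assay."""
    frame = pd.read_csv(
        path,
        sep=_sep(path),
        na_values=list(NON_DETECT_TOKENS),
        keep_default_na=True,
        dtype={"sample_id": str, "cell_line": str},
    )
    missing = [c for c in _CQ_ID_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing id columns {missing}")
    long = frame.melt(
        id_vars=list(_CQ_ID_COLUMNS), var_name="assay", value_name="cq"
    )
    return CqTable(data=long, **table_kwargs)


def write_cq_long(table: CqTable, path: str | Path) -> None:
    out = table.data[list(_CQ_ID_COLUMNS) + ["assay", "cq"]].copy()
    out.to_csv(path, sep=_sep(path), index=False, na_rep="Undetermined")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# line-numbered validation


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``line`` is 1-based (header = line 1)."""

    path: str
    line: int
    message: str

    def __str__(self) -> str:
        return f"{self.path}:{self.line}: {self.message}"


def _read_rows(path: str | Path) -> list[list[str]]:
    with open(path, newline="") as handle:
        return list(csv.reader(handle, delimiter=_sep(path)))


def validate_matrix_file(path: str | Path) -> list[Finding]:
    findings: list[Finding] = []
    try:
        rows = _read_rows(path)
    except OSError as exc:
        return [Finding(str(path), 0, f"unreadable: {exc}")]
    if not rows:
        return [Finding(str(path), 1, "empty file")]
    header = rows[0]
    if header[:2] != ["patient_id", "stage"]:
        findings.append(
            Finding(str(path), 1, "header must start with 'patient_id, stage'")
        )
        return findings
    genes = header[2:]
    seen_genes = set()
    for g in genes:
        if g in seen_genes:
            findings.append(Finding(str(path), 1, f"duplicate gene column {g!r}"))
        seen_genes.add(g)
    seen_patients: set[str] = set()
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            findings.append(
                Finding(str(path), i, f"expected {len(header)} fields, got {len(row)}")
            )
            continue
        pid, stage = row[0], row[1]
        if pid in seen_patients:
            findings.append(Finding(str(path), i, f"duplicate patient_id {pid!r}"))
        seen_patients.add(pid)
        if stage not in VALID_STAGE_LABELS:
            findings.append(
                Finding(
                    str(path),
                    i,
                    f"stage {stage!r} not in allowed set {VALID_STAGE_LABELS}",
                )
            )
        for value in row[2:]:
            if value not in ("0", "1"):
                findings.append(
                    Finding(str(path), i, f"alteration entry {value!r} must be 0 or 1")
                )
                break
    return findings


def validate_annotation_file(path: str | Path) -> list[Finding]:
    findings: list[Finding] = []
    try:
        rows = _read_rows(path)
    except OSError as exc:
        return [Finding(str(path), 0, f"unreadable: {exc}")]
    if not rows:
        return [Finding(str(path), 1, "empty file")]
    header = rows[0]
    required = [
        "symbol",
        "exosomal",
        "dir_pancreatitis_vs_healthy",
        "dir_pdac_vs_pancreatitis",
        "mature_arms",
    ]
    missing = [c for c in required if c not in header]
    if missing:
        return [Finding(str(path), 1, f"missing columns {missing}")]
    idx = {c: header.index(c) for c in required}
    seen: set[str] = set()
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            findings.append(
                Finding(str(path), i, f"expected {len(header)} fields, got {len(row)}")
            )
            continue
        symbol = row[idx["symbol"]]
        if symbol in seen:
            findings.append(Finding(str(path), i, f"duplicate symbol {symbol!r}"))
        seen.add(symbol)
        if row[idx["exosomal"]] not in ("0", "1"):
            findings.append(Finding(str(path), i, "exosomal flag must be 0 or 1"))
        for col in ("dir_pancreatitis_vs_healthy", "dir_pdac_vs_pancreatitis"):
            if row[idx[col]] not in DIRECTIONS:
                findings.append(
                    Finding(str(path), i, f"{col} {row[idx[col]]!r} not in {DIRECTIONS}")
                )
    return findings


def validate_cq_file(path: str | Path) -> list[Finding]:
    findings: list[Finding] = []
    try:
        rows = _read_rows(path)
    except OSError as exc:
        return [Finding(str(path), 0, f"unreadable: {exc}")]
    if not rows:
        return [Finding(str(path), 1, "empty file")]
    header = rows[0]
    required = list(_CQ_ID_COLUMNS) + ["assay", "cq"]
    missing = [c for c in required if c not in header]
    if missing:
        return [Finding(str(path), 1, f"missing columns {missing}")]
    idx = {c: header.index(c) for c in required}
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            findings.append(
                Finding(str(path), i, f"expected {len(header)} fields, got {len(row)}")
            )
            continue
        key = (row[idx["sample_id"]], row[idx["assay"]], row[idx["technical_replicate"]])
        if key in seen:
            findings.append(
                Finding(
                    str(path),
                    i,
                    f"duplicate (sample_id, assay, technical_replicate) row {key}",
                )
            )
        seen.add(key)
        raw = row[idx["cq"]]
        if raw not in NON_DETECT_TOKENS:
            try:
                value = float(raw)
            except ValueError:
                findings.append(
                    Finding(str(path), i, f"cq {raw!r} is neither numeric nor non-detect")
                )
                continue
            if not np.isfinite(value) or value <= 0:
                findings.append(Finding(str(path), i, f"cq {value} must be finite and > 0"))
    return findings


def validate_inputs(
    matrix: str | Path | None = None,
    annotations: str | Path | None = None,
    cq: str | Path | None = None,
) -> list[Finding]:
    """Schema/uniqueness/range checks for any subset of the three file types."""
    findings: list[Finding] = []
    if matrix is not None:
        findings.extend(validate_matrix_file(matrix))
    if annotations is not None:
        findings.extend(validate_annotation_file(annotations))
    if cq is not None:
        findings.extend(validate_cq_file(cq))
    return findings
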