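"""Readers and writers for the pipeline's plain-text formats.

Expression files are TSV with probe-set IDs in the first column and one
column per patient (the layout expression matrices are distributed in);
in memory the package uses the transposed, patients x probes orientation.
A GEO series-matrix-like dialect is also read: metadata lines start with
"!" and the matrix sits between the table-begin/table-end markers.
Clinical tables are one TSV row per patient.  "Not reached" medians are
serialized as the literal token "NR".
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gene_sets",
    "write_gene_sets",
    "format_duration",
    "NOT_REACHED",
]

NOT_REACHED = "NR"

CLINICAL_REQUIRED = ("os_days", "os_event")
CLINICAL_FLAGS = ("os_event", "efs_event", "npm1_mutated", "flt3_itd")


class ValidationError(ValueError):
    """A file failed structural validation."""


def _detect_dialect(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "series_matrix" if line.startswith("!") else "tsv"
    raise ValidationError(f"{path}: file is empty")


def read_expression(path, dialect: str = "auto") -> pd.DataFrame:
    """Read an expression matrix; returns patients x probe sets (float).

    ``dialect`` is "tsv", "series_matrix" or "auto" (sniffed from the
    first non-blank line).  Duplicate probe or patient IDs and non-numeric
    cells are rejected with coordinates.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif dialect == "series_matrix":
        lines = []
        in_table = False
        for line in path.read_text().splitlines():
            marker = line.strip().lower()
            if marker.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if marker.startswith("!series_matrix_table_end"):
                break
            if in_table and line.strip():
                lines.append(line)
            # lines before the table marker starting with "!" are metadata
        if not lines:
            raise ValidationError(f"{path}: no series-matrix table found")
        from io import StringIO

        frame = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0, dtype=str)
        frame.index = frame.index.map(lambda s: str(s).strip('"'))
        frame.columns = [str(c).strip('"') for c in frame.columns]
    else:
        raise ValidationError(f"unknown expression dialect {dialect!r}")

    if frame.index.duplicated().any():
        dups = sorted(frame.index[frame.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicated probe set ID(s): {dups}")
    if pd.Index(frame.columns).duplicated().any():
        dups = sorted(pd.Index(frame.columns)[pd.Index(frame.columns).duplicated()])
        raise ValidationError(f"{path}: duplicated patient ID(s): {dups}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {frame.iat[r, c]!r} at probe "
            f"{frame.index[r]!r}, patient {frame.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise ValidationError(f"{path}: missing expression values")
    out = numeric.T
    out.index.name = "patient_id"
    out.columns.name = "probe_set"
    return out


def write_expression(frame: pd.DataFrame, path) -> None:
    """Write a patients x probes matrix in the probes x patients file layout."""
    out = frame.T
    out.index.name = "probe_set"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_clinical(path) -> pd.DataFrame:
    """Clinical TSV: patient_id, os_days, os_event, [efs_days, efs_event],
    npm1_mutated, flt3_itd, [cohort]."""
    frame = pd.read_csv(path, sep="\t")
    if "patient_id" not in frame.columns:
        raise ValidationError(f"{path}: missing patient_id column")
    frame = frame.set_index("patient_id")
    if frame.index.duplicated().any():
        dups = sorted(frame.index[frame.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicated patient row(s): {dups}")
    missing = [c for c in CLINICAL_REQUIRED if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s): {missing}")
    for col in ("os_days", "efs_days"):
        if col in frame.columns and (frame[col] < 0).any():
            raise ValidationError(f"{path}: negative duration in {col}")
    for col in CLINICAL_FLAGS:
        if col in frame.columns:
            vals = frame[col].dropna()
            if not vals.isin([0, 1]).all():
                raise ValidationError(f"{path}: column {col} must be 0/1")
    return frame


def write_clinical(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t")


def read_gene_sets(path) -> dict[str, list[str]]:
    """Gene-set file: probe set -> list of pathways.

    Two formats: GMT (one line per pathway: name, description, members...)
    or a two-column TSV (probe_set <tab> pathway, with or without header).
    """
    path = Path(path)
    text = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not text:
        raise ValidationError(f"{path}: empty gene-set file")
    mapping: dict[str, list[str]] = {}
    if path.suffix.lower() == ".gmt" or len(text[0].split("\t")) >= 3:
        for line in text:
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}: malformed GMT line: {line[:60]!r}")
            pathway = fields[0]
            for probe in fields[2:]:
                if probe:
                    mapping.setdefault(probe, []).append(pathway)
    else:
        rows = text
        if rows[0].lower().replace("\t", " ").startswith(("probe", "probe_set")):
            rows = rows[1:]
        for line in rows:
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}: malformed gene-set line: {line[:60]!r}")
            mapping.setdefault(fields[0], []).append(fields[1])
    return {probe: sorted(set(pws)) for probe, pws in mapping.items()}


def write_gene_sets(mapping, path) -> None:
    """Write a probe->pathway(s) map as two-column TSV."""
    with open(path, "w") as fh:
        fh.write("probe_set\tpathway\n")
        if isinstance(mapping, pd.DataFrame):
            pairs = mapping[["probe_set", "pathway"]].itertuples(index=False)
        else:
            pairs = (
                (probe, pw)
                for probe, pws in mapping.items()
                for pw in ([pws] if isinstance(pws, str) else pws)
            )
        for probe, pw in pairs:
            fh.write(f"{probe}\t{pw}\n")


def format_duration(value: float | None, decimals: int = 1) -> str:
    """Days as text; None (median never reached) becomes the token "NR"."""
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return NOT_REACHED
    return f"{value:.{decimals}f}"


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
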