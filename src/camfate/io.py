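"""CSV schemas, readers and validators for the pipeline's tables.

All tables travel as plain CSV. The central schema is the *section-count*
table, one row per histology observation::

    patient_id, compartment, marker, days_post_transplant,
    n_marker_pos, n_y_pos, is_male_control

Controls are male tissue without a transplant time (``days_post_transplant``
empty); transplant rows carry a positive time. Validators return
human-readable violation messages naming the row (0-based data row) and
column, so the CLI can report schema problems precisely.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SECTION_COUNT_COLUMNS = [
    "patient_id",
    "compartment",
    "marker",
    "days_post_transplant",
    "n_marker_pos",
    "n_y_pos",
    "is_male_control",
]

QUANTIFICATION_COLUMNS = ["patient_id", "group", "marker_pair", "measure"]

COMPOSITION_COLUMNS = ["cluster", "condition", "count"]


def read_section_counts(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path)
    if "is_male_control" in df.columns:
        df["is_male_control"] = df["is_male_control"].astype(bool)
    return df


def write_section_counts(df: pd.DataFrame, path: "str | Path") -> None:
    df.to_csv(path, index=False)


def read_composition(path: "str | Path") -> pd.DataFrame:
    """Read a composition table, accepting long (cluster,condition,count) or
    wide (clusters x conditions matrix with a leading label column) CSVs."""
    df = pd.read_csv(path)
    if set(COMPOSITION_COLUMNS).issubset(df.columns):
        return (
            df.pivot_table(
                index="cluster", columns="condition", values="count", fill_value=0
            )
            .rename_axis(index=None, columns=None)
        )
    return df.set_index(df.columns[0]).rename_axis(index=None, columns=None)


def read_quantification(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path)


def _check_columns(df: pd.DataFrame, required: list[str]) -> list[str]:
    missing = [c for c in required if c not in df.columns]
    return [f"missing required column {c!r}" for c in missing]


def validate_section_counts(df: pd.DataFrame) -> list[str]:
    """All invariant violations of a section-count table, one message each."""
    violations = _check_columns(df, SECTION_COUNT_COLUMNS)
    if violations:
        return violations
    for idx, row in df.iterrows():
        loc = f"row {idx}"
        for col in ("n_marker_pos", "n_y_pos"):
            value = row[col]
            if pd.isna(value) or value < 0 or value != int(value):
                violations.append(f"{loc}: column {col!r} must be a non-negative integer, got {value}")
        if pd.notna(row["n_marker_pos"]) and pd.notna(row["n_y_pos"]):
            if row["n_y_pos"] > row["n_marker_pos"]:
                violations.append(
                    f"{loc}: n_y_pos ({row['n_y_pos']}) exceeds n_marker_pos ({row['n_marker_pos']})"
                )
        is_control = bool(row["is_male_control"])
        has_days = pd.notna(row["days_post_transplant"])
        if is_control and has_days:
            violations.append(
                f"{loc}: male-control rows must not carry days_post_transplant"
            )
        if not is_control:
            if not has_days:
                violations.append(f"{loc}: transplant rows require days_post_transplant")
            elif row["days_post_transplant"] <= 0:
                violations.append(
                    f"{loc}: days_post_transplant must be positive, got {row['days_post_transplant']}"
                )
    return violations


def validate_quantification(df: pd.DataFrame) -> list[str]:
    violations = _check_columns(df, QUANTIFICATION_COLUMNS)
    if violations:
        return violations
    bad = df.index[df["measure"].isna() | (df["measure"] < 0)]
    return [f"row {i}: column 'measure' must be a non-negative number" for i in bad]


def validate_composition(table: pd.DataFrame) -> list[str]:
    violations: list[str] = []
    values = table.to_numpy()
    if values.size == 0:
        return ["composition table is empty"]
    arr = values.astype(float)
    if np.isnan(arr).any():
        violations.append("composition table contains missing entries")
    if (arr < 0).any():
        violations.append("composition table contains negative counts")
    if not np.allclose(arr[~np.isnan(arr)], np.round(arr[~np.isnan(arr)])):
        violations.append("composition table contains non-integer counts")
    if np.nansum(arr) == 0:
        violations.append("composition table has no cells")
    return violations


def validate_tables(paths: "dict[str, str | Path]") -> dict:
    """Validate a set of named tables; returns a per-file report.

    ``paths`` maps table kinds (``counts``, ``controls``, ``composition``,
    ``quantification``) to file paths. The report maps each kind to a dict
    with ``path``, ``ok`` and ``violations``; an unreadable file raises
    ``OSError`` naming the path.
    """
    report = {}
    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            raise OSError(f"cannot read {kind} table: {path}")
        if kind in ("counts", "controls"):
            violations = validate_section_counts(read_section_counts(path))
        elif kind == "composition":
            violations = validate_composition(read_composition(path))
        elif kind == "quantification":
            violations = validate_quantification(read_quantification(path))
        else:
            raise ValueError(f"unknown table kind {kind!r}")
        report[kind] = {"path": str(path), "ok": not violations, "violations": violations}
    return report
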