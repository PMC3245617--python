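"""Tab-delimited file I/O for every artifact in the pipeline.

All files are plain TSV with a header row.  Expression matrices use the
probe id as the first column (header ``probe``) and sample ids as the
remaining headers; detection calls live in a parallel same-shape file.
Round trips are lossless: ``read(write(x)) == x`` at full float precision
(values are serialized with :func:`repr`-shortest formatting, which pandas
produces by default).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (ExpressionMatrix, GroundTruth, validate_probe_map,
                         validate_sample_sheet, validate_target_table)
from .errors import ParseError


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str,
                         keep_default_na=False, na_values=[])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    return df


def _check_unique_ids(ids: pd.Series, what: str, path) -> None:
    dup = ids.duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        # +2: one for the header line, one for 1-based numbering
        raise ParseError(f"{path}: duplicate {what} id {ids.iloc[i]!r} "
                         f"at line {i + 2}")


def _numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].isin(["nan", "NaN"])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"{path}: non-numeric cell {df[col].iloc[i]!r} "
                             f"in column {col!r} at line {i + 2}")
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# expression matrices

def write_matrix(matrix: ExpressionMatrix, values_path, calls_path=None) -> None:
    """Write values (and, if present, detection calls) to TSV files."""
    df = matrix.values.copy()
    df.insert(0, "probe", matrix.values.index)
    df.to_csv(values_path, sep="\t", index=False)
    if matrix.calls is not None:
        if calls_path is None:
            raise ValueError("matrix has detection calls but no calls_path given")
        cf = matrix.calls.copy()
        cf.insert(0, "probe", matrix.calls.index)
        cf.to_csv(calls_path, sep="\t", index=False)


def read_matrix(values_path, calls_path=None, scale: str = "log2") -> ExpressionMatrix:
    """Read an expression matrix, optionally with its detection-call file."""
    df = _read_tsv(values_path)
    if df.columns[0] != "probe":
        raise ParseError(f"{values_path}: first column must be 'probe', "
                         f"got {df.columns[0]!r}")
    _check_unique_ids(df["probe"], "probe", values_path)
    values = _numeric(df.drop(columns="probe"), values_path)
    values.index = pd.Index(df["probe"], name="probe")

    calls = None
    if calls_path is not None:
        cf = _read_tsv(calls_path)
        _check_unique_ids(cf["probe"], "probe", calls_path)
        calls = cf.drop(columns="probe")
        calls.index = pd.Index(cf["probe"], name="probe")
    return ExpressionMatrix(values=values, calls=calls, scale=scale)


# ---------------------------------------------------------------------------
# annotation tables

def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_unique_ids(df["sample"], "sample", path)
    return validate_sample_sheet(df)


def write_probe_map(pmap: pd.DataFrame, path) -> None:
    validate_probe_map(pmap).to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_unique_ids(df["probe"], "probe", path)
    for col in ("is_control", "species_ok", "replicate"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    return validate_probe_map(df)


def write_target_table(targets: pd.DataFrame, path) -> None:
    validate_target_table(targets).to_csv(path, sep="\t", index=False)


def read_target_table(path) -> pd.DataFrame:
    return validate_target_table(_read_tsv(path))


# ---------------------------------------------------------------------------
# ground truth (one long-format file: kind / feature / value)

_TRUTH_KINDS = ("model_specific", "subtype_differential", "regulated", "decoy")


def write_ground_truth(truth: GroundTruth, path) -> None:
    rows = []
    for _, r in truth.model_specific.iterrows():
        rows.append(("model_specific", r["feature"], r["group"]))
    for _, r in truth.subtype_differential.iterrows():
        rows.append(("subtype_differential", r["feature"], r["direction"]))
    for _, r in truth.regulated_pairs.iterrows():
        rows.append(("regulated", r["mirna"], r["gene"]))
    for _, r in truth.decoy_pairs.iterrows():
        rows.append(("decoy", r["mirna"], r["gene"]))
    pd.DataFrame(rows, columns=["kind", "feature", "value"]).to_csv(
        path, sep="\t", index=False)


def read_ground_truth(path) -> GroundTruth:
    df = _read_tsv(path)
    bad = set(df["kind"].unique()) - set(_TRUTH_KINDS)
    if bad:
        raise ParseError(f"{path}: unknown ground-truth kinds {sorted(bad)}")

    def _sub(kind, cols):
        sel = df.loc[df["kind"] == kind, ["feature", "value"]]
        sel.columns = cols
        return sel.reset_index(drop=True)

    return GroundTruth(
        model_specific=_sub("model_specific", ["feature", "group"]),
        subtype_differential=_sub("subtype_differential", ["feature", "direction"]),
        regulated_pairs=_sub("regulated", ["mirna", "gene"]),
        decoy_pairs=_sub("decoy", ["mirna", "gene"]),
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as TSV (header, no index)."""
    df.to_csv(path, sep="\t", index=False)
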