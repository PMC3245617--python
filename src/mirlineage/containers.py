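"""In-memory containers for the analysis.

The central object is :class:`ExpressionMatrix`: a probes x samples table of
log2 intensities (or per-array z-scores) with an optional parallel table of
MAS5-style detection calls ('P'/'M'/'A').  Sample sheets, probe maps and
predicted-target tables are plain :class:`pandas.DataFrame` objects with
documented, validated column sets -- the same convention the tab-delimited
file formats use.

Required columns
----------------
sample sheet : ``sample`` (unique), ``model``, ``subtype`` (basal/luminal/normal), ``strain``
probe map    : ``probe`` (unique), ``feature``, ``kind`` (miRNA/mRNA), ``strand`` (+/-),
               ``is_control`` (0/1), ``species_ok`` (0/1), ``replicate`` (1..k)
target table : ``mirna``, ``gene``, ``source`` (predicted/true/decoy); (mirna, gene) unique
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: allowed values of the ExpressionMatrix scale tag
SCALE_LINEAR = "linear"
SCALE_LOG2 = "log2"
SCALE_ZSCORE = "zscore"
_SCALES = (SCALE_LINEAR, SCALE_LOG2, SCALE_ZSCORE)

SAMPLE_SHEET_COLUMNS = ("sample", "model", "subtype", "strain")
PROBE_MAP_COLUMNS = ("probe", "feature", "kind", "strand", "is_control",
                     "species_ok", "replicate")
TARGET_TABLE_COLUMNS = ("mirna", "gene", "source")
DETECTION_CALLS = frozenset("PMA")


@dataclass
class ExpressionMatrix:
    """Probes x samples expression table with optional detection calls.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns are sample ids, float values.
    calls
        Optional same-shape DataFrame of single-character detection calls
        ('P' present, 'M' marginal, 'A' absent).
    scale
        One of ``"linear"``, ``"log2"`` or ``"zscore"``.
    """

    values: pd.DataFrame
    calls: pd.DataFrame | None = None
    scale: str = SCALE_LOG2

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate probe ids: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dupes[:5])}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if self.calls is not None:
            if (list(self.calls.index) != list(self.values.index)
                    or list(self.calls.columns) != list(self.values.columns)):
                raise ValidationError("detection calls must share the matrix "
                                      "probe and sample ids, in order")
            bad = set(np.unique(self.calls.to_numpy().astype(str))) - DETECTION_CALLS
            if bad:
                raise ValidationError(f"invalid detection calls: {sorted(bad)}")

    # -- conveniences -------------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            calls=None if self.calls is None else self.calls.copy(),
            scale=self.scale,
        )

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        """Row subset preserving the requested order."""
        return ExpressionMatrix(
            values=self.values.loc[probe_ids],
            calls=None if self.calls is None else self.calls.loc[probe_ids],
            scale=self.scale,
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Column subset preserving the requested order."""
        return ExpressionMatrix(
            values=self.values[list(sample_ids)],
            calls=None if self.calls is None else self.calls[list(sample_ids)],
            scale=self.scale,
        )


@dataclass
class GroundTruth:
    """Record of the effects a synthetic dataset planted; the recovery oracle.

    ``model_specific``      : columns (feature, group)
    ``subtype_differential``: columns (feature, direction) with direction in
                              {basal, luminal} = the class the miRNA is up in
    ``regulated_pairs``     : columns (mirna, gene) -- genes truly repressed
    ``decoy_pairs``         : columns (mirna, gene) -- predicted but uncoupled
    """

    model_specific: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["feature", "group"]))
    subtype_differential: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["feature", "direction"]))
    regulated_pairs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["mirna", "gene"]))
    decoy_pairs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["mirna", "gene"]))

    def __post_init__(self) -> None:
        reg = set(map(tuple, self.regulated_pairs[["mirna", "gene"]].to_numpy()))
        dec = set(map(tuple, self.decoy_pairs[["mirna", "gene"]].to_numpy()))
        overlap = reg & dec
        if overlap:
            raise ValidationError(
                f"regulated and decoy pairs overlap: {sorted(overlap)[:5]}")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns {missing}")
    if sheet["sample"].duplicated().any():
        dupes = sheet.loc[sheet["sample"].duplicated(), "sample"].tolist()
        raise ValidationError(f"duplicate sample ids in sheet: {dupes[:5]}")
    return sheet


def validate_probe_map(pmap: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROBE_MAP_COLUMNS if c not in pmap.columns]
    if missing:
        raise ValidationError(f"probe map missing columns {missing}")
    if pmap["probe"].duplicated().any():
        dupes = pmap.loc[pmap["probe"].duplicated(), "probe"].tolist()
        raise ValidationError(f"duplicate probe ids in map: {dupes[:5]}")
    bad = set(pmap["strand"].unique()) - {"+", "-"}
    if bad:
        raise ValidationError(f"invalid strand values: {sorted(bad)}")
    return pmap


def validate_target_table(targets: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TARGET_TABLE_COLUMNS if c not in targets.columns]
    if missing:
        raise ValidationError(f"target table missing columns {missing}")
    if targets.duplicated(subset=["mirna", "gene"]).any():
        dupes = targets.loc[targets.duplicated(subset=["mirna", "gene"]),
                            ["mirna", "gene"]].to_numpy()
        raise ValidationError(
            f"duplicate (mirna, gene) pairs: {list(map(tuple, dupes[:5]))}")
    return targets


def samples_in_group(sheet: pd.DataFrame, column: str, level: str) -> list[str]:
    """Sample ids whose sample-sheet ``column`` equals ``level``."""
    validate_sample_sheet(sheet)
    if column not in sheet.columns:
        raise ValidationError(f"sample sheet has no column {column!r}")
    return sheet.loc[sheet[column] == level, "sample"].tolist()
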