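"""miRNA matrix preprocessing: probe selection, global median normalization,
detection-call filtering and per-array z-scoring.

The processing order mirrors standard single-channel array practice:
select analyzable probes (mouse, '+' strand, non-control), scale each array
multiplicatively on the linear scale so all per-array medians agree, drop
probes absent from nearly every array, then convert each array to z-scores
(each probe's log2 value relative to the mean and standard deviation of all
probes on that array).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_probe_map
from .errors import (DegenerateArrayError, MappingError, NormalizationError,
                     ValidationError)

log = logging.getLogger(__name__)


def select_probes(matrix: ExpressionMatrix, probes: pd.DataFrame) -> ExpressionMatrix:
    """Keep non-control, species-matched, '+'-strand probes (order preserved)."""
    validate_probe_map(probes)
    pmap = probes.set_index("probe")
    unmapped = [p for p in matrix.probe_ids if p not in pmap.index]
    if unmapped:
        raise MappingError(f"probes missing from the probe map: {unmapped[:10]}"
                           + ("..." if len(unmapped) > 10 else ""))
    sub = pmap.loc[matrix.probe_ids]
    keep_mask = ((sub["is_control"].astype(int) == 0)
                 & (sub["species_ok"].astype(int) == 1)
                 & (sub["strand"] == "+"))
    keep = [p for p, k in zip(matrix.probe_ids, keep_mask) if k]
    return matrix.subset_probes(keep)


def global_median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each array so every per-array median equals the global target.

    Scaling is multiplicative on the linear intensity scale (equivalently,
    an additive shift on log2): each array is multiplied by
    ``target / median(array)`` where the target is the median of the
    original per-array medians.  Accepts matrices tagged ``linear`` or
    ``log2``; the output keeps the input's scale tag.  Idempotent.
    """
    if matrix.scale == "zscore":
        raise ValidationError("cannot median-normalize a z-scored matrix")
    if matrix.n_probes < 1:
        raise ValidationError("normalization requires at least one probe")
    values = matrix.values.to_numpy(dtype=float)
    linear = np.exp2(values) if matrix.scale == "log2" else values
    medians = np.median(linear, axis=0)
    if (medians <= 0).any():
        bad = [s for s, m in zip(matrix.sample_ids, medians) if m <= 0]
        raise NormalizationError(
            f"non-positive linear-scale median for samples {bad[:5]}")
    target = np.median(medians)
    scaled = linear * (target / medians)[None, :]
    out = np.log2(scaled) if matrix.scale == "log2" else scaled
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=matrix.values.index,
                            columns=matrix.values.columns),
        calls=None if matrix.calls is None else matrix.calls.copy(),
        scale=matrix.scale)


def detection_filter(matrix: ExpressionMatrix, min_present: int = 3) -> ExpressionMatrix:
    """Drop probes detected ('P' or 'M') in fewer than ``min_present`` arrays."""
    if matrix.calls is None:
        raise ValidationError("detection_filter requires a detection-call table")
    calls = matrix.calls.to_numpy().astype(str)
    n_present = ((calls == "P") | (calls == "M")).sum(axis=1)
    keep = [p for p, n in zip(matrix.probe_ids, n_present) if n >= min_present]
    dropped = matrix.n_probes - len(keep)
    if dropped:
        log.info("detection_filter: dropped %d of %d probes "
                 "(P/M in < %d samples)", dropped, matrix.n_probes, min_present)
    return matrix.subset_probes(keep)


def zscore_per_sample(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert each array to z-scores over its probes.

    For each sample (array), ``z = (x - mean(x)) / sd(x)`` with the sample
    standard deviation (n-1 denominator), taken across all probes on the
    array.  Probes with zero variance across samples carry no comparative
    signal and are dropped first with a logged warning.
    """
    if matrix.n_probes < 2:
        raise ValidationError("z-scoring requires at least two probes")
    values = matrix.values.to_numpy(dtype=float)
    row_var = values.var(axis=1)
    if (row_var == 0).any() and matrix.n_samples > 1:
        keep = [p for p, v in zip(matrix.probe_ids, row_var) if v > 0]
        log.warning("zscore_per_sample: dropping %d constant probes",
                    matrix.n_probes - len(keep))
        matrix = matrix.subset_probes(keep)
        values = matrix.values.to_numpy(dtype=float)
        if matrix.n_probes < 2:
            raise ValidationError("fewer than two non-constant probes remain")
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = [s for s, sd in zip(matrix.sample_ids, sds) if sd == 0]
        raise DegenerateArrayError(
            f"zero per-array variance for samples {bad[:5]}")
    z = (values - means[None, :]) / sds[None, :]
    return ExpressionMatrix(
        values=pd.DataFrame(z, index=matrix.values.index,
                            columns=matrix.values.columns),
        calls=None if matrix.calls is None else matrix.calls.copy(),
        scale="zscore")


def preprocess_mirna(matrix: ExpressionMatrix, probes: pd.DataFrame,
                     min_present: int = 3):
    """Full preprocessing chain; returns (normalized log2, z-scored) matrices."""
    selected = select_probes(matrix, probes)
    normalized = global_median_normalize(selected)
    filtered = detection_filter(normalized, min_present=min_present)
    return filtered, zscore_per_sample(filtered)
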