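"""Array vs qPCR concordance: per-feature Pearson correlation between the
mean log2 array intensity of a miRNA (over its replicate probes) and the
paired -dCt qPCR measurement across samples."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


def concordance(array: ExpressionMatrix, probes: pd.DataFrame,
                qpcr: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Per-feature correlation between array intensity and qPCR -dCt.

    ``qpcr`` is the paired table (columns ``sample``, ``feature``,
    ``neg_delta_ct``).  Unmatched samples are dropped with a warning;
    features with fewer than ``min_pairs`` paired samples are skipped.
    Returns a DataFrame with columns ``feature``, ``n``, ``r``, ``p``.
    """
    feature_probes = probes[probes["kind"] == "miRNA"].groupby("feature")["probe"]
    known_samples = set(array.sample_ids)
    rows = []
    for feature, block in qpcr.groupby("feature", sort=False):
        unmatched = block[~block["sample"].isin(known_samples)]
        if len(unmatched):
            log.warning("concordance: dropping %d unmatched samples for %s",
                        len(unmatched), feature)
        block = block[block["sample"].isin(known_samples)]
        if len(block) < min_pairs:
            log.warning("concordance: skipping %s (%d paired samples < %d)",
                        feature, len(block), min_pairs)
            continue
        try:
            probe_ids = feature_probes.get_group(feature)
        except KeyError:
            log.warning("concordance: skipping %s (not in probe map)", feature)
            continue
        present = [p for p in probe_ids if p in array.values.index]
        if not present:
            log.warning("concordance: skipping %s (no probes in matrix)",
                        feature)
            continue
        mean_log2 = array.values.loc[present, block["sample"]].mean(axis=0)
        x = mean_log2.to_numpy(dtype=float)
        y = block["neg_delta_ct"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            log.warning("concordance: skipping %s (constant values)", feature)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((feature, len(block), float(r), float(p)))
    return pd.DataFrame(rows, columns=["feature", "n", "r", "p"])
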