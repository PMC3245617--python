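"""Model-specific miRNA signature discovery from per-array z-scores.

A miRNA probe is *model-specific* for a group when

* every sample of the group has z-score above a threshold (default 0.75),
  i.e. the miRNA is relatively highly expressed in all of the group's
  arrays, and
* the median z-score of the group exceeds the third-highest z-score among
  all pooled samples outside the group -- equivalently, no more than two
  outside samples are above the group median.

The decision boundary of that rule, the *margin*

    margin = median_z(group) - third_highest_z(outside samples),

serves as the permutation statistic: group labels are reassigned uniformly
at random (preserving group size), the permuted margins pooled across
probes give per-probe p-values, and a SAM-style permutation FDR compares
the mean permuted hit count above each margin cutoff with the observed
count.  Benjamini-Hochberg control is applied per group across features.
Running the rule with the normal-gland group finds normal-only miRNAs with
no code change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, samples_in_group
from .differential import bh_adjust, ttest_two_class
from .errors import GroupingError, ValidationError


@dataclass(frozen=True)
class SignatureThresholds:
    """Selection thresholds, defaulting to the published values."""
    z: float = 0.75
    p: float = 0.001
    perm_fdr: float = 0.01
    bh_q: float = 0.05


def _group_indices(zmatrix: ExpressionMatrix, sheet: pd.DataFrame, group: str):
    group_samples = samples_in_group(sheet, "model", group)
    if not group_samples:
        raise GroupingError(f"no samples in group {group!r}")
    in_group = np.array([s in set(group_samples) for s in zmatrix.sample_ids])
    missing = set(group_samples) - set(zmatrix.sample_ids)
    if missing:
        raise GroupingError(f"group samples missing from matrix: "
                            f"{sorted(missing)[:5]}")
    if in_group.sum() < 3:
        raise GroupingError(f"group {group!r} has {int(in_group.sum())} "
                            "samples; the rule needs >= 3")
    if (~in_group).sum() < 3:
        raise GroupingError("fewer than 3 samples outside the group; "
                            "the third-highest rule is ill-posed")
    return np.flatnonzero(in_group), np.flatnonzero(~in_group)


def _rule_arrays(Z, g_idx, o_idx, z_threshold, min_fraction=1.0):
    """(is_hit, margin, min_model_z, median_z) for every probe, vectorized."""
    group_vals = Z[:, g_idx]
    others = Z[:, o_idx]
    med = np.median(group_vals, axis=1)
    min_z = group_vals.min(axis=1)
    third = np.partition(others, others.shape[1] - 3, axis=1)[:, -3]
    margin = med - third
    if min_fraction >= 1.0:
        z_ok = min_z > z_threshold
    else:
        frac = (group_vals > z_threshold).mean(axis=1)
        z_ok = frac >= min_fraction
    return z_ok & (margin > 0), margin, min_z, med


def model_specific_rule(zmatrix: ExpressionMatrix, samples: pd.DataFrame,
                        group: str, z_threshold: float = 0.75,
                        min_fraction: float = 1.0) -> pd.DataFrame:
    """Evaluate the model-specific rule for one group.

    ``min_fraction`` relaxes the all-samples z condition to a fraction of
    group samples (1.0 = the strict published reading).  Returns a DataFrame
    indexed by probe with columns ``is_hit``, ``margin``, ``min_model_z``,
    ``median_z``.
    """
    if zmatrix.scale != "zscore":
        raise ValidationError("model_specific_rule expects a z-scored matrix")
    g_idx, o_idx = _group_indices(zmatrix, samples, group)
    Z = zmatrix.values.to_numpy(dtype=float)
    is_hit, margin, min_z, med = _rule_arrays(Z, g_idx, o_idx, z_threshold,
                                              min_fraction)
    return pd.DataFrame({"is_hit": is_hit, "margin": margin,
                         "min_model_z": min_z, "median_z": med},
                        index=zmatrix.values.index)


def signature_permutation(zmatrix: ExpressionMatrix, samples: pd.DataFrame,
                          group: str, margins=None, n_perm: int = 1999,
                          seed: int = 0, z_threshold: float = 0.75) -> pd.DataFrame:
    """Sample-label permutation p-values and FDR for the margin statistic.

    Group membership is reassigned uniformly at random ``n_perm`` times,
    preserving group size.  p-values use the pooled permuted-margin null
    with a pseudocount:

        p_i = (1 + #{permuted margins >= margin_i} / n_probes) / (n_perm + 1)

    The permutation FDR at a margin cutoff is the mean number of permuted
    rule hits at or above the cutoff divided by the observed hit count,
    capped at 1 and monotone in the margin.  Returns a DataFrame with
    columns ``margin``, ``perm_p``, ``perm_fdr`` (``perm_fdr`` is NaN for
    probes below every observed hit).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    g_idx, o_idx = _group_indices(zmatrix, samples, group)
    Z = zmatrix.values.to_numpy(dtype=float)
    k = g_idx.size
    n = Z.shape[1]
    n_probes = Z.shape[0]
    obs_hit, obs_margin, _, _ = _rule_arrays(Z, g_idx, o_idx, z_threshold)
    if margins is None:
        margins = obs_margin
    else:
        margins = np.asarray(margins, dtype=float)

    rng = np.random.default_rng(seed)
    all_idx = np.arange(n)
    perm_margins = np.empty((n_probes, n_perm))
    perm_hits = np.empty((n_probes, n_perm), dtype=bool)
    for b in range(n_perm):
        perm = rng.permutation(all_idx)
        hit_b, margin_b, _, _ = _rule_arrays(Z, perm[:k], perm[k:], z_threshold)
        perm_margins[:, b] = margin_b
        perm_hits[:, b] = hit_b

    pool = np.sort(perm_margins.ravel())
    count = pool.size - np.searchsorted(pool, margins, side="left")
    p = (1.0 + count / n_probes) / (n_perm + 1)
    p = np.minimum(p, 1.0)

    # permutation FDR at each probe's own margin cutoff
    hit_margin_pool = np.sort(perm_margins[perm_hits])
    mean_perm_hits = (hit_margin_pool.size
                      - np.searchsorted(hit_margin_pool, margins, side="left")
                      ) / n_perm
    obs_hit_margins = np.sort(obs_margin[obs_hit])
    obs_count = obs_hit_margins.size - np.searchsorted(obs_hit_margins,
                                                       margins, side="left")
    fdr = np.full(n_probes, np.nan)
    have = obs_count > 0
    fdr[have] = np.minimum(mean_perm_hits[have] / obs_count[have], 1.0)
    # monotone: minimal FDR over cutoffs at or below each probe's margin
    order = np.argsort(-margins, kind="stable")
    f = fdr[order]
    valid = ~np.isnan(f)
    if valid.any():
        f_filled = np.where(valid, f, np.inf)
        f_mono = np.minimum.accumulate(f_filled[::-1])[::-1]
        f = np.where(np.isinf(f_mono), np.nan, f_mono)
    out_fdr = np.empty(n_probes)
    out_fdr[order] = f
    return pd.DataFrame({"margin": margins, "perm_p": p, "perm_fdr": out_fdr},
                        index=zmatrix.values.index)


def assemble_signatures(zmatrix: ExpressionMatrix, samples: pd.DataFrame,
                        probes: pd.DataFrame,
                        thresholds: SignatureThresholds = SignatureThresholds(),
                        n_perm: int = 1999, seed: int = 0):
    """Run the rule + permutation machinery over every model group.

    A probe is selected for a group when it passes the raw rule, the
    permutation p threshold and the permutation FDR threshold; a feature
    is reported for a group when at least one of its probes is selected and
    its feature-level Benjamini-Hochberg q (per group, over the minimum
    probe p of every feature) passes.  Groups may legitimately yield zero
    hits.

    The default ``n_perm`` of 1999 makes the smallest attainable p-value
    (1/2000) strictly finer than the 0.001 selection threshold, so the
    threshold can actually distinguish probes.

    Returns ``(feature_table, probe_table)``; the feature table has columns
    (group, feature, n_probes, margin, p, perm_fdr, bh_q, ttest_p).
    """
    if zmatrix.scale != "zscore":
        raise ValidationError("assemble_signatures expects a z-scored matrix")
    feature_of = probes.set_index("probe")["feature"]
    groups = list(dict.fromkeys(samples["model"]))
    probe_rows, feature_rows = [], []
    for gi, group in enumerate(groups):
        rule = model_specific_rule(zmatrix, samples, group,
                                   z_threshold=thresholds.z)
        perm = signature_permutation(zmatrix, samples, group,
                                     margins=rule["margin"].to_numpy(),
                                     n_perm=n_perm, seed=seed + gi,
                                     z_threshold=thresholds.z)
        group_samples = samples_in_group(samples, "model", group)
        rest = [s for s in zmatrix.sample_ids if s not in set(group_samples)]
        tt = ttest_two_class(zmatrix, group_samples, rest)

        feats = feature_of.reindex(zmatrix.probe_ids).to_numpy()
        selected = (rule["is_hit"].to_numpy()
                    & (perm["perm_p"].to_numpy() <= thresholds.p)
                    & (np.nan_to_num(perm["perm_fdr"].to_numpy(), nan=1.0)
                       <= thresholds.perm_fdr))
        df = pd.DataFrame({
            "group": group,
            "probe": zmatrix.probe_ids,
            "feature": feats,
            "margin": rule["margin"].to_numpy(),
            "min_model_z": rule["min_model_z"].to_numpy(),
            "is_hit": rule["is_hit"].to_numpy(),
            "perm_p": perm["perm_p"].to_numpy(),
            "perm_fdr": perm["perm_fdr"].to_numpy(),
            "ttest_p": tt["ttest_p"].to_numpy(),
            "selected": selected,
        })
        probe_rows.append(df)

        # feature-level BH per group on each feature's best probe p
        feat_p = df.groupby("feature", sort=False)["perm_p"].min()
        feat_q = pd.Series(bh_adjust(feat_p.to_numpy()), index=feat_p.index)
        sel = df[df["selected"]]
        for feature, block in sel.groupby("feature", sort=False):
            q = float(feat_q[feature])
            if q > thresholds.bh_q:
                continue
            feature_rows.append({
                "group": group,
                "feature": feature,
                "n_probes": len(block),
                "margin": float(block["margin"].max()),
                "p": float(block["perm_p"].min()),
                "perm_fdr": float(block["perm_fdr"].min()),
                "bh_q": q,
                "ttest_p": float(block["ttest_p"].min()),
            })

    probe_table = pd.concat(probe_rows, ignore_index=True)
    feature_table = pd.DataFrame(
        feature_rows, columns=["group", "feature", "n_probes", "margin", "p",
                               "perm_fdr", "bh_q", "ttest_p"])
    return feature_table, probe_table
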