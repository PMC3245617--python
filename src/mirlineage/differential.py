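"""Two-class differential miRNA analysis.

The workhorse is a SAM-style moderated statistic

    d_i = (mean1_i - mean2_i) / (s_i + s0)

where ``s_i`` is the pooled two-sample standard error of probe ``i`` and
``s0`` is a fudge constant (default: the median of the ``s_i``) that keeps
low-variance probes from dominating the ranking.  Significance comes from
class-label permutations with the permuted statistics pooled across probes
(the standard SAM null), and the per-probe false discovery rate is the
SAM-style median number of permuted exceedances divided by the observed
count, made monotone in |d|.  Plain equal-variance t-tests, linear-scale
fold changes and Benjamini-Hochberg adjustment round out the reported
columns.
"""

from __future__ import annotations

import logging
from math import comb
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import GroupingError, ValidationError

log = logging.getLogger(__name__)


def _class_arrays(matrix: ExpressionMatrix, class1, class2,
                  min_per_class: int = 2):
    class1, class2 = list(class1), list(class2)
    overlap = set(class1) & set(class2)
    if overlap:
        raise GroupingError(f"classes overlap: {sorted(overlap)[:5]}")
    known = set(matrix.sample_ids)
    unknown = [s for s in class1 + class2 if s not in known]
    if unknown:
        raise GroupingError(f"unknown sample ids: {unknown[:5]}")
    if len(class1) < min_per_class or len(class2) < min_per_class:
        raise GroupingError(
            f"each class needs >= {min_per_class} samples "
            f"(got {len(class1)} and {len(class2)})")
    x1 = matrix.values[class1].to_numpy(dtype=float)
    x2 = matrix.values[class2].to_numpy(dtype=float)
    return x1, x2


def _pooled_se(x1, x2):
    """Pooled two-sample standard error per probe (equal-variance form)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = (ss1 + ss2) / (n1 + n2 - 2)
    return np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))


def sam_statistic(matrix: ExpressionMatrix, class1, class2, s0="auto"):
    """Per-probe SAM d statistic and pooled standard error.

    Returns a DataFrame with columns ``d`` and ``s`` (indexed by probe) and
    the resolved value of ``s0``.  ``s0="auto"`` uses the median of the
    per-probe standard errors; ``s0=0`` makes ``d`` the equal-variance
    two-sample t statistic.
    """
    x1, x2 = _class_arrays(matrix, class1, class2)
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    s = _pooled_se(x1, x2)
    if s0 == "auto":
        s0_val = float(np.median(s))
    else:
        s0_val = float(s0)
        if s0_val < 0:
            raise ValidationError("s0 must be nonnegative")
    denom = s + s0_val
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(diff == 0, 0.0, diff / denom)
    out = pd.DataFrame({"d": d, "s": s}, index=matrix.values.index)
    return out, s0_val


def _permutation_indicators(n, n1, n_perm, rng):
    """0/1 matrix (n_perm x n): which columns play class 1 per permutation.

    Falls back to exhaustive enumeration (with a logged warning) when fewer
    than ``n_perm`` distinct label assignments exist.
    """
    n_distinct = comb(n, n1)
    if n_distinct <= n_perm:
        log.warning("only %d distinct label permutations (< %d requested); "
                    "using exhaustive enumeration", n_distinct, n_perm)
        P = np.zeros((n_distinct, n), dtype=float)
        for b, cols in enumerate(combinations(range(n), n1)):
            P[b, list(cols)] = 1.0
        return P, True
    P = np.zeros((n_perm, n), dtype=float)
    for b in range(n_perm):
        P[b, rng.permutation(n)[:n1]] = 1.0
    return P, False


def _permuted_d(X, P1, s0):
    """|d*| for every (probe, permutation); X is probes x (n1+n2)."""
    n = X.shape[1]
    n1 = int(P1[0].sum())
    n2 = n - n1
    Xsq = X ** 2
    T1 = X @ P1.T                      # per-perm class-1 sums
    T2 = X.sum(axis=1, keepdims=True) - T1
    M1, M2 = T1 / n1, T2 / n2
    SS1 = Xsq @ P1.T - n1 * M1 ** 2
    SS2 = Xsq.sum(axis=1, keepdims=True) - Xsq @ P1.T - n2 * M2 ** 2
    pooled_var = (SS1 + SS2) / (n1 + n2 - 2)
    pooled_var = np.clip(pooled_var, 0.0, None)   # guard fp negatives
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    diff = M1 - M2
    with np.errstate(divide="ignore", invalid="ignore"):
        dstar = np.where(diff == 0, 0.0, diff / (se + s0))
    return np.abs(dstar)


def sam_permutation(matrix: ExpressionMatrix, class1, class2,
                    n_perm: int = 999, seed: int = 0, s0="auto", d=None):
    """Permutation p-values and SAM-style q-values for the d statistic.

    Class labels are permuted ``n_perm`` times and the permuted |d*| pooled
    across probes.  The p-value uses a pseudocount so it is never zero:

        p_i = (1 + #{pooled |d*| >= |d_i|} / n_probes) / (n_perm + 1)

    (in exhaustive-enumeration mode the identity relabeling is part of the
    null, so p_i = #{|d*| >= |d_i|} / (n_probes * n_perms) without a
    pseudocount and equals the exact permutation p).  The q-value at probe i
    is the median over permutations of the per-permutation count of
    |d*| >= |d_i|, divided by the observed count of |d| >= |d_i|, capped at
    1 and made monotone in |d| (suffix minimum over lower thresholds).

    Returns a DataFrame with columns ``d``, ``perm_p``, ``perm_q``.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if d is None or s0 == "auto":
        d_df, s0_val = sam_statistic(matrix, class1, class2, s0=s0)
        if d is None:
            d = d_df["d"].to_numpy()
        else:
            d = np.asarray(d, dtype=float)
    else:
        d = np.asarray(d, dtype=float)
        s0_val = float(s0)
    class1, class2 = list(class1), list(class2)
    X = matrix.values[class1 + class2].to_numpy(dtype=float)
    n_probes = X.shape[0]
    rng = np.random.default_rng(seed)
    P1, exhaustive = _permutation_indicators(X.shape[1], len(class1),
                                             n_perm, rng)
    abs_dstar = _permuted_d(X, P1, s0_val)        # probes x n_perms
    n_perms_done = abs_dstar.shape[1]
    absd = np.abs(d)

    # exceedances counted as |d*| >= |d_i| up to fp noise: the observed and
    # permuted statistics come from different (algebraically equal)
    # computation paths, so exact ties differ by ~1e-16
    thresholds = absd - 1e-9 * np.maximum(1.0, absd)
    pool = np.sort(abs_dstar.ravel())
    pooled_count = pool.size - np.searchsorted(pool, thresholds, side="left")
    if exhaustive:
        p = pooled_count / (n_probes * n_perms_done)
    else:
        p = (1.0 + pooled_count / n_probes) / (n_perms_done + 1)
    p = np.minimum(p, 1.0)

    # per-permutation exceedance counts -> median-FDR q-values
    V = np.empty((n_probes, n_perms_done))
    for b in range(n_perms_done):
        col = np.sort(abs_dstar[:, b])
        V[:, b] = n_probes - np.searchsorted(col, thresholds, side="left")
    med_v = np.median(V, axis=1)
    order = np.argsort(-absd, kind="stable")
    R = np.empty(n_probes)
    sorted_absd = absd[order]
    R[order] = np.searchsorted(-sorted_absd, -absd[order], side="right")
    fdr = np.minimum(med_v / R, 1.0)
    # q_i = minimal FDR over thresholds at or below |d_i|
    q = np.empty(n_probes)
    q[order] = np.minimum.accumulate(fdr[order][::-1])[::-1]

    return pd.DataFrame({"d": d, "perm_p": p, "perm_q": q},
                        index=matrix.values.index)


def ttest_two_class(matrix: ExpressionMatrix, class1, class2) -> pd.DataFrame:
    """Equal-variance two-sample t-test per probe (two-sided).

    A probe whose two classes are identical gets t = 0, p = 1; a probe with
    zero pooled variance but unequal means has no defined p and is flagged
    in the ``undefined`` column.
    """
    x1, x2 = _class_arrays(matrix, class1, class2)
    n1, n2 = x1.shape[1], x2.shape[1]
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    se = _pooled_se(x1, x2)
    df = n1 + n2 - 2
    t = np.zeros_like(diff)
    p = np.ones_like(diff)
    undefined = np.zeros(diff.shape, dtype=bool)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    degenerate = (~ok) & (diff != 0)
    t[degenerate] = np.where(diff[degenerate] > 0, np.inf, -np.inf)
    p[degenerate] = np.nan
    undefined[degenerate] = True
    return pd.DataFrame({"t": t, "ttest_p": p, "undefined": undefined},
                        index=matrix.values.index)


def fold_change(matrix: ExpressionMatrix, class1, class2) -> pd.DataFrame:
    """Linear-scale fold change between class means of a log2 matrix.

    Reported as the larger-mean / smaller-mean ratio (>= 1) with a
    ``direction`` flag naming the higher class.
    """
    if matrix.scale != "log2":
        raise ValidationError("fold_change expects a log2-scale matrix")
    x1, x2 = _class_arrays(matrix, class1, class2)
    log_diff = x1.mean(axis=1) - x2.mean(axis=1)
    fc = np.exp2(np.abs(log_diff))
    direction = np.where(log_diff >= 0, "up-in-class1", "up-in-class2")
    return pd.DataFrame({"fold_change": fc, "direction": direction},
                        index=matrix.values.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_analysis(matrix: ExpressionMatrix, probes: pd.DataFrame,
                          class1, class2, n_perm: int = 999, seed: int = 0,
                          s0="auto") -> pd.DataFrame:
    """Complete two-class analysis table, one row per probe.

    Columns: probe, feature, d, s, t, ttest_p, ttest_q, perm_p, perm_q,
    fold_change, direction.
    """
    d_df, s0_val = sam_statistic(matrix, class1, class2, s0=s0)
    perm = sam_permutation(matrix, class1, class2, n_perm=n_perm, seed=seed,
                           s0=s0_val, d=d_df["d"].to_numpy())
    tt = ttest_two_class(matrix, class1, class2)
    fc = fold_change(matrix, class1, class2)
    feature_of = probes.set_index("probe")["feature"]
    out = pd.DataFrame({
        "probe": matrix.probe_ids,
        "feature": feature_of.reindex(matrix.probe_ids).to_numpy(),
        "d": d_df["d"].to_numpy(),
        "s": d_df["s"].to_numpy(),
        "t": tt["t"].to_numpy(),
        "ttest_p": tt["ttest_p"].to_numpy(),
        "perm_p": perm["perm_p"].to_numpy(),
        "perm_q": perm["perm_q"].to_numpy(),
        "fold_change": fc["fold_change"].to_numpy(),
        "direction": fc["direction"].to_numpy(),
    })
    valid = ~tt["undefined"].to_numpy()
    ttest_q = np.full(len(out), np.nan)
    if valid.any():
        ttest_q[valid] = bh_adjust(out.loc[valid, "ttest_p"].to_numpy())
    out.insert(6, "ttest_q", ttest_q)
    return out


def select_differential(results: pd.DataFrame, p_max: float = 0.01,
                        q_max: float = 0.0):
    """Apply the permutation p / FDR cutoffs and roll probes up to features.

    Returns ``(probe_hits, feature_hits)`` where ``feature_hits`` reports
    each feature called by at least one probe, with its probe count, best
    p/q and the direction of change (the "N miRNAs (M probes)" style of
    reporting).
    """
    hits = results[(results["perm_p"] <= p_max)
                   & (results["perm_q"] <= q_max)].copy()
    if hits.empty:
        feature_hits = pd.DataFrame(columns=["feature", "n_probes", "best_p",
                                             "best_q", "direction"])
        return hits, feature_hits
    grouped = hits.groupby("feature", sort=False)
    feature_hits = pd.DataFrame({
        "feature": list(grouped.groups),
        "n_probes": grouped.size().to_numpy(),
        "best_p": grouped["perm_p"].min().to_numpy(),
        "best_q": grouped["perm_q"].min().to_numpy(),
        "direction": grouped["direction"].agg(
            lambda s: s.mode().iloc[0]).to_numpy(),
    })
    return hits.reset_index(drop=True), feature_hits
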