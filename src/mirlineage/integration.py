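"""miRNA-mRNA inverse-correlation target analysis.

For each miRNA probe, Pearson correlations against every mRNA probe are
screened for significant negative correlation (r < 0 and two-sided
correlation p <= 0.001 from the t transform).  Genes are the units of the
enrichment test: a gene counts as negatively correlated when at least one
of its probes passes the screen, as a predicted target when it appears in
the in-silico target table of the miRNA.  A 2x2 contingency table over all
screened genes

                      target   not target
    negative             a         b
    not negative         c         d

is tested one-sided for enrichment of negative correlations among targets
(Fisher's exact test = hypergeometric tail).  Candidate targets are the
negatively correlated predicted targets; the *consensus* target set of a
miRNA is the intersection of candidate sets across its replicate probes.
A two-sample Kolmogorov-Smirnov comparison of the correlation-coefficient
distributions (targets vs all mRNAs) provides the left-shift diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import GroupingError, InsufficientOverlapError, ValidationError

log = logging.getLogger(__name__)


def match_samples(mirna: ExpressionMatrix, mrna: ExpressionMatrix,
                  min_common: int = 5):
    """Restrict both matrices to their common samples, identically ordered."""
    common = [s for s in mirna.sample_ids if s in set(mrna.sample_ids)]
    if len(common) < min_common:
        raise InsufficientOverlapError(
            f"only {len(common)} samples shared between platforms "
            f"(need >= {min_common})")
    return mirna.subset_samples(common), mrna.subset_samples(common)


def pearson_screen(mirna_probe, mrna: ExpressionMatrix,
                   p_max: float = 0.001) -> pd.DataFrame:
    """Correlate one miRNA probe vector against every mRNA probe.

    ``mirna_probe`` is a pandas Series indexed by the same samples as
    ``mrna``.  p-values come from ``t = r * sqrt((n-2) / (1-r^2))`` with
    n-2 degrees of freedom, two-sided.  Constant mRNA probes have no
    defined correlation; they are excluded (``excluded`` column) and belong
    to neither margin of any downstream table.  Returns a DataFrame indexed
    by mRNA probe with columns ``r``, ``p``, ``is_negative``, ``excluded``.
    """
    x = np.asarray(mirna_probe, dtype=float)
    n = x.size
    if n < 5:
        raise ValidationError("pearson_screen needs >= 5 paired samples")
    if list(getattr(mirna_probe, "index", mrna.sample_ids)) != mrna.sample_ids:
        raise ValidationError("miRNA probe vector and mRNA matrix must share "
                              "sample ids in identical order")
    if x.std() == 0:
        raise ValidationError("miRNA probe vector is constant")
    Y = mrna.values.to_numpy(dtype=float)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    y_ss = (Yc ** 2).sum(axis=1)
    excluded = y_ss == 0
    denom = np.sqrt((xc ** 2).sum() * y_ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc @ xc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isnan(t)] = 0.0               # |r| == 1 -> p limit 0
    p[np.abs(r) == 1.0] = 0.0
    r[excluded] = np.nan
    p[excluded] = np.nan
    is_negative = (~excluded) & (r < 0) & (p <= p_max)
    if excluded.any():
        log.warning("pearson_screen: %d constant mRNA probes excluded",
                    int(excluded.sum()))
    return pd.DataFrame({"r": r, "p": p, "is_negative": is_negative,
                         "excluded": excluded}, index=mrna.values.index)


@dataclass
class EnrichmentResult:
    """Per-miRNA-probe enrichment of negative correlations among targets."""
    mirna_probe: str
    mirna_feature: str
    a: int                 # negative & target
    b: int                 # negative & not target
    c: int                 # not negative & target
    d: int                 # not negative & not target
    fisher_p: float
    significant: bool
    candidate_genes: frozenset = field(default_factory=frozenset)
    n_predicted: int = 0
    shift_d: float = float("nan")
    shift_p: float = float("nan")


def fisher_enrichment(screen: pd.DataFrame, targets, gene_map: pd.Series,
                      alpha: float = 0.05, alternative: str = "greater"):
    """Gene-level 2x2 enrichment test of one miRNA probe's screen.

    ``targets`` is the predicted gene set of the miRNA; ``gene_map`` maps
    mRNA probe id -> gene id.  Returns (a, b, c, d, fisher_p, significant,
    candidate_genes).  The one-sided p is the upper hypergeometric tail
    (probability of >= a negative targets given the margins).
    """
    usable = screen[~screen["excluded"]]
    if usable.empty:
        raise ValidationError("screen has no usable mRNA probes")
    genes = gene_map.reindex(usable.index)
    neg_by_gene = usable["is_negative"].groupby(genes).any()
    all_genes = set(neg_by_gene.index)
    targets = set(targets) & all_genes
    if not targets:
        raise ValidationError("no predicted target genes present on the array")
    neg_genes = set(neg_by_gene.index[neg_by_gene])
    a = len(neg_genes & targets)
    b = len(neg_genes - targets)
    c = len(targets - neg_genes)
    d = len(all_genes) - a - b - c
    if alternative == "greater":
        # P(X >= a), X ~ Hypergeom(N genes, K targets, n negative)
        p = float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
    elif alternative == "two-sided":
        p = float(stats.fisher_exact([[a, b], [c, d]],
                                     alternative="two-sided")[1])
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)
    candidates = frozenset(neg_genes & targets)
    return a, b, c, d, p, p < alpha, candidates


def consensus_targets(results) -> set:
    """Intersect candidate target sets across the replicate probes of a miRNA."""
    results = list(results)
    if not results:
        raise ValidationError("consensus_targets needs >= 1 probe result")
    sets = [set(r.candidate_genes) for r in results]
    consensus = set.intersection(*sets)
    return consensus


def correlation_shift(all_r, target_r):
    """Two-sample KS comparison of correlation distributions.

    Returns ``(D, p, curve)`` where ``curve`` is a long-format ECDF table
    (columns ``which``, ``r``, ``ecdf``) for plotting.  A *left shift* --
    the enrichment diagnostic -- is declared by :func:`declare_left_shift`
    when the target mean correlation is below the global mean AND the KS
    test rejects at 0.05.
    """
    all_r = np.asarray(all_r, dtype=float)
    target_r = np.asarray(target_r, dtype=float)
    if all_r.size == 0 or target_r.size == 0:
        raise ValidationError("correlation vectors must be non-empty")
    ks = stats.ks_2samp(target_r, all_r, method="asymp")
    rows = []
    for which, vec in (("all", all_r), ("targets", target_r)):
        xs = np.sort(vec)
        ecdf = np.arange(1, xs.size + 1) / xs.size
        rows.append(pd.DataFrame({"which": which, "r": xs, "ecdf": ecdf}))
    return float(ks.statistic), float(ks.pvalue), pd.concat(rows,
                                                            ignore_index=True)


def declare_left_shift(all_r, target_r, alpha: float = 0.05) -> bool:
    """Left shift requires both a lower target mean and KS p < alpha."""
    d, p, _ = correlation_shift(all_r, target_r)
    return bool(np.mean(target_r) < np.mean(all_r) and p < alpha)


def integrate_all(mirna: ExpressionMatrix, mrna: ExpressionMatrix,
                  probes: pd.DataFrame, targets: pd.DataFrame,
                  mirna_subset, p_max: float = 0.001,
                  fisher_alpha: float = 0.05):
    """Screen + enrichment for every probe of the given miRNAs.

    ``mirna_subset`` is a non-empty list of miRNA feature ids (typically the
    signature or differential miRNAs).  Returns ``(enrichment_table,
    consensus_table)``; per-miRNA degenerate cases (no mapped targets,
    constant probes) are skipped with a logged warning, never aborting the
    batch.  The enrichment table reports, per probe, the 2x2 cells, the
    one-sided Fisher p, the "k of K predicted targets inversely correlated"
    counts and the KS left-shift statistics; it is sorted by Fisher p.
    """
    mirna_subset = list(mirna_subset)
    if not mirna_subset:
        raise ValidationError("mirna_subset must be non-empty")
    mirna_m, mrna_m = match_samples(mirna, mrna)
    pmap = probes.set_index("probe")
    gene_map = pmap.loc[pmap["kind"] == "mRNA", "feature"]
    gene_map = gene_map.reindex(mrna_m.values.index).dropna()
    targets_by_mirna = {m: set(t["gene"]) for m, t in targets.groupby("mirna")}

    mirna_probes = probes[(probes["kind"] == "miRNA")
                          & probes["feature"].isin(mirna_subset)]
    enrich_rows, consensus_rows = [], []
    for feature, block in mirna_probes.groupby("feature", sort=False):
        predicted = targets_by_mirna.get(feature, set())
        results = []
        for probe_id in block["probe"]:
            if probe_id not in mirna_m.values.index:
                continue                      # filtered out upstream
            vec = mirna_m.values.loc[probe_id]
            try:
                screen = pearson_screen(vec, mrna_m, p_max=p_max)
                a, b, c, d, p, sig, cands = fisher_enrichment(
                    screen, predicted, gene_map, alpha=fisher_alpha)
            except ValidationError as exc:
                log.warning("integrate_all: skipping %s (%s)", probe_id, exc)
                continue
            # left-shift diagnostic on gene-level best (most negative) r
            usable = screen[~screen["excluded"]]
            gene_r = usable["r"].groupby(
                gene_map.reindex(usable.index)).min()
            target_r = gene_r[gene_r.index.isin(predicted)]
            shift_d, shift_p, _ = correlation_shift(gene_r.to_numpy(),
                                                    target_r.to_numpy())
            results.append(EnrichmentResult(
                mirna_probe=probe_id, mirna_feature=feature,
                a=a, b=b, c=c, d=d, fisher_p=p, significant=sig,
                candidate_genes=cands, n_predicted=a + c,
                shift_d=shift_d, shift_p=shift_p))
        if not results:
            log.warning("integrate_all: no usable probes for %s", feature)
            continue
        for r in results:
            enrich_rows.append({
                "mirna": r.mirna_feature, "probe": r.mirna_probe,
                "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "fisher_p": r.fisher_p, "significant": r.significant,
                "n_candidates": len(r.candidate_genes),
                "n_predicted": r.n_predicted,
                "shift_d": r.shift_d, "shift_p": r.shift_p,
            })
        consensus = sorted(consensus_targets(results))
        consensus_rows.append({
            "mirna": feature,
            "n_probes": len(results),
            "n_consensus": len(consensus),
            "consensus_genes": ";".join(consensus),
        })

    enrichment = pd.DataFrame(
        enrich_rows, columns=["mirna", "probe", "a", "b", "c", "d", "fisher_p",
                              "significant", "n_candidates", "n_predicted",
                              "shift_d", "shift_p"])
    enrichment = enrichment.sort_values("fisher_p", kind="stable",
                                        ignore_index=True)
    consensus_table = pd.DataFrame(
        consensus_rows, columns=["mirna", "n_probes", "n_consensus",
                                 "consensus_genes"])
    return enrichment, consensus_table
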