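"""End-to-end pipeline: normalize -> filter -> z-score -> differential /
signatures -> integration -> clustering, with every stage's result written
as a tab-delimited table under one output directory.

Stages are independently re-runnable: each reads its inputs from the output
directory if an earlier stage is not being recomputed, so e.g. the
signature stage can be repeated from a cached z-score matrix and produce a
byte-identical table.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import io
from .cluster import cluster_export
from .containers import ExpressionMatrix, samples_in_group
from .differential import differential_analysis, select_differential
from .errors import ConfigurationError
from .integration import integrate_all
from .preprocess import detection_filter, preprocess_mirna
from .signatures import SignatureThresholds, assemble_signatures
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger(__name__)

ALL_STAGES = ("inputs", "preprocess", "differential", "signatures",
              "integrate", "cluster")


@dataclass
class PipelineConfig:
    """Paths, thresholds and run parameters for :func:`run_pipeline`.

    All numeric thresholds default to the published analysis values.  When
    ``simulate`` is true the input tables are generated (and written) from
    ``sim`` instead of being read from the ``*_path`` fields.
    """

    out_dir: str = "mirlineage_out"
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    mirna_values_path: str | None = None
    mirna_calls_path: str | None = None
    mrna_values_path: str | None = None
    mrna_calls_path: str | None = None
    sample_sheet_path: str | None = None
    probe_map_path: str | None = None
    targets_path: str | None = None

    z_threshold: float = 0.75
    signature_p: float = 0.001
    signature_perm_fdr: float = 0.01
    signature_bh_q: float = 0.05
    sam_p: float = 0.01
    sam_fdr: float = 0.0
    correlation_p: float = 0.001
    fisher_alpha: float = 0.05
    min_present: int = 3
    n_perm: int = 999
    signature_n_perm: int = 1999
    seed: int = 0

    def validate(self) -> None:
        for name in ("signature_p", "signature_bh_q", "sam_p",
                     "correlation_p", "fisher_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        for name in ("signature_perm_fdr", "sam_fdr"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_perm < 100 or self.signature_n_perm < 100:
            raise ConfigurationError("permutation counts must be >= 100")
        if not self.simulate:
            required = ("mirna_values_path", "mirna_calls_path",
                        "mrna_values_path", "sample_sheet_path",
                        "probe_map_path", "targets_path")
            missing = [n for n in required if getattr(self, n) is None]
            if missing:
                raise ConfigurationError(
                    f"simulate=False requires input paths: {missing}")


def _setup_run_log(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mirlineage")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig, stages=None) -> Path:
    """Run the requested stages; returns the output directory path.

    ``stages`` defaults to all of ``inputs, preprocess, differential,
    signatures, integrate, cluster``; a stage that is skipped is replaced by
    reading its previous output from ``out_dir``.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    stages = tuple(stages) if stages is not None else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(out)
    try:
        log.info("config: %s", json.dumps(_config_echo(config), sort_keys=True))
        log.info("python %s, pandas %s", sys.version.split()[0], pd.__version__)

        # -- inputs ---------------------------------------------------------
        if "inputs" in stages:
            if config.simulate:
                sim = replace(config.sim, seed=config.seed)
                mirna, mrna, sheet, pmap, targets, truth = simulate_dataset(sim)
                io.write_ground_truth(truth, out / "ground_truth.tsv")
            else:
                mirna = io.read_matrix(config.mirna_values_path,
                                       config.mirna_calls_path)
                mrna = io.read_matrix(config.mrna_values_path,
                                      config.mrna_calls_path)
                sheet = io.read_sample_sheet(config.sample_sheet_path)
                pmap = io.read_probe_map(config.probe_map_path)
                targets = io.read_target_table(config.targets_path)
            io.write_matrix(mirna, out / "mirna_values.tsv",
                            out / "mirna_calls.tsv")
            io.write_matrix(mrna, out / "mrna_values.tsv",
                            out / "mrna_calls.tsv")
            io.write_sample_sheet(sheet, out / "sample_sheet.tsv")
            io.write_probe_map(pmap, out / "probe_map.tsv")
            io.write_target_table(targets, out / "targets.tsv")
        else:
            mirna = io.read_matrix(out / "mirna_values.tsv",
                                   out / "mirna_calls.tsv")
            mrna = io.read_matrix(out / "mrna_values.tsv",
                                  out / "mrna_calls.tsv")
            sheet = io.read_sample_sheet(out / "sample_sheet.tsv")
            pmap = io.read_probe_map(out / "probe_map.tsv")
            targets = io.read_target_table(out / "targets.tsv")
        log.info("inputs: %d miRNA probes x %d samples; %d mRNA probes x %d",
                 mirna.n_probes, mirna.n_samples, mrna.n_probes, mrna.n_samples)

        # -- preprocess -----------------------------------------------------
        if "preprocess" in stages:
            normalized, zmatrix = preprocess_mirna(
                mirna, pmap, min_present=config.min_present)
            mrna_filtered = detection_filter(mrna,
                                             min_present=config.min_present)
            io.write_matrix(normalized, out / "mirna_normalized.tsv",
                            out / "mirna_normalized_calls.tsv")
            io.write_matrix(zmatrix, out / "mirna_zscores.tsv",
                            out / "mirna_zscores_calls.tsv")
            io.write_matrix(mrna_filtered, out / "mrna_filtered.tsv",
                            out / "mrna_filtered_calls.tsv")
        else:
            normalized = io.read_matrix(out / "mirna_normalized.tsv",
                                        out / "mirna_normalized_calls.tsv")
            zmatrix = io.read_matrix(out / "mirna_zscores.tsv",
                                     out / "mirna_zscores_calls.tsv",
                                     scale="zscore")
            mrna_filtered = io.read_matrix(out / "mrna_filtered.tsv",
                                           out / "mrna_filtered_calls.tsv")
        log.info("preprocess: %d probes retained", normalized.n_probes)

        # -- differential (basal vs luminal tumors, normals excluded) -------
        basal = [s for s in normalized.sample_ids
                 if s in set(samples_in_group(sheet, "subtype", "basal"))]
        luminal = [s for s in normalized.sample_ids
                   if s in set(samples_in_group(sheet, "subtype", "luminal"))]
        if "differential" in stages:
            diff = differential_analysis(normalized, pmap, basal, luminal,
                                         n_perm=config.n_perm,
                                         seed=config.seed)
            probe_hits, feature_hits = select_differential(
                diff, p_max=config.sam_p, q_max=config.sam_fdr)
            io.write_table(diff, out / "differential_probes.tsv")
            io.write_table(probe_hits, out / "differential_hits.tsv")
            io.write_table(feature_hits, out / "differential_features.tsv")
        else:
            diff = pd.read_csv(out / "differential_probes.tsv", sep="\t")
            feature_hits = pd.read_csv(out / "differential_features.tsv",
                                       sep="\t")
        log.info("differential: %d features called (%d probes at p<=%g, "
                 "q<=%g)", len(feature_hits),
                 int(feature_hits["n_probes"].sum()) if len(feature_hits) else 0,
                 config.sam_p, config.sam_fdr)

        # -- signatures -----------------------------------------------------
        thresholds = SignatureThresholds(
            z=config.z_threshold, p=config.signature_p,
            perm_fdr=config.signature_perm_fdr, bh_q=config.signature_bh_q)
        if "signatures" in stages:
            sig_features, sig_probes = assemble_signatures(
                zmatrix, sheet, pmap, thresholds=thresholds,
                n_perm=config.signature_n_perm, seed=config.seed)
            io.write_table(sig_features, out / "signature_features.tsv")
            io.write_table(sig_probes, out / "signature_probes.tsv")
        else:
            sig_features = pd.read_csv(out / "signature_features.tsv", sep="\t")
        log.info("signatures: %d (feature, group) hits", len(sig_features))

        # -- integration ----------------------------------------------------
        if "integrate" in stages:
            interest = list(dict.fromkeys(
                list(sig_features["feature"]) + list(feature_hits["feature"])))
            interest = [f for f in interest
                        if f in set(targets["mirna"])]
            if interest:
                enrichment, consensus = integrate_all(
                    normalized, mrna_filtered, pmap, targets, interest,
                    p_max=config.correlation_p,
                    fisher_alpha=config.fisher_alpha)
            else:
                log.warning("integration: no selected miRNA has predicted "
                            "targets; emitting empty tables")
                enrichment = pd.DataFrame(columns=[
                    "mirna", "probe", "a", "b", "c", "d", "fisher_p",
                    "significant", "n_candidates", "n_predicted",
                    "shift_d", "shift_p"])
                consensus = pd.DataFrame(columns=[
                    "mirna", "n_probes", "n_consensus", "consensus_genes"])
            io.write_table(enrichment, out / "enrichment.tsv")
            io.write_table(consensus, out / "consensus_targets.tsv")
            log.info("integration: %d probe tests, %d significant",
                     len(enrichment), int(enrichment["significant"].sum())
                     if len(enrichment) else 0)

        # -- clustering -----------------------------------------------------
        if "cluster" in stages:
            clust = cluster_export(zmatrix)
            (out / "sample_tree.nwk").write_text(clust["sample_tree"] + "\n")
            io.write_matrix(ExpressionMatrix(
                values=clust["ordered"].values, scale="zscore"),
                out / "clustered_zscores.tsv")
            log.info("cluster: %d samples ordered",
                     clust["ordered"].n_samples)
    finally:
        logging.getLogger("mirlineage").removeHandler(handler)
        handler.close()
    return out


def _config_echo(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["sim"] = {k: list(v) if isinstance(v, tuple) else v
                for k, v in d["sim"].items()}
    return d
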