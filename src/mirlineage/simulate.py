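"""Synthetic miRNA/mRNA expression datasets with planted, recoverable effects.

The generator emulates the structure of a two-platform mouse mammary tumor
study: eight genetically engineered tumor models plus normal pregnant
mammary glands (nine groups of 4-7 arrays), a custom miRNA array carrying
four replicate probes per mature miRNA, and an accompanying mRNA array with
1-3 probes per gene.  Effects are planted additively on the log2 scale:

``log2 intensity = feature baseline + probe offset + array effect
                   + planted delta + noise``

Three kinds of effect are planted and recorded in a :class:`GroundTruth`:

* *model-specific* miRNAs -- up-shifted by ``model_specific_delta`` in the
  arrays of one group only.  These emulate abundant, model-restricted
  species, so their baselines are drawn from the upper intensity range
  (``model_specific_baseline_range``): a miRNA expressed near the array
  noise floor cannot stand out on the per-array z-score scale no matter how
  specific its regulation, and the phenomenon being modeled is high
  expression in one model.
* *subtype-differential* miRNAs -- up-shifted in all basal (or all luminal)
  tumor arrays; normal-gland arrays are left at baseline.
* *regulated miRNA -> gene pairs* -- each regulated gene's log2 expression
  is ``baseline + regulation_slope * z`` where ``z`` is the standardized
  latent abundance of its regulator miRNA, plus noise.  The predicted-target
  table dilutes these true targets among many decoy genes drawn
  independently of any expression, emulating in-silico prediction false
  positives.

Detection calls are generated rather than derived from intensities (the
analysis consumes MAS5-style flags produced upstream): a configurable
fraction of probes is 'A' (absent) in all but at most two arrays, which is
exactly the class of probe the detection filter removes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroundTruth
from .errors import ConfigurationError, FeatureLookupError

# default design: Table-1-style groups (3 basal models, 5 luminal, 1 normal)
DEFAULT_GROUPS = ("C31Tag", "p53null", "BRCA1p53",
                  "HRas", "Her2neu", "cMyc", "PymT", "Wnt1", "normal")
DEFAULT_SUBTYPES = ("basal", "basal", "basal",
                    "luminal", "luminal", "luminal", "luminal", "luminal",
                    "normal")
DEFAULT_STRAINS = ("FVB", "BalbC", "129B6FVB",
                   "FVB", "FVB", "FVB", "FVB", "FVB", "FVB")
DEFAULT_SAMPLES_PER_GROUP = (5, 7, 5, 5, 5, 5, 6, 4, 5)

# affine map from mean log2 array intensity to qPCR -dCt; the positive slope
# makes array/qPCR concordance positive by construction
QPCR_INTERCEPT = -12.0
QPCR_SLOPE = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model (all effects in log2 units)."""

    group_names: tuple = DEFAULT_GROUPS
    group_subtypes: tuple = DEFAULT_SUBTYPES
    group_strains: tuple = DEFAULT_STRAINS
    samples_per_group: tuple = DEFAULT_SAMPLES_PER_GROUP
    n_mirnas: int = 334
    probes_per_mirna: int = 4
    n_genes: int = 2000
    probes_per_gene: tuple = (1, 3)          # inclusive range
    baseline_mean_range: tuple = (6.0, 12.0)
    model_specific_baseline_range: tuple = (9.5, 11.5)
    probe_offset_sd: float = 0.1
    probe_noise_sd: float = 0.3
    sample_effect_sd: float = 0.2
    model_specific_delta: float = 2.0
    subtype_delta: float = 2.0
    regulation_slope: float = -0.8
    regulation_noise_sd: float = 0.5
    n_model_specific: int = 5
    n_subtype_mirnas: int = 10
    n_regulated_mirnas: int = 6
    n_decoy_only_mirnas: int = 6
    true_targets_per_mirna: int = 20
    decoy_targets_per_mirna: int = 130
    fraction_absent_probes: float = 0.05
    mrna_missing_samples: int = 2
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def validate(self) -> None:
        def bad(msg):
            raise ConfigurationError(msg)

        if not (len(self.group_subtypes) == len(self.group_strains)
                == len(self.samples_per_group) == self.n_groups):
            bad("group_names, group_subtypes, group_strains and "
                "samples_per_group must have equal length")
        for name, val in (("n_mirnas", self.n_mirnas),
                          ("probes_per_mirna", self.probes_per_mirna),
                          ("n_genes", self.n_genes)):
            if val < 1:
                bad(f"{name} must be positive, got {val}")
        if any(n < 1 for n in self.samples_per_group):
            bad("samples_per_group entries must be positive")
        if not 0 <= self.fraction_absent_probes < 1:
            bad("fraction_absent_probes must lie in [0, 1)")
        if self.regulation_slope > 0:
            bad("regulation_slope must be <= 0 (planted repression)")
        n_planted = (self.n_model_specific * self.n_groups
                     + self.n_subtype_mirnas)
        if n_planted > self.n_mirnas:
            bad(f"n_model_specific * n_groups + n_subtype_mirnas = {n_planted} "
                f"exceeds n_mirnas = {self.n_mirnas}")
        n_profiles = ((self.n_groups if self.n_model_specific > 0 else 0)
                      + (2 if self.n_subtype_mirnas > 0 else 0))
        if self.n_regulated_mirnas > n_profiles:
            if n_planted == 0:
                bad("n_regulated_mirnas > 0 requires planted miRNAs "
                    "(regulators need expression variance)")
            bad(f"n_regulated_mirnas = {self.n_regulated_mirnas} exceeds the "
                f"number of distinct planted profiles = {n_profiles}")
        if self.n_regulated_mirnas * self.true_targets_per_mirna > self.n_genes:
            bad("n_regulated_mirnas * true_targets_per_mirna exceeds n_genes")
        if (self.true_targets_per_mirna + self.decoy_targets_per_mirna
                > self.n_genes):
            bad("true + decoy targets per miRNA exceed n_genes")
        if self.n_subtype_mirnas > 0:
            subtypes = set(self.group_subtypes)
            if not {"basal", "luminal"} <= subtypes:
                bad("subtype planting requires both basal and luminal groups")
        if self.mrna_missing_samples >= sum(self.samples_per_group):
            bad("mrna_missing_samples must leave at least one mRNA sample")

    def null_config(self) -> "SimulationConfig":
        """Copy with every planted effect switched off (global-null mode)."""
        from dataclasses import replace
        return replace(self, model_specific_delta=0.0, subtype_delta=0.0,
                       regulation_slope=0.0)


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for g, (name, subtype, strain, n) in enumerate(zip(
            config.group_names, config.group_subtypes,
            config.group_strains, config.samples_per_group)):
        for i in range(n):
            rows.append((f"{name}_{i + 1}", name, subtype, strain))
    return pd.DataFrame(rows, columns=["sample", "model", "subtype", "strain"])


def simulate_dataset(config: SimulationConfig):
    """Generate one complete synthetic study.

    Returns
    -------
    tuple of (mirna matrix, mrna matrix, sample sheet, probe map,
    target table, ground truth).  Fixing ``config.seed`` makes every output
    byte-identical across runs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sheet = _sample_sheet(config)
    samples = sheet["sample"].to_numpy()
    n_samples = len(samples)
    group_of = sheet["model"].to_numpy()
    subtype_of = sheet["subtype"].to_numpy()

    features = np.array([f"mmu-miR-{i + 1:04d}" for i in range(config.n_mirnas)])

    # -- choose planted features (disjoint sets) ----------------------------
    order = rng.permutation(config.n_mirnas)
    cursor = 0
    model_specific_rows = []
    planted_model_idx = {}
    for name in config.group_names:
        idx = order[cursor:cursor + config.n_model_specific]
        cursor += config.n_model_specific
        for i in idx:
            model_specific_rows.append((features[i], name))
            planted_model_idx[i] = name
    subtype_idx = order[cursor:cursor + config.n_subtype_mirnas]
    cursor += config.n_subtype_mirnas
    subtype_rows = []
    planted_subtype_idx = {}
    for j, i in enumerate(subtype_idx):
        direction = "basal" if j % 2 == 0 else "luminal"
        subtype_rows.append((features[i], direction))
        planted_subtype_idx[i] = direction

    # -- latent per-(feature, sample) abundance -----------------------------
    lo, hi = config.baseline_mean_range
    baselines = _baseline_sample(rng, lo, hi, config.n_mirnas)
    ms_lo, ms_hi = config.model_specific_baseline_range
    for i in planted_model_idx:
        baselines[i] = rng.uniform(ms_lo, ms_hi)

    latent = np.tile(baselines[:, None], (1, n_samples))
    for i, group in planted_model_idx.items():
        latent[i, group_of == group] += config.model_specific_delta
    for i, direction in planted_subtype_idx.items():
        latent[i, subtype_of == direction] += config.subtype_delta

    # -- regulated miRNAs and the predicted-target table --------------------
    # Regulators are planted miRNAs (they need expression variance), at most
    # one per model group / subtype direction: two regulators with the same
    # planted profile are statistically indistinguishable, so their targets
    # would cross-recover and the ground truth would not be identifiable.
    reg_idx = _choose_regulators(rng, planted_model_idx, planted_subtype_idx,
                                 config.n_regulated_mirnas)
    unplanted = [i for i in range(config.n_mirnas)
                 if i not in planted_model_idx and i not in planted_subtype_idx]
    decoy_only_idx = list(rng.choice(
        unplanted, size=min(config.n_decoy_only_mirnas, len(unplanted)),
        replace=False)) if config.n_decoy_only_mirnas else []

    genes = np.array([f"gene{i + 1:05d}" for i in range(config.n_genes)])
    gene_order = rng.permutation(config.n_genes)
    regulated_rows, decoy_rows = [], []
    regulator_of_gene = {}          # gene index -> miRNA index
    gcursor = 0
    for i in reg_idx:
        true_genes = gene_order[gcursor:gcursor + config.true_targets_per_mirna]
        gcursor += config.true_targets_per_mirna
        for g in true_genes:
            regulated_rows.append((features[i], genes[g]))
            regulator_of_gene[g] = i
        pool = np.setdiff1d(np.arange(config.n_genes), true_genes)
        decoys = rng.choice(pool, size=config.decoy_targets_per_mirna,
                            replace=False)
        for g in decoys:
            decoy_rows.append((features[i], genes[g]))
    n_pred = config.true_targets_per_mirna + config.decoy_targets_per_mirna
    for i in decoy_only_idx:
        decoys = rng.choice(config.n_genes, size=n_pred, replace=False)
        for g in decoys:
            decoy_rows.append((features[i], genes[g]))

    # standardized regulator abundance (zero signal in null mode)
    reg_z = {}
    for i in set(regulator_of_gene.values()):
        a = latent[i]
        sd = a.std()
        reg_z[i] = (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)

    # -- miRNA probe-level matrix -------------------------------------------
    probes_mirna, feat_of_probe = [], []
    for f in features:
        for r in range(1, config.probes_per_mirna + 1):
            probes_mirna.append(f"{f}_p{r}")
            feat_of_probe.append(f)
    n_probes = len(probes_mirna)
    probe_offsets = rng.normal(0.0, config.probe_offset_sd, size=n_probes)
    array_effect = rng.normal(0.0, config.sample_effect_sd, size=n_samples)
    noise = rng.normal(0.0, config.probe_noise_sd, size=(n_probes, n_samples))
    feat_row = np.repeat(np.arange(config.n_mirnas), config.probes_per_mirna)
    mirna_values = (latent[feat_row] + probe_offsets[:, None]
                    + array_effect[None, :] + noise)

    mirna_calls = _detection_calls(rng, n_probes, n_samples,
                                   config.fraction_absent_probes)

    probe_map_mirna = pd.DataFrame({
        "probe": probes_mirna,
        "feature": feat_of_probe,
        "kind": "miRNA",
        "strand": "+",
        "is_control": 0,
        "species_ok": 1,
        "replicate": list(itertools.chain.from_iterable(
            range(1, config.probes_per_mirna + 1)
            for _ in range(config.n_mirnas))),
    })

    # -- mRNA probe-level matrix --------------------------------------------
    gene_baselines = _baseline_sample(rng, lo, hi, config.n_genes)
    gene_latent = np.tile(gene_baselines[:, None], (1, n_samples))
    gene_latent += rng.normal(0.0, config.regulation_noise_sd,
                              size=(config.n_genes, n_samples))
    for g, i in regulator_of_gene.items():
        gene_latent[g] += config.regulation_slope * reg_z[i]

    plo, phi = config.probes_per_gene
    n_probes_gene = rng.integers(plo, phi + 1, size=config.n_genes)
    probes_mrna, gene_of_probe, gene_row, replicate_idx = [], [], [], []
    for g in range(config.n_genes):
        for r in range(1, n_probes_gene[g] + 1):
            probes_mrna.append(f"{genes[g]}_at{r}")
            gene_of_probe.append(genes[g])
            gene_row.append(g)
            replicate_idx.append(r)
    gene_row = np.array(gene_row)
    n_mprobes = len(probes_mrna)
    m_offsets = rng.normal(0.0, config.probe_offset_sd, size=n_mprobes)
    m_array_effect = rng.normal(0.0, config.sample_effect_sd, size=n_samples)
    m_noise = rng.normal(0.0, config.probe_noise_sd, size=(n_mprobes, n_samples))
    mrna_values = (gene_latent[gene_row] + m_offsets[:, None]
                   + m_array_effect[None, :] + m_noise)
    mrna_calls = _detection_calls(rng, n_mprobes, n_samples,
                                  config.fraction_absent_probes)

    probe_map_mrna = pd.DataFrame({
        "probe": probes_mrna,
        "feature": gene_of_probe,
        "kind": "mRNA",
        "strand": "+",
        "is_control": 0,
        "species_ok": 1,
        "replicate": replicate_idx,
    })

    # mRNA platform misses a couple of samples, exercising sample matching
    mrna_samples = samples
    if config.mrna_missing_samples:
        drop = rng.choice(n_samples, size=config.mrna_missing_samples,
                          replace=False)
        keep = np.setdiff1d(np.arange(n_samples), drop)
        mrna_samples = samples[keep]
        mrna_values = mrna_values[:, keep]
        mrna_calls = mrna_calls[:, keep]

    mirna = ExpressionMatrix(
        values=pd.DataFrame(mirna_values, index=pd.Index(probes_mirna, name="probe"),
                            columns=samples),
        calls=pd.DataFrame(mirna_calls, index=pd.Index(probes_mirna, name="probe"),
                           columns=samples),
        scale="log2")
    mrna = ExpressionMatrix(
        values=pd.DataFrame(mrna_values, index=pd.Index(probes_mrna, name="probe"),
                            columns=mrna_samples),
        calls=pd.DataFrame(mrna_calls, index=pd.Index(probes_mrna, name="probe"),
                           columns=mrna_samples),
        scale="log2")

    probe_map = pd.concat([probe_map_mirna, probe_map_mrna], ignore_index=True)
    target_rows = ([(m, g, "true") for m, g in regulated_rows]
                   + [(m, g, "decoy") for m, g in decoy_rows])
    targets = pd.DataFrame(target_rows, columns=["mirna", "gene", "source"])
    truth = GroundTruth(
        model_specific=pd.DataFrame(model_specific_rows,
                                    columns=["feature", "group"]),
        subtype_differential=pd.DataFrame(subtype_rows,
                                          columns=["feature", "direction"]),
        regulated_pairs=pd.DataFrame(regulated_rows, columns=["mirna", "gene"]),
        decoy_pairs=pd.DataFrame(decoy_rows, columns=["mirna", "gene"]),
    )
    return mirna, mrna, sheet, probe_map, targets, truth


def _choose_regulators(rng, planted_model_idx, planted_subtype_idx, n):
    """Pick ``n`` regulator miRNAs with mutually distinct planted profiles.

    One model-specific miRNA per distinct group, then at most one subtype
    miRNA per direction.  Raises a configuration error if fewer distinct
    profiles exist than regulators requested.
    """
    if n == 0:
        return []
    by_group: dict = {}
    for i, group in planted_model_idx.items():
        by_group.setdefault(group, []).append(i)
    by_direction: dict = {}
    for i, direction in planted_subtype_idx.items():
        by_direction.setdefault(direction, []).append(i)
    pools = [by_group[g] for g in sorted(by_group)]
    pools += [by_direction[d] for d in sorted(by_direction)]
    if n > len(pools):
        raise ConfigurationError(
            f"n_regulated_mirnas = {n} exceeds the number of distinct "
            f"planted profiles = {len(pools)} (model groups + subtype "
            "directions)")
    chosen_pools = rng.permutation(len(pools))[:n]
    return [int(rng.choice(pools[k])) for k in chosen_pools]


def _baseline_sample(rng, lo, hi, n):
    """Baseline log2 intensities: normal centered in [lo, hi], truncated.

    Real single-channel log-intensity histograms are unimodal, with most
    probes near the array median; that density is what makes the per-array
    sample median a precise normalization anchor.  sd = (hi - lo) / 5 keeps
    essentially all mass inside the stated range; the rare outside draw is
    rejected and redrawn.
    """
    mid = 0.5 * (lo + hi)
    sd = (hi - lo) / 5.0
    out = rng.normal(mid, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mid, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _detection_calls(rng, n_probes, n_samples, fraction_absent):
    """'P' everywhere except a planted subset of mostly-absent probes.

    Each absent probe carries 'P' in at most two arrays, so the standard
    "present/marginal in >= 3 arrays" filter removes exactly these probes.
    """
    calls = np.full((n_probes, n_samples), "P", dtype="<U1")
    n_absent = int(round(fraction_absent * n_probes))
    if n_absent:
        absent = rng.choice(n_probes, size=n_absent, replace=False)
        for p in absent:
            calls[p, :] = "A"
            n_present = int(rng.integers(0, min(3, n_samples + 1)))
            if n_present:
                cols = rng.choice(n_samples, size=n_present, replace=False)
                calls[p, cols] = "P"
    return calls


def simulate_qpcr_panel(mirna: ExpressionMatrix, probes: pd.DataFrame,
                        chosen, noise_sd: float, seed: int) -> pd.DataFrame:
    """Paired qPCR measurements (-dCt) for selected miRNAs.

    -dCt is an affine function of the feature's mean log2 array intensity
    (positive slope) plus Gaussian noise, so array/qPCR concordance is
    positive by construction.  Returns one row per (sample, feature) with
    columns ``sample``, ``feature``, ``neg_delta_ct``.
    """
    rng = np.random.default_rng(seed)
    known = set(probes.loc[probes["kind"] == "miRNA", "feature"])
    rows = []
    for feature in chosen:
        if feature not in known:
            raise FeatureLookupError(f"unknown miRNA feature {feature!r}")
        probe_ids = probes.loc[probes["feature"] == feature, "probe"]
        present = [p for p in probe_ids if p in mirna.values.index]
        if not present:
            raise FeatureLookupError(
                f"no probes of {feature!r} present in the matrix")
        mean_log2 = mirna.values.loc[present].mean(axis=0)
        noise = rng.normal(0.0, noise_sd, size=mirna.n_samples)
        neg_dct = QPCR_INTERCEPT + QPCR_SLOPE * mean_log2.to_numpy() + noise
        for s, v in zip(mirna.sample_ids, neg_dct):
            rows.append((s, feature, v))
    return pd.DataFrame(rows, columns=["sample", "feature", "neg_delta_ct"])
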