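"""Synthetic mRNA/miRNA/exon bundles with planted effects and a truth record.

The generator emulates a three-phenotype neutrophil profiling design
(disease vs disease-control vs healthy) at configurable reduced scale:
matched log2 expression matrices for genes, miRNAs and exons, a sample
design, a TargetScan-style miRNA->gene target map, GMT-style immunologic
signature stand-ins, and a machine-readable record of every planted effect.

Generative model
----------------
Each feature draws a base level ``mu ~ Normal(8, 1.5)`` (log2 intensity).
mRNA and exon values add per-sample measurement noise ``Normal(0, noise_sd)``;
miRNA values add per-sample biological variation ``Normal(0, 1.5)`` so that
miRNA profiles vary across samples even in the noiseless-mRNA limit (they
drive the planted repression).  On this baseline the generator plants, inside
``affected_phenotype``:

* differential expression — signed log2 shifts of ``de_log2_shift``;
* miRNA->target repression — for a regulated pair the target becomes
  ``mu_g - repression_slope * (x_m - mean(x_m)) + noise`` so the pair is
  anti-correlated within the phenotype (exactly -1 as ``noise_sd -> 0``);
* differential splicing — one exon per spliced gene offset by
  ``si_magnitude``;
* signature activity — member genes of an active signature and the target
  genes of a designated miRNA receive a coordinated shift in a random half
  of the phenotype's samples, so their rank-based set scores covary.

Generation is a pure function of the config, including its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import (
    ExonMap,
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
    TargetMap,
    write_exon_map,
    write_expression_matrix,
    write_gene_sets,
    write_sample_design,
    write_target_map,
)

BASE_MEAN = 8.0       # log2 intensity scale of the arrays
BASE_SD = 1.5         # spread of per-feature base levels
MIRNA_SAMPLE_SD = 1.5  # across-sample biological variation of miRNA profiles
EXON_OFFSET_SD = 0.75  # per-exon additive offset relative to its gene


@dataclass(frozen=True)
class SimConfig:
    """Scaled-down defaults keep full-pipeline runs under a minute."""

    n_genes: int = 1000
    n_mirnas: int = 40
    group_sizes: tuple[tuple[str, int], ...] = (("JIA", 12), ("CF", 8), ("HC", 14))
    targets_per_mirna: int = 25
    frac_de_genes: float = 0.05
    de_log2_shift: float = 1.0
    n_regulated_pairs: int = 40
    repression_slope: float = 1.0
    noise_sd: float = 0.5
    exons_per_gene: int = 4
    frac_spliced_genes: float = 0.05
    si_magnitude: float = 2.0
    n_signatures: int = 50
    signature_size: int = 30
    frac_active_signatures: float = 0.2
    affected_phenotype: str = "JIA"
    seed: int = 0

    def __post_init__(self) -> None:
        groups = dict(self.group_sizes)
        for frac in (self.frac_de_genes, self.frac_spliced_genes, self.frac_active_signatures):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"proportion out of [0, 1]: {frac}")
        for name, value in (("n_genes", self.n_genes), ("n_mirnas", self.n_mirnas),
                            ("targets_per_mirna", self.targets_per_mirna),
                            ("exons_per_gene", self.exons_per_gene),
                            ("n_signatures", self.n_signatures),
                            ("signature_size", self.signature_size)):
            if value < 1:
                raise ConfigError(f"{name} must be positive, got {value}")
        if any(n < 3 for n in groups.values()):
            raise ConfigError("every group needs >= 3 samples (correlation and t-tests require it)")
        if self.n_regulated_pairs < 0:
            raise ConfigError("n_regulated_pairs must be non-negative")
        if self.n_regulated_pairs > self.n_mirnas * self.targets_per_mirna:
            raise ConfigError("n_regulated_pairs exceeds the number of (miRNA, target) pairs")
        if self.targets_per_mirna > self.n_genes:
            raise ConfigError("targets_per_mirna exceeds n_genes")
        if self.signature_size > self.n_genes:
            raise ConfigError("signature_size exceeds n_genes")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.repression_slope < 0:
            raise ConfigError("repression_slope must be non-negative")
        if self.affected_phenotype not in groups:
            raise ConfigError(f"affected_phenotype {self.affected_phenotype!r} not in group_sizes")

    @property
    def groups(self) -> dict[str, int]:
        return dict(self.group_sizes)


@dataclass
class SyntheticTruth:
    """Machine-readable record of every planted effect."""

    de_genes: dict[str, set[tuple[str, float]]] = field(default_factory=dict)
    de_mirnas: dict[str, set[tuple[str, float]]] = field(default_factory=dict)
    regulated_pairs: set[tuple[str, str, float]] = field(default_factory=set)
    spliced_exons: set[tuple[str, str, float]] = field(default_factory=set)
    active_signatures: dict[str, set[str]] = field(default_factory=dict)
    signature_pairs: set[tuple[str, str]] = field(default_factory=set)  # (miRNA, signature)

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, set):
                return sorted(list(t) if isinstance(t, tuple) else t for t in obj)
            return obj
        return json.dumps({k: enc(v) for k, v in asdict(self).items()}, indent=1)


@dataclass
class SyntheticBundle:
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    exon: ExpressionMatrix
    exon_map: ExonMap
    design: SampleDesign
    targets: TargetMap
    signatures: GeneSetCollection
    truth: SyntheticTruth
    config: SimConfig


def _round(frac: float, n: int) -> int:
    return int(round(frac * n))


def generate_dataset(config: SimConfig) -> SyntheticBundle:
    """Generate the full bundle; bit-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    groups = config.groups

    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    mirna_ids = [f"mir{i:04d}" for i in range(config.n_mirnas)]
    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    for label, size in groups.items():
        for i in range(size):
            sid = f"{label}_{i + 1:02d}"
            sample_ids.append(sid)
            assignments[sid] = label
    design = SampleDesign(assignments)
    n_samples = len(sample_ids)
    aff_cols = np.array([i for i, s in enumerate(sample_ids)
                         if assignments[s] == config.affected_phenotype])
    pheno = config.affected_phenotype
    truth = SyntheticTruth()

    # --- target map -------------------------------------------------------
    target_sets: dict[str, frozenset[str]] = {}
    for m in mirna_ids:
        idx = rng.choice(config.n_genes, size=config.targets_per_mirna, replace=False)
        target_sets[m] = frozenset(gene_ids[i] for i in idx)
    targets = TargetMap(dict(target_sets))

    # --- baselines --------------------------------------------------------
    gene_mu = rng.normal(BASE_MEAN, BASE_SD, config.n_genes)
    mirna_mu = rng.normal(BASE_MEAN, BASE_SD, config.n_mirnas)
    mrna_vals = gene_mu[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, n_samples))
    mirna_vals = mirna_mu[:, None] + rng.normal(0.0, MIRNA_SAMPLE_SD, (config.n_mirnas, n_samples))

    gene_row = {g: i for i, g in enumerate(gene_ids)}
    mirna_row = {m: i for i, m in enumerate(mirna_ids)}

    # --- differential expression -----------------------------------------
    n_de = _round(config.frac_de_genes, config.n_genes)
    de_gene_idx = rng.choice(config.n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    de_set: set[tuple[str, float]] = set()
    for j, gi in enumerate(de_gene_idx):
        shift = config.de_log2_shift if j % 2 == 0 else -config.de_log2_shift
        if shift != 0.0:
            mrna_vals[gi, aff_cols] += shift
            de_set.add((gene_ids[gi], shift))
    if de_set:
        truth.de_genes[pheno] = de_set

    n_de_mir = _round(config.frac_de_genes, config.n_mirnas)
    de_mir_idx = rng.choice(config.n_mirnas, size=n_de_mir, replace=False) if n_de_mir else np.array([], int)
    de_mir_set: set[tuple[str, float]] = set()
    for j, mi in enumerate(de_mir_idx):
        shift = config.de_log2_shift if j % 2 == 0 else -config.de_log2_shift
        if shift != 0.0:
            mirna_vals[mi, aff_cols] += shift
            de_mir_set.add((mirna_ids[mi], shift))
    if de_mir_set:
        truth.de_mirnas[pheno] = de_mir_set

    # --- planted repression ----------------------------------------------
    # one regulating miRNA per gene; regulated genes kept clear of DE genes
    de_gene_names = {g for g, _ in de_set}
    used_genes: set[str] = set()
    order = rng.permutation(config.n_mirnas)
    pair_list: list[tuple[str, str]] = []
    k = 0
    while len(pair_list) < config.n_regulated_pairs:
        m = mirna_ids[order[k % config.n_mirnas]]
        k += 1
        candidates = sorted(target_sets[m] - used_genes - de_gene_names)
        if not candidates and k > config.n_mirnas * (config.n_regulated_pairs + 1):
            raise ConfigError("could not place the requested number of regulated pairs")
        if not candidates:
            continue
        g = candidates[int(rng.integers(len(candidates)))]
        used_genes.add(g)
        pair_list.append((m, g))
    for m, g in pair_list:
        x = mirna_vals[mirna_row[m], aff_cols]
        mrna_vals[gene_row[g], aff_cols] = (
            gene_mu[gene_row[g]]
            - config.repression_slope * (x - x.mean())
            + rng.normal(0.0, config.noise_sd, len(aff_cols))
        )
        if config.repression_slope > 0:
            truth.regulated_pairs.add((m, g, config.repression_slope))

    # --- signatures and planted signature activity ------------------------
    sig_names = [f"SIG_{i:04d}" for i in range(config.n_signatures)]
    sig_sets: dict[str, tuple[str, frozenset[str]]] = {}
    for name in sig_names:
        idx = rng.choice(config.n_genes, size=config.signature_size, replace=False)
        sig_sets[name] = ("synthetic immunologic signature", frozenset(gene_ids[i] for i in idx))
    signatures = GeneSetCollection(dict(sig_sets))

    n_active = _round(config.frac_active_signatures, config.n_signatures)
    active_idx = rng.choice(config.n_signatures, size=n_active, replace=False) if n_active else np.array([], int)
    pair_mirnas = {m for m, _ in pair_list}
    free_mirnas = [m for m in mirna_ids if m not in pair_mirnas] or list(mirna_ids)
    active_set: set[str] = set()
    for j, si in enumerate(active_idx):
        name = sig_names[si]
        m = free_mirnas[j % len(free_mirnas)]
        half = rng.choice(aff_cols, size=max(1, len(aff_cols) // 2), replace=False)
        member_rows = [gene_row[g] for g in sig_sets[name][1]]
        target_rows = [gene_row[g] for g in target_sets[m]]
        shift = config.de_log2_shift
        if shift != 0.0:
            mrna_vals[np.ix_(member_rows, half)] += shift
            mrna_vals[np.ix_(sorted(set(target_rows) - set(member_rows)), half)] += shift
            active_set.add(name)
            truth.signature_pairs.add((m, name))
    if active_set:
        truth.active_signatures[pheno] = active_set

    # --- exon matrix ------------------------------------------------------
    exon_ids: list[str] = []
    parent: dict[str, str] = {}
    for g in gene_ids:
        for e in range(config.exons_per_gene):
            eid = f"{g}_e{e + 1}"
            exon_ids.append(eid)
            parent[eid] = g
    offsets = rng.normal(0.0, EXON_OFFSET_SD, len(exon_ids))
    exon_vals = (
        np.repeat(mrna_vals, config.exons_per_gene, axis=0)
        + offsets[:, None]
        + rng.normal(0.0, config.noise_sd, (len(exon_ids), n_samples))
    )

    n_spliced = _round(config.frac_spliced_genes, config.n_genes)
    spliced_gene_idx = rng.choice(config.n_genes, size=n_spliced, replace=False) if n_spliced else np.array([], int)
    for gi in spliced_gene_idx:
        if config.si_magnitude == 0.0:
            break
        erow = gi * config.exons_per_gene  # first exon of the gene
        exon_vals[np.ix_([erow], aff_cols)] += config.si_magnitude
        truth.spliced_exons.add((exon_ids[erow], pheno, config.si_magnitude))

    bundle = SyntheticBundle(
        mrna=ExpressionMatrix(pd.DataFrame(mrna_vals, index=gene_ids, columns=sample_ids), "gene"),
        mirna=ExpressionMatrix(pd.DataFrame(mirna_vals, index=mirna_ids, columns=sample_ids), "mirna"),
        exon=ExpressionMatrix(pd.DataFrame(exon_vals, index=exon_ids, columns=sample_ids), "exon"),
        exon_map=ExonMap(parent),
        design=design,
        targets=targets,
        signatures=signatures,
        truth=truth,
        config=config,
    )
    return bundle


def null_dataset(config: SimConfig) -> SyntheticBundle:
    """Same generator with every effect size forced to zero; empty truth."""
    null_config = replace(
        config,
        de_log2_shift=0.0,
        n_regulated_pairs=0,
        repression_slope=0.0,
        si_magnitude=0.0,
        frac_active_signatures=0.0,
    )
    bundle = generate_dataset(null_config)
    bundle.truth = SyntheticTruth()
    return bundle


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write every artifact of a bundle in the io_formats dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(bundle.mrna, out / "mrna.tsv")
    write_expression_matrix(bundle.mirna, out / "mirna.tsv")
    write_expression_matrix(bundle.exon, out / "exon.tsv")
    write_exon_map(bundle.exon_map, out / "exon_map.tsv")
    write_sample_design(bundle.design, out / "design.tsv")
    write_target_map(bundle.targets, out / "targets.tsv")
    write_gene_sets(bundle.signatures, out / "signatures.gmt")
    (out / "truth.json").write_text(bundle.truth.to_json(), encoding="utf-8")
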