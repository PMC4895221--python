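"""Three-level miRNA-mRNA anti-correlation screen with permutation nulls.

The screen asks whether miRNAs depress the abundance of their predicted
target transcripts, at three granularities within one phenotype's samples:

* **miRNA level** — one record per miRNA: the pooled point set
  ``{(miRNA[s], target_j[s])}`` over all of its targets j and samples s
  (anchor values repeated per member);
* **gene level** — one record per targeted gene, pooling over all miRNAs
  that target it;
* **pair level** — one record per (miRNA, target) pair, the plain per-pair
  correlation across samples.

Pearson r and Spearman rho are computed on the pooled point sets (Spearman
ranks the pooled coordinates globally, average ranks for ties).  The pooling
interpretation — concatenating (anchor, member) sample pairs over members —
is what makes the tiny published cutoffs (e.g. -0.0075 at the miRNA level)
meaningful: the pooled n is members x samples.

Significance is empirical: each permutation replicate applies one shared
random permutation of the phenotype's sample order to the miRNA matrix
(the mRNA matrix stays fixed, preserving its covariance structure), every
record statistic is recomputed, and ``perm_p`` is the fraction of replicates
whose Pearson statistic is at least as extreme as the observed one in the
requested tail.  With the lower tail, 1,000 replicates and the published
``p < 1e-3`` rule, selection requires zero exceedances; ``perm_p`` is
therefore reported without add-one correction by default (an optional
``(k+1)/(n+1)`` mode exists for conservative use).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import stats

from .errors import DesignError, InsufficientPairsError
from .io_formats import ExpressionMatrix, SampleDesign, TargetMap

logger = logging.getLogger("neutronet")

LEVELS = ("mirna", "gene", "pair")


@dataclass(frozen=True)
class CorrelationRecord:
    level: str
    entity: object  # miRNA id, gene id, or (miRNA, gene) tuple
    pearson_r: float
    spearman_rho: float
    n_points: int
    perm_p: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class LevelThresholds:
    """Conjunctive selection rule: perm_p < p_max AND r <= r_max AND rho <= rho_max."""

    p_max: float
    r_max: float
    rho_max: float

    def __post_init__(self) -> None:
        if self.r_max >= 0 or self.rho_max >= 0:
            raise ValueError("anti-correlation thresholds must be negative")


#: published per-level cutoffs (p < 1e-3 and both coefficients <= the bound)
MIRNA_LEVEL = LevelThresholds(p_max=1e-3, r_max=-0.0075, rho_max=-0.0075)
GENE_LEVEL = LevelThresholds(p_max=1e-3, r_max=-0.02, rho_max=-0.02)
PAIR_LEVEL = LevelThresholds(p_max=1e-3, r_max=-0.3, rho_max=-0.3)
THRESHOLDS = {"mirna": MIRNA_LEVEL, "gene": GENE_LEVEL, "pair": PAIR_LEVEL}


def pooled_correlation(anchor_profile, member_profiles, entity=None, level: str = "mirna") -> CorrelationRecord:
    """Pearson and Spearman on the pooled (anchor, member) point set.

    Reference implementation by explicit enumeration of the pooled points;
    the bulk screen computes the same quantities through per-sample
    aggregates.  Zero variance in either pooled coordinate yields
    coefficients of 0 with the degenerate flag set.
    """
    anchor = np.asarray(anchor_profile, dtype=float)
    members = [np.asarray(m, dtype=float) for m in member_profiles]
    if not members:
        raise ValueError("at least one member profile is required")
    if any(len(m) != len(anchor) for m in members):
        raise ValueError("anchor and members must share the same ordered sample set")
    x = np.concatenate([anchor] * len(members))
    y = np.concatenate(members)
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationRecord(level, entity, 0.0, 0.0, n, degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    rho = float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])
    return CorrelationRecord(level, entity, r, rho, n)


# ---------------------------------------------------------------------------
# screen internals: every record reduces to stat = (F . P[pi]) - c1) / c2
# where F is the fixed side and P the side carried by the permuted matrix
# ---------------------------------------------------------------------------

@dataclass
class _Internals:
    level: str
    entities: list
    n_points: np.ndarray
    fixed_p: np.ndarray   # records x samples, Pearson fixed side
    perm_p_side: np.ndarray
    c1_p: np.ndarray
    c2_p: np.ndarray
    fixed_s: np.ndarray   # Spearman (pooled-rank) analogues
    perm_s_side: np.ndarray
    c1_s: np.ndarray
    c2_s: np.ndarray

    def stats(self, order: np.ndarray | None = None, side: str = "mirna"):
        """Pearson and Spearman statistics, optionally permuting one side.

        ``side='mirna'`` permutes the miRNA-derived vectors (the default
        null); ``side='mrna'`` permutes the mRNA-derived vectors instead.
        """
        fp, pp, fs, ps = self.fixed_p, self.perm_p_side, self.fixed_s, self.perm_s_side
        if order is not None:
            if side == "mirna":
                pp, ps = pp[:, order], ps[:, order]
            else:
                fp, fs = fp[:, order], fs[:, order]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (np.einsum("rs,rs->r", fp, pp) - self.c1_p) / self.c2_p
            rho = (np.einsum("rs,rs->r", fs, ps) - self.c1_s) / self.c2_s
        r[~np.isfinite(r)] = 0.0
        rho[~np.isfinite(rho)] = 0.0
        return r, rho


def _pooled_rank_of_anchor(x: np.ndarray, multiplicity: int) -> np.ndarray:
    """Average global rank of each sample's anchor value when the anchor is
    repeated ``multiplicity`` times in the pooled point set."""
    if multiplicity == 1:
        return stats.rankdata(x)
    return stats.rankdata(np.repeat(x, multiplicity))[::multiplicity]


def _sum_stats(v_sum, v_sqsum, n):
    return v_sqsum - v_sum**2 / n


def _phenotype_samples(design: SampleDesign, phenotype: str,
                       mirna: ExpressionMatrix, mrna: ExpressionMatrix) -> list[str]:
    cols = [s for s in design.samples_of(phenotype)
            if s in set(mirna.sample_ids) and s in set(mrna.sample_ids)]
    if len(cols) < 3:
        raise DesignError(f"phenotype {phenotype!r} has {len(cols)} usable samples; >= 3 required")
    return cols


def _build_internals(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    targets: TargetMap,
    design: SampleDesign,
    phenotype: str,
    level: str,
) -> _Internals:
    if level not in LEVELS:
        raise ValueError(f"unknown screen level: {level!r}")
    cols = _phenotype_samples(design, phenotype, mirna, mrna)
    S = len(cols)
    X = mirna.data[cols]
    Y = mrna.data[cols]
    gene_index = {g: i for i, g in enumerate(Y.index)}
    Xv, Yv = X.to_numpy(), Y.to_numpy()
    mirna_index = {m: i for i, m in enumerate(X.index)}

    dropped = len(targets.unique_genes() - set(gene_index))
    if dropped:
        logger.info("%d target genes absent from the mRNA matrix were dropped", dropped)

    entities: list = []
    n_points: list[int] = []
    Fp, Pp, c1p, c2p = [], [], [], []
    Fs, Ps, c1s, c2s = [], [], [], []

    def add_pooled(anchor_vals, member_vals, entity, anchor_is_mirna: bool):
        m = member_vals.shape[0]
        n = m * S
        w = member_vals.sum(axis=0)
        sx, sxx = anchor_vals.sum(), (anchor_vals**2).sum()
        sy, syy = member_vals.sum(), (member_vals**2).sum()
        sxx_pool = m * _sum_stats(sx, sxx, S)
        syy_pool = _sum_stats(sy, syy, n)
        c2 = np.sqrt(max(sxx_pool * syy_pool, 0.0))
        # Spearman: global pooled ranks
        ra = _pooled_rank_of_anchor(anchor_vals, m)
        rm = stats.rankdata(member_vals.ravel()).reshape(m, S)
        wr = rm.sum(axis=0)
        sxr, sxxr = ra.sum(), (ra**2).sum()
        syr, syyr = rm.sum(), (rm**2).sum()
        c2r = np.sqrt(max(m * _sum_stats(sxr, sxxr, S) * _sum_stats(syr, syyr, n), 0.0))
        entities.append(entity)
        n_points.append(n)
        if anchor_is_mirna:   # anchor permutes
            Fp.append(w); Pp.append(anchor_vals)
            Fs.append(wr); Ps.append(ra)
        else:                 # member side (miRNAs) permutes jointly
            Fp.append(anchor_vals); Pp.append(w)
            Fs.append(ra); Ps.append(wr)
        c1p.append(sx * sy / S); c2p.append(c2)
        c1s.append(sxr * syr / S); c2s.append(c2r)

    if level == "mirna":
        for m_id in targets.mirna_ids:
            if m_id not in mirna_index:
                logger.info("miRNA %s absent from the miRNA matrix; skipped", m_id)
                continue
            rows = [gene_index[g] for g in sorted(targets.targets[m_id]) if g in gene_index]
            if not rows:
                logger.info("miRNA %s has no targets in the mRNA matrix; skipped", m_id)
                continue
            add_pooled(Xv[mirna_index[m_id]], Yv[rows], m_id, anchor_is_mirna=True)
    elif level == "gene":
        by_gene: dict[str, list[str]] = {}
        for m_id, genes in targets.targets.items():
            if m_id not in mirna_index:
                continue
            for g in genes:
                if g in gene_index:
                    by_gene.setdefault(g, []).append(m_id)
        for g in sorted(by_gene):
            rows = [mirna_index[m] for m in sorted(by_gene[g])]
            add_pooled(Yv[gene_index[g]], Xv[rows], g, anchor_is_mirna=False)
    else:  # pair
        for m_id in targets.mirna_ids:
            if m_id not in mirna_index:
                continue
            for g in sorted(targets.targets[m_id]):
                if g in gene_index:
                    add_pooled(Xv[mirna_index[m_id]], Yv[gene_index[g]][None, :],
                               (m_id, g), anchor_is_mirna=True)

    if not entities:
        raise ValueError(f"no records could be formed at level {level!r}")
    return _Internals(
        level=level,
        entities=entities,
        n_points=np.array(n_points, dtype=int),
        fixed_p=np.array(Fp), perm_p_side=np.array(Pp),
        c1_p=np.array(c1p), c2_p=np.array(c2p),
        fixed_s=np.array(Fs), perm_s_side=np.array(Ps),
        c1_s=np.array(c1s), c2_s=np.array(c2s),
    )


def screen(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    targets: TargetMap,
    design: SampleDesign,
    phenotype: str,
    level: str,
) -> list[CorrelationRecord]:
    """One CorrelationRecord per entity at the requested level."""
    internals = _build_internals(mirna, mrna, targets, design, phenotype, level)
    r, rho = internals.stats()
    degenerate = internals.c2_p == 0
    return [
        CorrelationRecord(level, e, float(ri), float(rhoi), int(n), degenerate=bool(d))
        for e, ri, rhoi, n, d in zip(internals.entities, r, rho, internals.n_points, degenerate)
    ]


def permutation_pvalues(
    records: list[CorrelationRecord],
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    targets: TargetMap,
    design: SampleDesign,
    phenotype: str,
    n_perm: int = 1000,
    tail: str = "lower",
    seed: int | None = None,
    permute_side: str = "mirna",
    add_one: bool = False,
) -> list[CorrelationRecord]:
    """Fill ``perm_p`` on a list of screen records.

    One shared sample permutation per replicate is applied to the chosen
    matrix side (miRNA by default), every Pearson statistic is recomputed
    and compared with the observed value in the requested tail (``lower``
    counts replicates <= observed; ``upper`` counts >=).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("lower", "upper"):
        raise ValueError(f"unknown tail: {tail!r}")
    if permute_side not in ("mirna", "mrna"):
        raise ValueError(f"unknown permute_side: {permute_side!r}")
    if not records:
        return []
    level = records[0].level
    internals = _build_internals(mirna, mrna, targets, design, phenotype, level)
    if internals.entities != [rec.entity for rec in records]:
        raise ValueError("records do not match the screen order for this input")
    obs = np.array([rec.pearson_r for rec in records])
    S = internals.fixed_p.shape[1]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(records), dtype=int)
    for _ in range(n_perm):
        order = rng.permutation(S)
        r, _rho = internals.stats(order=order, side=permute_side)
        if tail == "lower":
            exceed += r <= obs
        else:
            exceed += r >= obs
    if add_one:
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = exceed / n_perm
    return [_dc_replace(rec, perm_p=float(pi)) for rec, pi in zip(records, p)]


def select_significant(records: list[CorrelationRecord], thresholds: LevelThresholds) -> list[CorrelationRecord]:
    """Records with perm_p < p_max AND r <= r_max AND rho <= rho_max.

    The p inequality is strict: with 1,000 replicates and p_max = 1e-3 only
    perm_p = 0 (zero exceedances) survives.
    """
    out = []
    for rec in records:
        if rec.perm_p is None:
            raise ValueError("perm_p not filled; run permutation_pvalues first")
        if (rec.perm_p < thresholds.p_max
                and rec.pearson_r <= thresholds.r_max
                and rec.spearman_rho <= thresholds.rho_max):
            out.append(rec)
    return out


def compare_negative_distributions(
    records_a: list[CorrelationRecord],
    records_b: list[CorrelationRecord],
) -> tuple[float, int, int]:
    """Paired Wilcoxon signed-rank comparison of negative correlations.

    Records are paired by entity; the comparison is restricted to entities
    with a negative Pearson r in at least one of the two phenotypes.
    Returns ``(two_sided_p, direction, n_pairs)`` where direction is the
    sign of the median paired difference (a - b); all-zero differences give
    the degenerate p = 1.
    """
    by_b = {rec.entity: rec for rec in records_b}
    pairs = [
        (ra.pearson_r, by_b[ra.entity].pearson_r)
        for ra in records_a
        if ra.entity in by_b and (ra.pearson_r < 0 or by_b[ra.entity].pearson_r < 0)
    ]
    if len(pairs) < 6:
        raise InsufficientPairsError(f"only {len(pairs)} comparable pairs; >= 6 required")
    a = np.array([x for x, _ in pairs])
    b = np.array([y for _, y in pairs])
    diffs = a - b
    direction = int(np.sign(np.median(diffs)))
    if np.all(diffs == 0):
        return 1.0, 0, len(pairs)
    p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    return p, direction, len(pairs)
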