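"""Splicing Index and exon-level ANOVA for differential exon inclusion.

Gene-level signal is summarised as the unweighted mean of the gene's exon
log2 values per sample.  The normalized intensity of an exon is
``NI(e, s) = exon(e, s) - gene(g(e), s)``; the Splicing Index of an exon
between two groups is the difference of group-mean NI (log2 units); the
exon-level test is a one-way ANOVA of NI across groups, which is the
group-effect test the MiDAS program applies to gene-normalized exon
signals.  Selection combines ``midas_p <= p_max`` with ``|si| >= si_min``.

Exons of single-exon genes have NI identically zero by construction; they
are flagged, not rejected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .io_formats import ExonMap, ExpressionMatrix, SampleDesign

logger = logging.getLogger("neutronet")


def normalized_intensities(exon: ExpressionMatrix, exon_map: ExonMap) -> pd.DataFrame:
    """Exon log2 signal minus the per-sample mean over the gene's exons."""
    genes = pd.Series({e: exon_map.gene_of(e) for e in exon.feature_ids})
    gene_means = exon.data.groupby(genes).transform("mean")
    return exon.data - gene_means


def _group_columns(design: SampleDesign, matrix: ExpressionMatrix, label: str) -> list[str]:
    cols = [s for s in design.samples_of(label) if s in set(matrix.sample_ids)]
    if label not in design.group_sizes():
        raise DesignError(f"unknown phenotype label: {label!r}")
    if len(cols) < 2:
        raise DesignError(f"group {label!r} has {len(cols)} samples in the matrix; >= 2 required")
    return cols


def splicing_index(
    exon: ExpressionMatrix,
    exon_map: ExonMap,
    design: SampleDesign,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-exon SI table: gene, group-mean NI per group, si = ni_a - ni_b."""
    cols_a = _group_columns(design, exon, group_a)
    cols_b = _group_columns(design, exon, group_b)
    ni = normalized_intensities(exon, exon_map)
    ni_a = ni[cols_a].mean(axis=1)
    ni_b = ni[cols_b].mean(axis=1)
    exon_counts = pd.Series({e: 1 for e in exon.feature_ids}).groupby(
        pd.Series({e: exon_map.gene_of(e) for e in exon.feature_ids})
    ).transform("sum")
    single = exon_counts == 1
    if single.any():
        logger.info("%d exons belong to single-exon genes; their SI is 0 by construction", int(single.sum()))
    return pd.DataFrame(
        {
            "gene": [exon_map.gene_of(e) for e in exon.feature_ids],
            "ni_a": ni_a,
            "ni_b": ni_b,
            "si": ni_a - ni_b,
            "single_exon_gene": single,
        },
        index=exon.feature_ids,
    )


def midas_pvalues(
    exon: ExpressionMatrix,
    exon_map: ExonMap,
    design: SampleDesign,
    groups: list[str],
) -> pd.Series:
    """One-way ANOVA p-value of the group effect on each exon's NI."""
    if len(groups) < 2:
        raise DesignError("MiDAS-style ANOVA needs >= 2 groups")
    col_sets = [_group_columns(design, exon, g) for g in groups]
    ni = normalized_intensities(exon, exon_map)
    arrays = [ni[cols].to_numpy() for cols in col_sets]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(*arrays, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.warning("%d exons have zero residual variance; p set to 1", int(degenerate.sum()))
        p[degenerate] = 1.0
    return pd.Series(p, index=exon.feature_ids, name="midas_p")


def splicing_table(
    exon: ExpressionMatrix,
    exon_map: ExonMap,
    design: SampleDesign,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """SI plus MiDAS-style p in one per-exon table for the two-group case."""
    table = splicing_index(exon, exon_map, design, group_a, group_b)
    table["midas_p"] = midas_pvalues(exon, exon_map, design, [group_a, group_b])
    return table


def select_spliced(
    table: pd.DataFrame,
    p_max: float = 0.05,
    si_min: float = 1.2,
) -> tuple[pd.DataFrame, int]:
    """Exons with midas_p <= p_max and |si| >= si_min, plus distinct-gene count."""
    keep = (table["midas_p"] <= p_max) & (table["si"].abs() >= si_min)
    selected = table[keep]
    return selected, int(selected["gene"].nunique())
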