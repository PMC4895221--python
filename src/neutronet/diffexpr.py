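"""Two-group differential expression, rank-based FDR and sample clustering.

Three conventions of microarray practice are implemented exactly:

* the signed linear fold change ``2^d`` for a log2 mean difference ``d >= 0``
  and ``-2^(-d)`` otherwise, so the magnitude is always >= 1;
* the rank-based FDR ``fdr = p * N / R`` with ``N`` the total number of tests
  in the family and ``R`` the ascending rank of the p-value — deliberately
  WITHOUT the cumulative-minimum monotonicity pass of step-up
  Benjamini-Hochberg (the two coincide before that pass);
* average-linkage Euclidean hierarchical clustering of samples after each
  feature is centred on its across-sample median (log2 data), with
  per-cluster majority accuracy against the phenotype design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import DesignError
from .io_formats import ExpressionMatrix, SampleDesign

logger = logging.getLogger("neutronet")

#: selection presets from the study design: genes are filtered on raw p and
#: linear fold change, miRNAs on the rank-based FDR
GENE_PRESET = {"p_max": 0.001, "fc_min": 1.5}
MIRNA_PRESET = {"fdr_max": 0.1}


def signed_fold_change(mean_a_log2: float, mean_b_log2: float) -> float:
    """Signed linear ratio of two log2 means; magnitude always >= 1."""
    d = mean_a_log2 - mean_b_log2
    return float(2.0 ** d) if d >= 0 else float(-(2.0 ** (-d)))


def custom_fdr(p_values, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """fdr_i = p_i * n_total / rank_i with stable ascending ranks.

    ``n_total`` may exceed the list length: the list is then interpreted as
    the significant head of a larger test family.  No monotonicity
    adjustment is applied, so the output can be non-monotone in p.
    """
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if n_total < len(p):
        raise ValueError(f"n_total={n_total} smaller than the number of p-values ({len(p)})")
    ranks = stats.rankdata(p, method="ordinal")  # ties broken by input order
    fdr = p * n_total / ranks
    return fdr, ranks.astype(int)


def t_test_table(
    expr: ExpressionMatrix,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    n_total: int | None = None,
    flavor: str = "welch",
) -> pd.DataFrame:
    """Per-feature two-sample t-test between two phenotypes.

    Returns a DataFrame indexed by feature id with columns ``mean_a``,
    ``mean_b``, ``t``, ``p``, ``rank``, ``signed_fc`` and ``fdr``; the FDR
    family size is carried in ``table.attrs['n_total']``.  ``flavor`` selects
    Welch (default, safer for unequal group sizes) or pooled-variance
    Student's t.  Features with zero variance in both groups get t = 0,
    p = 1.
    """
    if flavor not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test flavor: {flavor!r}")
    present = set(expr.sample_ids)
    samples_a = [s for s in design.samples_of(group_a) if s in present]
    samples_b = [s for s in design.samples_of(group_b) if s in present]
    for label, samples in ((group_a, samples_a), (group_b, samples_b)):
        if label not in design.group_sizes():
            raise DesignError(f"unknown phenotype label: {label!r}")
        if len(samples) < 2:
            raise DesignError(f"group {label!r} has {len(samples)} samples in the matrix; >= 2 required")

    a = expr.data[samples_a].to_numpy()
    b = expr.data[samples_b].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=(flavor == "pooled"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0

    if n_total is None:
        n_total = len(p)
    fdr, ranks = custom_fdr(p, n_total)
    fc = np.array([signed_fold_change(x, y) for x, y in zip(mean_a, mean_b)])
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t": t,
            "p": p,
            "rank": ranks,
            "signed_fc": fc,
            "fdr": fdr,
        },
        index=expr.feature_ids,
    )
    table.attrs["n_total"] = int(n_total)
    table.attrs["groups"] = (group_a, group_b)
    return table


def select_differential(
    table: pd.DataFrame,
    p_max: float | None = None,
    fc_min: float | None = None,
    fdr_max: float | None = None,
) -> pd.DataFrame:
    """Conjunction of the given criteria; fold change is gated on |signed_fc|."""
    if p_max is None and fc_min is None and fdr_max is None:
        raise ValueError("give at least one selection criterion")
    keep = pd.Series(True, index=table.index)
    if p_max is not None:
        keep &= table["p"] <= p_max
    if fc_min is not None:
        keep &= table["signed_fc"].abs() >= fc_min
    if fdr_max is not None:
        keep &= table["fdr"] <= fdr_max
    return table[keep]


@dataclass
class ClusterResult:
    """Sample -> cluster assignment (clusters numbered 1..k)."""

    labels: dict[str, int]
    linkage_matrix: np.ndarray = field(repr=False, default=None)

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sample, c in self.labels.items():
            out.setdefault(c, []).append(sample)
        return out


def median_normalize(expr: ExpressionMatrix, mode: str = "subtract") -> ExpressionMatrix:
    """Normalize each feature to its across-sample median.

    ``subtract`` (default) is appropriate for log2 data; ``ratio`` divides
    and is provided for linear-scale input.
    """
    med = expr.data.median(axis=1)
    if mode == "subtract":
        data = expr.data.sub(med, axis=0)
    elif mode == "ratio":
        data = expr.data.div(med, axis=0)
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    return ExpressionMatrix(data, expr.feature_kind)


def cluster_samples(
    expr: ExpressionMatrix,
    feature_subset,
    k: int,
    normalize: str = "subtract",
) -> ClusterResult:
    """Agglomerative clustering of samples (average linkage, Euclidean)."""
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise ValueError("feature_subset must be non-empty")
    if k > len(expr.sample_ids):
        raise ValueError(f"k={k} exceeds the number of samples ({len(expr.sample_ids)})")
    sub = ExpressionMatrix(expr.data.loc[feature_subset], expr.feature_kind)
    normed = median_normalize(sub, normalize)
    z = linkage(normed.values.T, method="average", metric="euclidean")
    assignment = fcluster(z, t=k, criterion="maxclust")
    labels = {s: int(c) for s, c in zip(expr.sample_ids, assignment)}
    return ClusterResult(labels=labels, linkage_matrix=z)


def cluster_accuracy(result: ClusterResult, design: SampleDesign) -> pd.DataFrame:
    """Per-cluster phenotype composition and majority accuracy.

    The modal phenotype of each cluster is its prediction; accuracy is the
    modal count over the cluster size (ties broken lexicographically by
    label).  Returned with both the exact proportion and the rounded whole
    percent.
    """
    rows = []
    for cluster, members in sorted(result.cluster_members().items()):
        counts: dict[str, int] = {}
        for s in members:
            label = design.phenotype_of(s)
            counts[label] = counts.get(label, 0) + 1
        modal = sorted(counts, key=lambda l: (-counts[l], l))[0]
        acc = counts[modal] / len(members)
        rows.append(
            {
                "cluster": cluster,
                "size": len(members),
                "modal_phenotype": modal,
                "composition": dict(sorted(counts.items())),
                "accuracy": acc,
                "accuracy_pct": int(round(100 * acc)),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
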