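"""Single-sample rank gene-set scoring (RE-score) and the miRNA-signature screen.

The regulatory effect score of a gene set in one sample is the mean
expression rank of the set's genes minus the mean rank of all other genes
in that sample (ascending ranks, so a positive score means the set is
expressed above background).  Being rank-based it is invariant to any
strictly monotone per-sample transform of the expression values.

The screen correlates, across matched samples, the RE-score vector of each
miRNA's target set with the RE-score vector of each immunologic signature.
The permutation null shuffles the gene identity labels of the expression
matrix once per replicate — shared across all sets, preserving inter-set
overlap structure — recomputes both score matrices, and counts replicates
whose correlation is larger (for positive observed correlations) or smaller
(for negative) than the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, SetCoverageError
from .io_formats import ExpressionMatrix, GeneSetCollection, TargetMap

logger = logging.getLogger("neutronet")


def sample_ranks(expr: ExpressionMatrix) -> pd.DataFrame:
    """Ascending within-sample ranks 1..G, average ranks for ties."""
    if len(expr.feature_ids) < 2:
        raise ValueError("ranking needs at least 2 features")
    ranks = stats.rankdata(expr.values, axis=0)
    return pd.DataFrame(ranks, index=expr.feature_ids, columns=expr.sample_ids)


@dataclass
class REScoreMatrix:
    """Gene-set x sample matrix of rank-difference scores."""

    scores: pd.DataFrame

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def _membership(sets: dict[str, frozenset[str]], features: pd.Index) -> tuple[np.ndarray, np.ndarray, list[str]]:
    feature_pos = {f: i for i, f in enumerate(features)}
    names = list(sets)
    G = len(features)
    M = np.zeros((len(names), G), dtype=bool)
    for i, name in enumerate(names):
        rows = [feature_pos[g] for g in sets[name] if g in feature_pos]
        if not rows:
            raise SetCoverageError(f"gene set {name!r} shares no genes with the expression matrix")
        if len(rows) == G:
            raise SetCoverageError(f"gene set {name!r} covers every gene in the matrix")
        M[i, rows] = True
    return M, M.sum(axis=1), names


def _scores_from_ranks(M: np.ndarray, sizes: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """score(set, sample) = mean in-set rank - mean out-of-set rank."""
    G = ranks.shape[0]
    total = G * (G + 1) / 2.0  # column rank sums are conserved, ties included
    sum_in = M.astype(float) @ ranks
    mean_in = sum_in / sizes[:, None]
    mean_out = (total - sum_in) / (G - sizes)[:, None]
    return mean_in - mean_out


def _as_set_dict(sets) -> dict[str, frozenset[str]]:
    if isinstance(sets, GeneSetCollection):
        return {name: members for name, (_d, members) in sets.sets.items()}
    if isinstance(sets, TargetMap):
        return dict(sets.targets)
    return {name: frozenset(members) for name, members in dict(sets).items()}


def re_scores(ranks: pd.DataFrame, sets) -> REScoreMatrix:
    """RE-scores for a GeneSetCollection, TargetMap, or name->genes mapping.

    Each set is intersected with the rank matrix's features; an empty or
    all-gene intersection raises SetCoverageError naming the set.
    """
    set_dict = _as_set_dict(sets)
    M, sizes, names = _membership(set_dict, ranks.index)
    scores = _scores_from_ranks(M, sizes, ranks.to_numpy())
    return REScoreMatrix(pd.DataFrame(scores, index=names, columns=ranks.columns))


@dataclass(frozen=True)
class SignatureAssociation:
    mirna: str
    signature: str
    pearson_r: float
    spearman_rho: float
    perm_p: float | None = None
    sign: str = "positive"  # positive / negative by Pearson r
    degenerate: bool = False


def _row_standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled to zero mean, unit norm; zero-variance rows left at 0."""
    centred = a - a.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    return centred / safe[:, None], norms == 0


def signature_associations(
    ranks: pd.DataFrame,
    mirna_sets,
    signature_sets,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[SignatureAssociation]:
    """Correlate every (miRNA target set, signature) RE-score pair.

    ``ranks`` is the within-sample rank matrix of the expression data (see
    :func:`sample_ranks`), typically restricted to one phenotype's samples.
    Pearson r gates the permutation p-value; Spearman rho is recorded
    alongside.  Degenerate (constant) score vectors are flagged with r = 0.
    """
    if len(ranks.columns) < 3:
        raise DesignError("signature associations need >= 3 matched samples")
    mirna_dict = _as_set_dict(mirna_sets)
    sig_dict = _as_set_dict(signature_sets)
    Mm, sizes_m, names_m = _membership(mirna_dict, ranks.index)
    Ms, sizes_s, names_s = _membership(sig_dict, ranks.index)
    R = ranks.to_numpy()
    S = R.shape[1]

    A = _scores_from_ranks(Mm, sizes_m, R)
    B = _scores_from_ranks(Ms, sizes_s, R)
    Za, dega = _row_standardize(A)
    Zb, degb = _row_standardize(B)
    obs = Za @ Zb.T
    degenerate = dega[:, None] | degb[None, :]
    obs[degenerate] = 0.0
    Ra, _ = _row_standardize(np.apply_along_axis(stats.rankdata, 1, A))
    Rb, _ = _row_standardize(np.apply_along_axis(stats.rankdata, 1, B))
    rho = Ra @ Rb.T
    rho[degenerate] = 0.0

    perm_p: np.ndarray | None = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros_like(obs, dtype=int)
        pos = obs >= 0
        for _ in range(n_perm):
            order = rng.permutation(R.shape[0])
            Rp = R[order]
            Zp_a, _ = _row_standardize(_scores_from_ranks(Mm, sizes_m, Rp))
            Zp_b, _ = _row_standardize(_scores_from_ranks(Ms, sizes_s, Rp))
            C = Zp_a @ Zp_b.T
            exceed += np.where(pos, C >= obs, C <= obs)
        perm_p = exceed / n_perm

    out: list[SignatureAssociation] = []
    for i, m in enumerate(names_m):
        for j, s in enumerate(names_s):
            out.append(
                SignatureAssociation(
                    mirna=m,
                    signature=s,
                    pearson_r=float(obs[i, j]),
                    spearman_rho=float(rho[i, j]),
                    perm_p=None if perm_p is None else float(perm_p[i, j]),
                    sign="positive" if obs[i, j] >= 0 else "negative",
                    degenerate=bool(degenerate[i, j]),
                )
            )
    return out


@dataclass
class AssociationSelection:
    positive: list[SignatureAssociation]
    negative: list[SignatureAssociation]
    per_mirna: dict[str, int] = field(default_factory=dict)
    per_signature: dict[str, int] = field(default_factory=dict)


def select_associations(
    associations: list[SignatureAssociation],
    cutoff: float = 0.9,
    p_max: float = 1e-3,
) -> AssociationSelection:
    """Significant associations at |r| >= cutoff with perm_p < p_max.

    The cutoff gates Pearson r (Spearman is recorded but not gated); the
    per-miRNA and per-signature tallies count selected associations of
    either sign.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    positive, negative = [], []
    per_mirna: dict[str, int] = {}
    per_signature: dict[str, int] = {}
    for a in associations:
        if a.perm_p is None or a.perm_p >= p_max:
            continue
        if a.pearson_r >= cutoff:
            positive.append(a)
        elif a.pearson_r <= -cutoff:
            negative.append(a)
        else:
            continue
        per_mirna[a.mirna] = per_mirna.get(a.mirna, 0) + 1
        per_signature[a.signature] = per_signature.get(a.signature, 0) + 1
    return AssociationSelection(positive, negative, per_mirna, per_signature)
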