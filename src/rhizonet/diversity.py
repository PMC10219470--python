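"""Rarefaction, alpha diversity, Bray-Curtis ordination, and ANOSIM.

The ordination pipeline mirrors the standard community-ecology workflow:
subsample each community to a common depth, compute Bray-Curtis
dissimilarities, embed them by principal coordinate analysis (Gower
double-centering + eigendecomposition), and test group separation with the
rank-based ANOSIM permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

DEFAULT_RAREFACTION_DEPTH = 30815


def rarefy(table: pd.DataFrame, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int | None = 0) -> pd.DataFrame:
    """Subsample every sample, without replacement, to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning naming
    them; if nothing survives the call fails.  Drawing without replacement
    makes each rarefied count multivariate-hypergeometric given the
    original sample.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=1)
    short = totals.index[totals < depth].tolist()
    if len(short) == len(table):
        raise ValueError(f"all samples have fewer than {depth} reads (max {int(totals.max())})")
    if short:
        warnings.warn(f"dropping {len(short)} sample(s) below depth {depth}: {short}",
                      stacklevel=2)
    kept = table.drop(index=short)
    out = np.empty(kept.shape, dtype=np.int64)
    for i, (_, row) in enumerate(kept.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    return pd.DataFrame(out, index=kept.index, columns=kept.columns)


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample observed richness and Shannon entropy (natural log)."""
    totals = table.sum(axis=1)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"all-zero sample(s): {empty}")
    counts = table.to_numpy(float)
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.DataFrame({
        "richness": (counts > 0).sum(axis=1),
        "shannon": -plogp.sum(axis=1),
    }, index=table.index)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y)."""
    if len(table) < 2:
        raise ValueError("need at least 2 samples")
    x = table.to_numpy(float)
    zero = table.index[x.sum(axis=1) == 0].tolist()
    if len(zero) >= 2:
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {zero}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def _check_distance_matrix(d: pd.DataFrame) -> np.ndarray:
    m = d.to_numpy(float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    return m


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates on positive-eigenvalue axes,
    per-axis explained fraction (relative to the positive eigenvalue sum),
    and the full eigenvalue spectrum including any negative values."""
    coordinates: pd.DataFrame
    explained: np.ndarray
    eigenvalues: np.ndarray


def pcoa(d: pd.DataFrame) -> OrdinationResult:
    """Principal coordinate analysis via Gower double-centering.

    B = -J (d**2 / 2) J with J the centering matrix; eigenvectors scaled by
    sqrt(eigenvalue) give the coordinates.  Axes with eigenvalue <= 0 carry
    no coordinates; negative eigenvalues (possible for semi-metric inputs
    like Bray-Curtis) are reported but excluded from the explained-variance
    denominator.  No Lingoes/Cailliez correction is applied.
    """
    m = _check_distance_matrix(d)
    n = m.shape[0]
    a = -0.5 * m ** 2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    explained = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.index, columns=axes),
        explained=explained,
        eigenvalues=evals,
    )


@dataclass
class AnosimResult:
    """ANOSIM test statistic R in [-1, 1] and its permutation p-value."""
    r: float
    p_value: float
    n_permutations: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    n_pairs = ranks.size
    mean_within = ranks[within].mean()
    mean_between = ranks[~within].mean()
    return (mean_between - mean_within) / (n_pairs / 2.0)


def anosim(d: pd.DataFrame, groups, n_permutations: int = 999,
           seed: int | None = 0) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2), with
    ranks (average on ties) over all M = n(n-1)/2 pairwise distances.  The
    p-value permutes group labels and counts ties as exceedances:
    p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations).
    """
    m = _check_distance_matrix(d)
    labels = np.asarray(pd.Series(groups).reindex(d.index) if isinstance(groups, pd.Series)
                        else groups)
    if len(labels) != len(d):
        raise ValueError("group labels do not match the distance matrix")
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(m[iu, ju])
    codes = pd.factorize(labels)[0]
    r_obs = _anosim_r(ranks, codes[iu] == codes[ju])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    within = perms[:, iu] == perms[:, ju]           # (n_perm, M)
    n_pairs = ranks.size
    sum_within = within @ ranks
    cnt_within = within.sum(axis=1)
    mean_within = sum_within / cnt_within
    mean_between = (ranks.sum() - sum_within) / (n_pairs - cnt_within)
    r_perm = (mean_between - mean_within) / (n_pairs / 2.0)
    exceed = int(np.sum(r_perm >= r_obs - 1e-12))
    p = (1 + exceed) / (1 + n_permutations)
    return AnosimResult(r=float(r_obs), p_value=float(p), n_permutations=n_permutations)
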