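"""Beta diversity: Sorensen-family partition and neighbor-joining clustering.

Compositional dissimilarity between sites is measured with the
Sorensen-based index and partitioned into a turnover component
(species replacement, insensitive to richness differences) and a
nestedness-resultant component (richness-difference dissimilarity
among nested assemblages):

pairwise, with ``a`` shared species and ``b``, ``c`` unique to each site::

    beta_sim = min(b, c) / (a + min(b, c))
    beta_sor = (b + c) / (2a + b + c)
    beta_sne = beta_sor - beta_sim

multi-site, with per-site richness ``S_i``, pooled richness ``S_T`` and
``b_ij`` the number of species in site ``i`` absent from ``j``::

    beta_SIM = sum_min / (sum_min + (sum S_i - S_T))
    beta_SOR = (sum_min + sum_max) / (2 (sum S_i - S_T) + sum_min + sum_max)
    beta_SNE = beta_SOR - beta_SIM

where ``sum_min = sum_{i<j} min(b_ij, b_ji)`` and ``sum_max`` the
analogous maximum.  The additivity ``beta_sor = beta_sim + beta_sne``
holds identically in both forms.

Pairwise turnover distances feed an unrooted neighbor-joining tree
(scikit-bio's implementation) used to cluster trapping locations by
community similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .exceptions import ValidationError
from .survey import IncidenceMatrix


@dataclass(frozen=True)
class BetaPartition:
    """A Sorensen partition: total, turnover and nestedness components."""

    beta_sor: float
    beta_sim: float
    beta_sne: float
    scope: str  # "pairwise" or "multisite"
    n_sites: int
    n_species: int


@dataclass
class PairwiseBeta:
    """Square matrices of pairwise beta components over a site set."""

    sor: pd.DataFrame
    sim: pd.DataFrame
    sne: pd.DataFrame


def _presence_array(m: IncidenceMatrix | pd.DataFrame) -> tuple[np.ndarray, list]:
    if isinstance(m, IncidenceMatrix):
        return m.presence.to_numpy(dtype=bool), list(m.presence.index)
    df = pd.DataFrame(m).astype(bool)
    return df.to_numpy(), list(df.index)


def pairwise_components(x_i, x_j) -> tuple[int, int, int]:
    """Shared/unique species counts (a, b, c) for two presence vectors."""
    x_i = np.asarray(x_i, dtype=bool)
    x_j = np.asarray(x_j, dtype=bool)
    a = int((x_i & x_j).sum())
    b = int((x_i & ~x_j).sum())
    c = int((~x_i & x_j).sum())
    return a, b, c


def pairwise_partition(m: IncidenceMatrix | pd.DataFrame) -> PairwiseBeta:
    """All pairwise Sorensen partitions between sites.

    Pairs where both sites are empty have no defined dissimilarity and
    are reported as NaN (never silently 0, which would corrupt any
    clustering built on the matrix).
    """
    x, sites = _presence_array(m)
    n = len(sites)
    if n < 2:
        raise ValidationError("pairwise beta diversity needs at least 2 sites")
    sor = np.zeros((n, n))
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b, c = pairwise_components(x[i], x[j])
            if a + b + c == 0:
                s_sor = s_sim = np.nan
            else:
                mn = min(b, c)
                s_sim = mn / (a + mn) if (a + mn) > 0 else 0.0
                s_sor = (b + c) / (2 * a + b + c)
            sor[i, j] = sor[j, i] = s_sor
            sim[i, j] = sim[j, i] = s_sim
    sne = sor - sim
    labels = [f"{s[0]}:{s[1]}" if isinstance(s, tuple) else str(s) for s in sites]
    mk = lambda arr: pd.DataFrame(arr, index=labels, columns=labels)
    return PairwiseBeta(sor=mk(sor), sim=mk(sim), sne=mk(sne))


def multisite_partition(m: IncidenceMatrix | pd.DataFrame) -> BetaPartition:
    """Multi-site Sorensen partition over all sites at once.

    Sites with zero species carry no compositional information and are
    excluded with a warning.
    """
    x, sites = _presence_array(m)
    if x.shape[0] < 2:
        raise ValidationError("multi-site beta diversity needs at least 2 sites")
    empty = ~x.any(axis=1)
    if empty.any():
        warnings.warn(
            f"excluding {int(empty.sum())} site(s) with zero species from the "
            "multi-site partition",
            stacklevel=2,
        )
        x = x[~empty]
        if x.shape[0] < 2:
            raise ValidationError("fewer than 2 non-empty sites")
    s_i = x.sum(axis=1)
    s_t = int(x.any(axis=0).sum())
    shared = (x.astype(int) @ x.astype(int).T)
    b = s_i[:, None] - shared  # b[i, j] = species in i absent from j
    iu = np.triu_indices(x.shape[0], k=1)
    sum_min = float(np.minimum(b[iu], b.T[iu]).sum())
    sum_max = float(np.maximum(b[iu], b.T[iu]).sum())
    core = float(s_i.sum() - s_t)
    beta_sim = sum_min / (sum_min + core) if (sum_min + core) > 0 else 0.0
    denom = 2 * core + sum_min + sum_max
    beta_sor = (sum_min + sum_max) / denom if denom > 0 else 0.0
    return BetaPartition(
        beta_sor=beta_sor,
        beta_sim=beta_sim,
        beta_sne=beta_sor - beta_sim,
        scope="multisite",
        n_sites=int(x.shape[0]),
        n_species=s_t,
    )


def to_distance_matrix(square: pd.DataFrame) -> DistanceMatrix:
    """Validate a square dissimilarity table into a DistanceMatrix.

    Labels are sorted so that downstream tie-breaking in the clustering
    is deterministic.
    """
    arr = square.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValidationError(
            "distance matrix contains undefined (NaN) dissimilarities"
        )
    if not np.allclose(arr, arr.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0):
        raise ValidationError("distance matrix must have a zero diagonal")
    order = sorted(square.index)
    square = square.loc[order, order]
    return DistanceMatrix(square.to_numpy(dtype=float), ids=list(square.index))


def nj_tree(d: DistanceMatrix | pd.DataFrame) -> TreeNode:
    """Unrooted neighbor-joining tree from a site dissimilarity matrix.

    Negative branch lengths (which NJ can produce on non-additive
    input) are clamped to zero with a warning; the raw estimate is kept
    on each node as ``raw_length``.
    """
    if isinstance(d, pd.DataFrame):
        d = to_distance_matrix(d)
    if d.shape[0] < 3:
        raise ValidationError("neighbor-joining needs at least 3 sites")
    tree = _skbio_nj(d, neg_as_zero=False)
    n_clamped = 0
    for node in tree.traverse(include_self=False):
        node.raw_length = node.length
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        warnings.warn(
            f"clamped {n_clamped} negative NJ branch length(s) to 0 "
            "(raw values kept as node.raw_length)",
            stacklevel=2,
        )
    return tree


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialise a tree to Newick (with branch lengths); optionally to file."""
    s = str(tree).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s
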