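"""Genetic diversity analyses on the reference fingerprint dataset.

Distances are identity-by-state (IBS): one minus the allele-sharing
fraction over pairwise-complete markers, the same sharing convention
used for replicate identity QC.  IBS distances are symmetric with a zero
diagonal and live in [0, 1]; they are not guaranteed to satisfy the
triangle inequality.

On top of the distance matrix the module provides the distance
distribution binned at breeding-relevant breaks (including the 0.05
relatedness guard below which a new line is considered too close to an
existing one), mean within/between-subgroup distances, principal
component analysis of minor-allele dosages, Saitou–Nei neighbor-joining
trees, and parent–conversion distance tables.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .reference import ReferenceDataset
from .sample_qc import _pairwise_similarity, similarity_rate


def ibs_distance(a: np.ndarray, b: np.ndarray) -> float:
    """IBS distance between two genotype call vectors: 1 - similarity."""
    return 1.0 - similarity_rate(a, b)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, NaN where undefined

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def pair_values(self) -> np.ndarray:
        """Unordered distinct-pair distances (upper triangle)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def lookup(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def distance_matrix(
    data: Union[ReferenceDataset, GenotypeMatrix],
    labels: Optional[Sequence[str]] = None,
) -> DistanceMatrix:
    """All-pairs IBS distance matrix.

    For a :class:`ReferenceDataset` the labels are line names; for a raw
    :class:`GenotypeMatrix` they default to sample ids.  Pairs with no
    mutually non-missing marker propagate as NaN with a warning.
    """
    matrix = data.matrix if isinstance(data, ReferenceDataset) else data
    if matrix.n_samples < 2:
        raise ValueError("distance matrix needs at least two samples")
    if labels is None:
        labels = (
            data.line_names
            if isinstance(data, ReferenceDataset)
            else matrix.sample_ids
        )
    sim = _pairwise_similarity(matrix)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    n_undef = int(np.isnan(dist[np.triu_indices(matrix.n_samples, k=1)]).sum())
    if n_undef:
        warnings.warn(f"{n_undef} pair(s) share no called marker; distance NaN")
    return DistanceMatrix(labels=list(labels), values=dist)


@dataclass
class DistanceBins:
    table: pd.DataFrame  # bin edges and pair fractions (percent)
    zero_pairs: list[tuple[str, str]]
    n_pairs_below_guard: int
    guard: float
    n_pairs: int


def bin_distances(
    dm: DistanceMatrix,
    breaks: Sequence[float] = (0.05, 0.10, 0.30, 0.50),
    guard: float = 0.05,
) -> DistanceBins:
    """Histogram of pairwise distances over unordered distinct pairs.

    Bins are ``[0, b1], (b1, b2], ..., (bk, 1]``; fractions are percent
    and sum to 100.  Exact-zero pairs and pairs at or below the
    relatedness guard are reported alongside.
    """
    vals = dm.pair_values()
    defined = vals[~np.isnan(vals)]
    edges = [0.0] + sorted(breaks) + [1.0]
    counts, _ = np.histogram(defined, bins=edges)
    # np.histogram bins are half-open [lo, hi); report (lo, hi] to match
    # "greater than" phrasing, recount explicitly
    counts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == 0.0:
            counts.append(int(((defined >= 0.0) & (defined <= hi)).sum()))
        else:
            counts.append(int(((defined > lo) & (defined <= hi)).sum()))
    n = len(defined)
    table = pd.DataFrame(
        {
            "lower": edges[:-1],
            "upper": edges[1:],
            "n_pairs": counts,
            "fraction_pct": [100.0 * c / n if n else np.nan for c in counts],
        }
    )
    iu = np.triu_indices(dm.n, k=1)
    zero_pairs = [
        (dm.labels[i], dm.labels[j])
        for i, j in zip(*iu)
        if dm.values[i, j] == 0.0
    ]
    below = int((defined < guard).sum())
    return DistanceBins(
        table=table,
        zero_pairs=zero_pairs,
        n_pairs_below_guard=below,
        guard=guard,
        n_pairs=n,
    )


def subgroup_distances(
    dm: DistanceMatrix, groups: Mapping[str, Optional[str]]
) -> pd.DataFrame:
    """Mean within- and between-group IBS distances.

    ``groups`` maps each label to its group (subgroup or heterotic
    group); labels mapping to None are left out.  Within-group means use
    unordered distinct pairs; between-group means the full cross
    product.  Groups with fewer than two members get NaN within-means.
    """
    idx_by_group: dict[str, list[int]] = {}
    for i, label in enumerate(dm.labels):
        g = groups.get(label)
        if g is not None:
            idx_by_group.setdefault(g, []).append(i)
    names = sorted(idx_by_group)
    rows = []
    for a, b in itertools.combinations_with_replacement(names, 2):
        ia, ib = idx_by_group[a], idx_by_group[b]
        if a == b:
            pairs = [dm.values[i, j] for i, j in itertools.combinations(ia, 2)]
        else:
            pairs = dm.values[np.ix_(ia, ib)].ravel().tolist()
        vals = np.asarray(pairs, dtype=float)
        vals = vals[~np.isnan(vals)]
        rows.append(
            (
                a,
                b,
                float(vals.mean()) if len(vals) else np.nan,
                int(len(vals)),
            )
        )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_distance", "n_pairs"]
    )


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # index: labels; columns PC1..PCk
    explained_variance_ratio: np.ndarray


def pca(
    data: Union[ReferenceDataset, GenotypeMatrix],
    n_components: int = 3,
    labels: Optional[Sequence[str]] = None,
) -> PCAResult:
    """Principal components of the minor-allele dosage matrix.

    Genotypes are encoded as 0/1/2 dosages, missing values imputed to
    the marker mean, columns centred (no variance scaling), and the
    centred matrix decomposed by SVD.  Component signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    matrix = data.matrix if isinstance(data, ReferenceDataset) else data
    if labels is None:
        labels = (
            data.line_names
            if isinstance(data, ReferenceDataset)
            else matrix.sample_ids
        )
    if matrix.n_samples < 2 or matrix.n_markers < 2:
        raise ValueError("PCA needs at least two samples and two markers")
    X = matrix.dosage().astype(float)
    X[X < 0] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = col_mean[nan_idx[1]]
    X -= X.mean(axis=0)
    total_ss = float((X**2).sum())
    if total_ss == 0.0:
        raise ValueError("dosage matrix has zero variance; PCA undefined")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    signs = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    coords = (U[:, :k] * S[:k]) * signs[:k]
    evr = S**2 / (S**2).sum()
    return PCAResult(
        coordinates=pd.DataFrame(
            coords, index=list(labels), columns=[f"PC{i+1}" for i in range(k)]
        ),
        explained_variance_ratio=evr[:k],
    )


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class NJTree:
    newick: str
    tree: dendropy.Tree


def nj_tree(dm: DistanceMatrix) -> NJTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Q-matrix ties are broken by the lowest (row, column) index pair;
    negative branch-length estimates are clamped to zero with the length
    transferred to the sibling edge.  Fewer than three labels yields a
    degenerate tree with a warning.
    """
    D = np.array(dm.values, dtype=float)
    if np.isnan(D).any():
        raise ValueError("NJ requires finite distances")
    nodes = [_quote(l) for l in dm.labels]
    n = len(nodes)
    if n < 2:
        raise ValueError("NJ needs at least two labels")
    if n == 2:
        warnings.warn("fewer than three labels: degenerate single-edge tree")
        half = D[0, 1] / 2.0
        newick = f"({nodes[0]}:{half:.10g},{nodes[1]}:{half:.10g});"
        return _as_njtree(newick)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        Q[np.tril_indices(m)] = np.inf
        # argmin scans row-major: first occurrence = lowest (row, col)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        if li < 0:
            li, lj = 0.0, d_ij
        elif lj < 0:
            li, lj = d_ij, 0.0
        ai, aj = active[i], active[j]
        new = f"({nodes[ai]}:{li:.10g},{nodes[aj]}:{lj:.10g})"
        # distances from the new node u to every other active node k
        d_new = {}
        for k in active:
            if k in (ai, aj):
                continue
            d_new[k] = max(0.5 * (D[ai, k] + D[aj, k] - d_ij), 0.0)
        nodes[ai] = new  # reuse slot ai for the merged node
        for k, v in d_new.items():
            D[ai, k] = D[k, ai] = v
        active.remove(aj)

    a, b, c = active
    la = max(0.5 * (D[a, b] + D[a, c] - D[b, c]), 0.0)
    lb = max(0.5 * (D[a, b] + D[b, c] - D[a, c]), 0.0)
    lc = max(0.5 * (D[a, c] + D[b, c] - D[a, b]), 0.0)
    newick = (
        f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"
    )
    return _as_njtree(newick)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ():,;[]'\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _as_njtree(newick: str) -> NJTree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return NJTree(newick=newick, tree=tree)


# ---------------------------------------------------------------------------
# parent-offspring / conversion tests


def conversion_test(
    pairs: Sequence[tuple[str, str]],
    dm: DistanceMatrix,
    closeness_threshold: float = 0.20,
) -> pd.DataFrame:
    """IBS distance between each (original parent, converted line) pair.

    A conversion is expected to sit close to its recurrent parent; pairs
    whose distance exceeds ``closeness_threshold`` are flagged for
    review.  Pairs with a line absent from the reference are reported
    with a MISSING status and skipped.
    """
    labels = set(dm.labels)
    rows = []
    for parent, converted in pairs:
        if parent not in labels or converted not in labels:
            missing = [x for x in (parent, converted) if x not in labels]
            rows.append((parent, converted, np.nan, False, f"MISSING:{','.join(missing)}"))
            continue
        d = dm.lookup(parent, converted)
        rows.append((parent, converted, d, d > closeness_threshold, "OK"))
    return pd.DataFrame(
        rows,
        columns=["parent", "converted", "distance", "exceeds_threshold", "status"],
    )
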