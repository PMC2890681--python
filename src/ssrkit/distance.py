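"""Pairwise distances, trees, ordination and nearest-partner assignment.

Jaccard distance on allelic phenotypes — d = 1 - |A ∩ B| / |A ∪ B| over
(locus, allele) presence columns — deliberately ignores absence/absence
pairs, whose count is inflated by dominant scoring of a codominant marker.
Columns of a locus missing in either member of a pair are skipped, so a
dropout never masquerades as absence.  Trees come from neighbour-joining
(Saitou & Nei, via scikit-bio), ordination from classical principal
coordinates (Gower double-centering), and plants are assigned to varieties
by the majority origin of their k most similar partner plants panel-wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PhenotypeMatrix

__all__ = [
    "DistanceResult",
    "AssignmentResult",
    "jaccard_distance",
    "neighbor_joining",
    "pco",
    "assign_knn",
]


@dataclass
class DistanceResult:
    """Symmetric distance matrix with labels and a metric tag."""

    labels: list
    values: np.ndarray
    metric: str = "jaccard"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        with np.errstate(invalid="ignore"):
            if not np.allclose(v, v.T, equal_nan=True):
                raise ValueError("distance matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class AssignmentResult:
    """k-nearest-partner variety assignment.

    ``assignments`` — per plant: true variety, assigned variety, whether
    they agree; ``correct_by_variety`` — per variety, count of its plants
    assigned back to it; ``similarity_by_assignment`` — Sa[x, y], the
    fraction of variety x's plants' top-k partners that originate from
    variety y (each row sums to 1).
    """

    k: int
    assignments: pd.DataFrame
    correct_by_variety: pd.Series
    similarity_by_assignment: pd.DataFrame


def _pairwise_jaccard(X: np.ndarray, scored: np.ndarray, slices: list[slice]) -> np.ndarray:
    """Masked pairwise Jaccard: columns of a locus count only for co-scored pairs."""
    n = X.shape[0]
    inter = np.zeros((n, n))
    union = np.zeros((n, n))
    for l, sl in enumerate(slices):
        Xl = X[:, sl]
        s = scored[:, l].astype(float)
        I = Xl @ Xl.T
        c = Xl.sum(axis=1)
        both = np.outer(s, s)
        inter += both * I
        union += both * (c[:, None] + c[None, :] - I)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def _matrix_arrays(matrix: PhenotypeMatrix):
    X = matrix.data.to_numpy(dtype=float)
    scored = ~matrix.missing.to_numpy()
    cols = matrix.data.columns.get_level_values(0)
    slices, start = [], 0
    for loc in matrix.locus_names:
        width = int((cols == loc).sum())
        slices.append(slice(start, start + width))
        start += width
    return X, scored, slices


def jaccard_distance(matrix: PhenotypeMatrix, level: str = "plant") -> DistanceResult:
    """Pairwise Jaccard distances between plants or variety consensus profiles.

    At variety level the profile is the union of plant presences (any
    carrier => present) and a locus is missing only if all of the
    variety's plants dropped out there.  Pairs with no co-scored locus get
    NaN with a warning.
    """
    if level == "plant":
        X, scored, slices = _matrix_arrays(matrix)
        labels = matrix.plant_ids
    elif level == "variety":
        varieties = list(dict.fromkeys(matrix.meta["variety"]))
        X_p, scored_p, slices = _matrix_arrays(matrix)
        X = np.zeros((len(varieties), X_p.shape[1]))
        scored = np.zeros((len(varieties), len(slices)), dtype=bool)
        for i, v in enumerate(varieties):
            rows = (matrix.meta["variety"] == v).to_numpy()
            X[i] = X_p[rows].max(axis=0)
            scored[i] = scored_p[rows].any(axis=0)
        labels = varieties
    else:
        raise ValueError("level must be 'plant' or 'variety'")
    d = _pairwise_jaccard(X, scored, slices)
    off = d[~np.eye(len(labels), dtype=bool)]
    if np.isnan(off).any():
        warnings.warn("some pairs share no co-scored locus; distances undefined (NaN)")
    return DistanceResult(list(labels), d, metric="jaccard")


def neighbor_joining(d: DistanceResult, clamp_negative: bool = False):
    """Neighbour-joining tree (unrooted) from a distance matrix.

    Wraps scikit-bio's Saitou & Nei implementation; negative branch
    lengths are retained as computed unless ``clamp_negative``.  Ties in
    the Q-criterion resolve deterministically in input label order.
    """
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    if len(d.labels) < 3:
        raise ValueError("neighbour-joining needs >= 3 labels")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix has undefined entries")
    tree = nj(SkbioDM(d.values, ids=[str(l) for l in d.labels]))
    if clamp_negative:
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
    return tree


def pco(d: DistanceResult, k: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical principal coordinates (metric MDS).

    Gower double-centering of -d^2/2 followed by eigendecomposition;
    coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues.  All eigenvalues are returned unaltered (negative ones
    flag non-Euclidean distances); asking for more axes than there are
    positive eigenvalues truncates with a warning.
    """
    from scipy.linalg import eigh

    D = d.values
    if np.isnan(D).any():
        raise ValueError("distance matrix has undefined entries")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-9 * max(abs(eigvals[0]), 1.0)
    n_pos = int(pos.sum())
    if k is None:
        k = n_pos
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating to {n_pos} axes")
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    frame = pd.DataFrame(
        coords, index=d.labels, columns=[f"PCo{i + 1}" for i in range(k)]
    )
    return frame, eigvals


def assign_knn(matrix: PhenotypeMatrix, k: int = 10) -> AssignmentResult:
    """Assign each plant to the majority variety of its k most similar partners.

    Similarity is 1 - Jaccard distance, computed panel-wide with self
    excluded.  Variety ties among the partners are broken by the summed
    similarity of the tied varieties' partners.  Sa[x, y] aggregates the
    partner origins of variety x's plants and each row sums to 1.
    """
    n = len(matrix.plant_ids)
    if not (1 <= k < n):
        raise ValueError(f"k must be in [1, {n - 1}]")
    d = jaccard_distance(matrix, level="plant")
    sim = 1.0 - d.values
    np.fill_diagonal(sim, -np.inf)
    sim = np.where(np.isnan(sim), -np.inf, sim)
    varieties = matrix.meta["variety"].to_numpy()
    variety_list = list(dict.fromkeys(varieties))

    assigned = []
    partner_counts = {v: pd.Series(0.0, index=variety_list) for v in variety_list}
    for i in range(n):
        order = np.argsort(-sim[i], kind="stable")[:k]
        part_vars = varieties[order]
        part_sims = sim[i, order]
        tally: dict = {}
        weight: dict = {}
        for v, s in zip(part_vars, part_sims):
            tally[v] = tally.get(v, 0) + 1
            weight[v] = weight.get(v, 0.0) + s
        best = max(tally.items(), key=lambda kv: (kv[1], weight[kv[0]]))[0]
        assigned.append(best)
        pc = partner_counts[varieties[i]]
        for v, c in tally.items():
            pc[v] += c
    assignments = pd.DataFrame(
        {
            "variety": varieties,
            "assigned": assigned,
        },
        index=pd.Index(matrix.plant_ids, name="plant_id"),
    )
    assignments["correct"] = assignments["variety"] == assignments["assigned"]
    correct = (
        assignments[assignments["correct"]].groupby("variety").size().reindex(variety_list).fillna(0).astype(int)
    )
    sa = pd.DataFrame(
        {v: partner_counts[v] / partner_counts[v].sum() for v in variety_list}
    ).T
    sa.index.name = "variety"
    return AssignmentResult(k, assignments, correct, sa)
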