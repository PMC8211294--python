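"""Pedigree-derived relatedness and genotype clustering.

Relatedness between breeding lines is computed as Wright's numerator
relationship matrix A via the tabular (recursive) method, normalized to a
correlation matrix C (C_ij = A_ij / sqrt(A_ii A_jj)), and genotypes are
partitioned by K-means on the rows of C, each genotype being represented by
its correlation profile.  The resulting hard cluster ID is the reduced
pedigree representation fed to the yield models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ConfigurationError, MatrixError, PedigreeError

__all__ = [
    "RelationshipMatrix",
    "ClusterAssignment",
    "build_relationship_matrix",
    "to_correlation",
    "kmeans_cluster",
    "inertia_curve",
]

UNKNOWN_TOKENS = {"NA", "", "0", "NaN", "nan", None}


@dataclass
class RelationshipMatrix:
    """Symmetric relatedness matrix with its genotype-ID ordering."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MatrixError(f"matrix shape {self.values.shape} does not match {n} ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class ClusterAssignment:
    """Hard partition of genotypes into K clusters with the attained inertia."""

    labels: dict[str, int]
    k: int
    inertia: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"genotype_id": list(self.labels), "cluster_id": list(self.labels.values())}
        )


def _is_unknown(x) -> bool:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return True
    return str(x) in UNKNOWN_TOKENS


def _toposort(ped: pd.DataFrame) -> list[int]:
    """Order rows parents-before-offspring; raise PedigreeError on cycles."""
    ids = list(ped["id"].astype(str))
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise PedigreeError(f"duplicate individual id {dup!r}")
    index = {g: i for i, g in enumerate(ids)}
    parents = []
    for _, row in ped.iterrows():
        ps = []
        for col in ("parent1", "parent2"):
            p = row[col]
            if not _is_unknown(p):
                p = str(p)
                if p not in index:
                    raise PedigreeError(f"parent {p!r} of {row['id']!r} not in pedigree")
                ps.append(index[p])
        parents.append(ps)

    state = np.zeros(len(ids), dtype=int)  # 0 unvisited, 1 in stack, 2 done
    order: list[int] = []

    def visit(i: int) -> None:
        stack = [(i, 0)]
        while stack:
            node, pi = stack.pop()
            if pi == 0:
                if state[node] == 1:
                    raise PedigreeError(f"pedigree cycle involving {ids[node]!r}")
                if state[node] == 2:
                    continue
                state[node] = 1
            if pi < len(parents[node]):
                stack.append((node, pi + 1))
                child = parents[node][pi]
                if state[child] == 1:
                    raise PedigreeError(f"pedigree cycle involving {ids[child]!r}")
                if state[child] == 0:
                    stack.append((child, 0))
            else:
                state[node] = 2
                order.append(node)

    for i in range(len(ids)):
        if state[i] == 0:
            visit(i)
    return order


def build_relationship_matrix(ped: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    A_ii = 1 + 0.5 * A_{p1,p2} (inbreeding from related parents) and
    A_ij = 0.5 * (A_{j,p1} + A_{j,p2}); unknown parents contribute zero and
    are treated as unrelated, non-inbred founders.
    """
    ids = list(ped["id"].astype(str))
    order = _toposort(ped)
    index = {g: i for i, g in enumerate(ids)}
    par: list[list[int]] = []
    for _, row in ped.iterrows():
        par.append(
            [index[str(row[c])] for c in ("parent1", "parent2") if not _is_unknown(row[c])]
        )

    n = len(ids)
    A = np.zeros((n, n))
    done: list[int] = []
    for i in order:
        ps = par[i]
        if len(ps) == 2:
            A[i, i] = 1.0 + 0.5 * A[ps[0], ps[1]]
        else:
            A[i, i] = 1.0
        for j in done:
            if j == i:
                continue
            a = sum(A[j, p] for p in ps)
            A[i, j] = A[j, i] = 0.5 * a
        done.append(i)
    return RelationshipMatrix(ids, A)


def to_correlation(A: RelationshipMatrix) -> RelationshipMatrix:
    """Diagonal-normalize relatedness: C_ij = A_ij / sqrt(A_ii A_jj)."""
    d = np.diag(A.values)
    if np.any(d <= 0):
        bad = A.ids[int(np.argmax(d <= 0))]
        raise MatrixError(f"nonpositive diagonal entry for {bad!r}")
    s = np.sqrt(d)
    C = A.values / np.outer(s, s)
    np.fill_diagonal(C, 1.0)
    return RelationshipMatrix(list(A.ids), C)


def kmeans_cluster(
    C: RelationshipMatrix, k: int, seed: int = 0, n_init: int = 10
) -> ClusterAssignment:
    """K-means on correlation-profile rows (k-means++ init, best of n_init)."""
    if not 1 <= k <= C.n:
        raise ConfigurationError(f"need 1 <= k <= {C.n}, got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(C.values)
    return ClusterAssignment(dict(zip(C.ids, (int(l) for l in labels))), k, float(km.inertia_))


def inertia_curve(
    C: RelationshipMatrix, k_values: list[int], seed: int = 0, n_init: int = 10
) -> list[tuple[int, float]]:
    """Best-of-n_init inertia for each K, for elbow inspection."""
    return [(k, kmeans_cluster(C, k, seed=seed, n_init=n_init).inertia) for k in k_values]


def cluster_from_organization(ids: list[str], org: dict[str, str]) -> ClusterAssignment:
    """Alternative grouping: label genotypes by developing organization."""
    orgs = sorted({org[g] for g in ids})
    code = {o: i for i, o in enumerate(orgs)}
    labels = {g: code[org[g]] for g in ids}
    return ClusterAssignment(labels, len(orgs), float("nan"))


def read_pedigree_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)
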