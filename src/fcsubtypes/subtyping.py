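"""FC subtype extraction.

The dissimilarity between two individuals' residual seed-FC maps is
D = 1 - r, with r their spatial Pearson correlation, so D ranges from 0
(perfectly correlated maps) through 1 (no spatial relationship) to 2
(perfectly anti-correlated maps). Individuals are clustered by hierarchical
agglomerative clustering of D with unweighted-average (UPGMA) linkage, and
communities are read off the dendrogram top-down: a node is accepted as a
community iff the average pairwise dissimilarity among its members is below a
threshold (default 1.0), otherwise its children are visited. Accepted
communities with at least ``min_size`` members (default 20) become subtypes;
everyone else is unassigned. Subtype maps are the member means of the residual
maps, and an individual's continuous assignment to a subtype is the spatial
correlation of their residual map with the subtype map, in [-1, 1].
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from ._utils import as_matrix, pearson_pairwise, pearson_rows

__all__ = [
    "UNASSIGNED",
    "SubtypeModel",
    "FCSubtyper",
    "dissimilarity_matrix",
    "extract_subtypes",
    "subtype_maps",
    "continuous_assignments",
]

UNASSIGNED = -1


def dissimilarity_matrix(residuals) -> np.ndarray:
    """Symmetric N x N matrix D = 1 - spatial correlation, zero diagonal, in [0, 2]."""
    X = as_matrix(residuals)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    D = 1.0 - pearson_pairwise(X)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def _mean_pairwise(D: np.ndarray, members: np.ndarray) -> float:
    """Average off-diagonal dissimilarity within a member set (0.0 for singletons)."""
    n = members.size
    if n < 2:
        return 0.0
    sub = D[np.ix_(members, members)]
    return float(sub.sum() / (n * (n - 1)))


def extract_subtypes(
    D: np.ndarray,
    theta: float = 1.0,
    min_size: int = 20,
    strict: bool = True,
) -> np.ndarray:
    """Discrete membership from the UPGMA dendrogram of a dissimilarity matrix.

    Top-down traversal from the root: a node is accepted iff the average
    pairwise dissimilarity among its leaves is < theta (<= with
    ``strict=False``); otherwise both children are visited. Accepted nodes
    with >= ``min_size`` leaves become subtypes, numbered by decreasing size
    (ties by smallest member index); all remaining individuals are UNASSIGNED
    (-1). Degenerate inputs yield an all-UNASSIGNED labelling rather than an
    error.
    """
    D = np.asarray(D, dtype=float)
    N = D.shape[0]
    if D.shape != (N, N) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    Z = linkage(squareform(D, checks=False), method="average")
    root = to_tree(Z)

    accepted: list[np.ndarray] = []
    stack = [root]
    while stack:
        node = stack.pop()
        members = np.asarray(node.pre_order(lambda leaf: leaf.id), dtype=int)
        avg = _mean_pairwise(D, members)
        ok = avg < theta if strict else avg <= theta
        if ok:
            if members.size >= min_size:
                accepted.append(np.sort(members))
        elif not node.is_leaf():
            stack.append(node.get_right())
            stack.append(node.get_left())

    accepted.sort(key=lambda m: (-m.size, m[0]))
    labels = np.full(N, UNASSIGNED, dtype=int)
    for s, members in enumerate(accepted):
        labels[members] = s
    return labels


def subtype_maps(residuals, membership) -> np.ndarray:
    """S x F matrix; row s is the elementwise mean residual map of subtype s's members."""
    X = as_matrix(residuals)
    labels = np.asarray(membership, dtype=int)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("membership length does not match residual rows")
    n_subtypes = labels.max() + 1 if (labels >= 0).any() else 0
    maps = np.empty((n_subtypes, X.shape[1]))
    for s in range(n_subtypes):
        members = labels == s
        if not members.any():
            raise ValueError(f"subtype {s} has no members")
        maps[s] = np.nanmean(X[members], axis=0)
    return maps


def continuous_assignments(residuals, maps) -> np.ndarray:
    """N x S spatial correlations of each residual map with each subtype map.

    Defined for any individual, including those from an independent sample
    (replication transfer uses the discovery subtype maps unchanged).
    """
    maps = as_matrix(maps)
    sd = np.nanstd(maps, axis=1)
    if (sd == 0).any():
        raise ValueError(f"zero-variance subtype map(s): {np.flatnonzero(sd == 0).tolist()}")
    return pearson_rows(residuals, maps)


@dataclasses.dataclass
class SubtypeModel:
    """A fitted subtyping solution for one seed network."""

    membership: np.ndarray  # (N,) subtype index or UNASSIGNED
    maps: np.ndarray  # (S, F) mean residual maps
    theta: float
    min_size: int
    linkage: str = "average"
    network_id: str = "network"
    subject_ids: list[str] | None = None
    feature_ids: list[str] | None = None

    @property
    def n_subtypes(self) -> int:
        return self.maps.shape[0]

    @property
    def subtype_sizes(self) -> np.ndarray:
        return np.bincount(self.membership[self.membership >= 0], minlength=self.n_subtypes)

    @property
    def assigned_fraction(self) -> float:
        return float((self.membership >= 0).mean())

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        ids = self.subject_ids or [str(i) for i in range(len(self.membership))]
        pd.DataFrame({"subject_id": ids, "subtype": self.membership}).to_csv(
            d / "membership.csv", index=False
        )
        cols = self.feature_ids or [f"f{i}" for i in range(self.maps.shape[1])]
        pd.DataFrame(self.maps, columns=cols).to_csv(d / "subtype_maps.tsv", sep="\t", index=False)
        (d / "params.json").write_text(
            json.dumps(
                {
                    "theta": self.theta,
                    "min_size": self.min_size,
                    "linkage": self.linkage,
                    "network_id": self.network_id,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, directory) -> "SubtypeModel":
        d = Path(directory)
        mem = pd.read_csv(d / "membership.csv")
        maps = pd.read_csv(d / "subtype_maps.tsv", sep="\t")
        params = json.loads((d / "params.json").read_text())
        return cls(
            membership=mem["subtype"].to_numpy(dtype=int),
            maps=maps.to_numpy(dtype=float),
            subject_ids=list(mem["subject_id"].astype(str)),
            feature_ids=list(maps.columns),
            **params,
        )


class FCSubtyper(BaseEstimator, ClusterMixin, TransformerMixin):
    """Hierarchical FC subtyping as an sklearn-style clusterer/transformer.

    ``fit(X)`` takes an individuals x features matrix of residualized seed-FC
    maps, builds the 1 - correlation dissimilarity matrix, and cuts the UPGMA
    dendrogram under the homogeneity (< theta) and size (>= min_size)
    acceptance criteria. ``transform(X)`` returns continuous assignments
    (spatial correlation with each fitted subtype map) for any compatible
    sample, which is how a replication cohort is scored against discovery
    subtypes.

    Parameters
    ----------
    theta : float, default 1.0
        Maximum average within-community dissimilarity.
    min_size : int, default 20
        Minimum number of members for an accepted community to become a subtype.
    strict : bool, default True
        Use strict inequality (< theta) for the homogeneity criterion.

    Attributes
    ----------
    labels_ : (N,) int array, -1 for unassigned
    subtype_maps_ : (S, F) array of member-mean residual maps
    n_subtypes_ : int
    dissimilarity_ : (N, N) array
    """

    def __init__(self, theta: float = 1.0, min_size: int = 20, strict: bool = True):
        self.theta = theta
        self.min_size = min_size
        self.strict = strict

    def fit(self, X, y=None) -> "FCSubtyper":
        X = as_matrix(X)
        if not (0 < self.theta <= 2):
            raise ValueError(f"theta must be in (0, 2], got {self.theta}")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        D = dissimilarity_matrix(X)
        self.dissimilarity_ = D
        self.labels_ = extract_subtypes(D, theta=self.theta, min_size=self.min_size, strict=self.strict)
        self.n_subtypes_ = int(self.labels_.max() + 1) if (self.labels_ >= 0).any() else 0
        self.subtype_maps_ = subtype_maps(X, self.labels_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "subtype_maps_"):
            raise AttributeError("FCSubtyper is not fitted yet")
        if self.n_subtypes_ == 0:
            return np.empty((as_matrix(X).shape[0], 0))
        return continuous_assignments(X, self.subtype_maps_)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def to_model(self, network_id: str = "network", subject_ids=None, feature_ids=None) -> SubtypeModel:
        return SubtypeModel(
            membership=self.labels_,
            maps=self.subtype_maps_,
            theta=self.theta,
            min_size=self.min_size,
            network_id=network_id,
            subject_ids=subject_ids,
            feature_ids=feature_ids,
        )
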