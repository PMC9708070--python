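"""Post-hoc characterization of subtype maps.

Covers the similarity structure of subtype maps across networks (do negASD /
posASD subtypes converge on a shared topography?), decomposition of a map into
brain-network means, PCA of the individual seed-FC maps, and the sweep over
the dissimilarity threshold that implicitly sets the number of subtypes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._utils import as_matrix, pearson_pairwise
from .stability import map_match_stability
from .subtyping import FCSubtyper

__all__ = [
    "MapSimilarity",
    "PCAResult",
    "subtype_map_similarity",
    "network_decomposition",
    "pca_maps",
    "threshold_sweep",
]


@dataclasses.dataclass
class MapSimilarity:
    """Pairwise spatial correlations over subtype maps with group medians."""

    correlations: np.ndarray  # (S, S), symmetric, unit diagonal
    labels: list[str]
    median_within: dict[str, float]
    median_between: dict[tuple[str, str], float]


def subtype_map_similarity(maps, group_labels: Sequence[str]) -> MapSimilarity:
    """Correlation structure of subtype maps (or continuous-assignment columns).

    ``group_labels`` tags each map (e.g. negASD / posASD / other); medians of
    the off-diagonal correlations are reported within each group and between
    each pair of groups.
    """
    X = as_matrix(maps)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 maps")
    labels = [str(g) for g in group_labels]
    if len(labels) != X.shape[0]:
        raise ValueError("one group label per map required")
    R = pearson_pairwise(X)
    groups = sorted(set(labels))
    lab = np.asarray(labels)
    within: dict[str, float] = {}
    between: dict[tuple[str, str], float] = {}
    for gi, g in enumerate(groups):
        idx = np.flatnonzero(lab == g)
        if idx.size >= 2:
            sub = R[np.ix_(idx, idx)]
            within[g] = float(np.median(sub[np.triu_indices(idx.size, k=1)]))
        for h in groups[gi + 1 :]:
            jdx = np.flatnonzero(lab == h)
            if idx.size and jdx.size:
                between[(g, h)] = float(np.median(R[np.ix_(idx, jdx)]))
    return MapSimilarity(correlations=R, labels=labels, median_within=within, median_between=between)


def network_decomposition(map_values, feature_networks: Sequence) -> pd.Series:
    """Mean of a map's values within each brain-network label of its features."""
    v = np.asarray(map_values, dtype=float).ravel()
    nets = pd.Series([None if pd.isna(x) else str(x) for x in feature_networks])
    if len(nets) != v.size:
        raise ValueError("one network label per feature required")
    if nets.isna().any():
        raise ValueError(f"unlabeled features at {nets[nets.isna()].index.tolist()}")
    return pd.Series(v).groupby(nets).mean()


@dataclasses.dataclass
class PCAResult:
    components: np.ndarray  # (n_components, n_kept_features)
    explained_variance_ratio: np.ndarray
    kept_features: np.ndarray  # indices of non-degenerate features
    scores: np.ndarray  # (N, n_components)


def pca_maps(maps, n_components: int | None = None) -> PCAResult:
    """PCA of seed-FC maps after feature-wise centering and unit-variance scaling.

    Features with zero variance across individuals are dropped (their indices
    are excluded from ``kept_features``).
    """
    X = as_matrix(maps)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    Xs = (X[:, kept] - X[:, kept].mean(axis=0)) / sd[kept]
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    return PCAResult(
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        kept_features=kept,
        scores=scores,
    )


def threshold_sweep(
    residuals,
    thetas: Sequence[float],
    min_size: int = 20,
) -> pd.DataFrame:
    """Re-run the full subtyping per threshold and track counts and map drift.

    Returns one row per theta with the subtype count, assigned proportion, and
    the best-match map correlation against the previous theta's maps
    (``cross_theta_r``; NaN for the first theta or empty map sets).
    """
    X = as_matrix(residuals)
    rows = []
    prev_maps = None
    for theta in thetas:
        if not (0 < theta <= 2):
            raise ValueError(f"theta values must lie in (0, 2], got {theta}")
        st = FCSubtyper(theta=theta, min_size=min_size).fit(X)
        cross = np.nan
        if prev_maps is not None and prev_maps.shape[0] and st.n_subtypes_:
            cross = map_match_stability(st.subtype_maps_, prev_maps)
        rows.append(
            {
                "theta": theta,
                "n_subtypes": st.n_subtypes_,
                "assigned_proportion": float((st.labels_ >= 0).mean()),
                "cross_theta_r": cross,
            }
        )
        prev_maps = st.subtype_maps_
    return pd.DataFrame(rows)
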