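"""Stability analyses: split-half subsampling and test-retest ICC.

Three robustness measures: (1) Dice overlap of an individual's discrete
community neighbours across two stratified half-subsamples of the cohort,
(2) best-match spatial correlation between the subtype maps extracted in two
half-subsamples, and (3) the intraclass correlation coefficient of continuous
assignments across repeated scan sessions, optionally with session averaging
under the frame-budget scheme (M sessions truncated to K session-equivalents
of frames).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import as_matrix, pearson_rows
from .residualize import ConfoundRegressor
from .subtyping import UNASSIGNED, FCSubtyper, SubtypeModel, continuous_assignments
from .timeseries import FrameSeries, truncate_and_average

__all__ = [
    "SubsamplePair",
    "half_split_subsamples",
    "dice_coefficient",
    "dice_discrete_stability",
    "map_match_stability",
    "icc",
    "icc_session_analysis",
    "icc_frame_budget_analysis",
]


@dataclasses.dataclass
class SubsamplePair:
    """Two half-subsamples (index sets) preserving the diagnosis ratio."""

    indices_a: np.ndarray
    indices_b: np.ndarray
    pair_id: int


def _stratified_half(rng: np.random.Generator, groups: pd.Series) -> np.ndarray:
    """One half-subsample of size floor(N/2), stratified to preserve group ratios."""
    n = len(groups)
    target = n // 2
    takes: dict[str, int] = {}
    fracs: list[tuple[float, str]] = []
    for g, idx in groups.groupby(groups).groups.items():
        takes[g] = len(idx) // 2
        fracs.append((-(len(idx) / 2 - len(idx) // 2), g))  # largest remainder first
    short = target - sum(takes.values())
    for _, g in sorted(fracs):
        if short <= 0:
            break
        takes[g] += 1
        short -= 1
    chosen = []
    for g, idx in groups.groupby(groups).groups.items():
        idx = np.asarray(idx)
        chosen.append(rng.choice(idx, size=takes[g], replace=False))
    return np.sort(np.concatenate(chosen))


def half_split_subsamples(
    phenotypes: pd.DataFrame,
    n_subsamples: int = 1000,
    n_pairs: int = 1000,
    seed: int | None = None,
    stratify_on: str = "diagnosis",
) -> list[SubsamplePair]:
    """Draw stratified half-subsamples, then unique unordered pairs of them.

    Each subsample holds floor(N/2) individuals with the per-group counts
    within one individual of half the group size, so the ASD:NTC ratio is
    preserved. Pairs are drawn uniformly without repetition.
    """
    if len(phenotypes) < 4:
        raise ValueError("need at least 4 individuals")
    groups = phenotypes[stratify_on].astype(str).reset_index(drop=True)
    if groups.nunique() < 2 and stratify_on == "diagnosis":
        raise ValueError("both diagnosis groups must be present")
    max_pairs = math.comb(n_subsamples, 2)
    if n_pairs > max_pairs:
        raise ValueError(f"{n_pairs} pairs requested but only {max_pairs} unique pairs exist")
    rng = np.random.default_rng(seed)
    subsamples = [_stratified_half(rng, groups) for _ in range(n_subsamples)]
    seen: set[tuple[int, int]] = set()
    pairs: list[SubsamplePair] = []
    while len(pairs) < n_pairs:
        i, j = rng.choice(n_subsamples, size=2, replace=False)
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(SubsamplePair(subsamples[key[0]], subsamples[key[1]], pair_id=len(pairs)))
    return pairs


def dice_coefficient(set_a: set, set_b: set) -> float:
    """2|A∩B| / (|A| + |B|); 1.0 when both sets are empty (identical)."""
    total = len(set_a) + len(set_b)
    if total == 0:
        return 1.0
    return 2.0 * len(set_a & set_b) / total


def dice_discrete_stability(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    pair: SubsamplePair,
    unassigned: str = "exclude",
) -> tuple[pd.DataFrame, float]:
    """Per-individual Dice overlap of community neighbours across two subsamples.

    ``labels_a[k]`` is the subtype of the k-th member of ``pair.indices_a``
    (order as in the index set), UNASSIGNED allowed. For each individual in
    the intersection of the subsamples, the community is restricted to the
    intersection and the individual itself is excluded (its neighbours), so
    identical neighbour sets give 1 and disjoint ones give 0. Individuals
    unassigned in either model are excluded from the mean (``unassigned=
    'exclude'``) or scored 0 (``'zero'``).
    """
    a_idx, b_idx = pair.indices_a, pair.indices_b
    if len(labels_a) != len(a_idx) or len(labels_b) != len(b_idx):
        raise ValueError("label vectors must match the subsample index sets")
    common = np.intersect1d(a_idx, b_idx)
    if common.size == 0:
        raise ValueError("empty intersection between subsamples")
    lab_a = dict(zip(a_idx.tolist(), np.asarray(labels_a).tolist()))
    lab_b = dict(zip(b_idx.tolist(), np.asarray(labels_b).tolist()))
    common_set = set(common.tolist())
    rows = []
    for i in common.tolist():
        la, lb = lab_a[i], lab_b[i]
        if la == UNASSIGNED or lb == UNASSIGNED:
            if unassigned == "zero":
                rows.append((i, 0.0, False))
            else:
                rows.append((i, np.nan, False))
            continue
        nb_a = {j for j in common_set if lab_a[j] == la} - {i}
        nb_b = {j for j in common_set if lab_b[j] == lb} - {i}
        rows.append((i, dice_coefficient(nb_a, nb_b), True))
    df = pd.DataFrame(rows, columns=["individual", "dice", "assigned_in_both"])
    mean = float(df["dice"].mean(skipna=True))
    return df, mean


def map_match_stability(maps_a, maps_b) -> float:
    """Mean over A-maps of the best spatial correlation with any B-map (A→B, with replacement)."""
    maps_a, maps_b = as_matrix(maps_a), as_matrix(maps_b)
    if maps_a.shape[0] == 0 or maps_b.shape[0] == 0:
        raise ValueError("empty subtype map set")
    R = pearson_rows(maps_a, maps_b)
    return float(R.max(axis=1).mean())


def icc(measurements, form: str = "icc1") -> float:
    """Intraclass correlation of an individuals x sessions table.

    ``icc1`` is ICC(1,1): one-way random effects, single measurement,
    (MS_between - MS_within) / (MS_between + (k-1) MS_within). ``icc2`` is
    ICC(2,1) (two-way random, absolute agreement). Negative values are
    reported as computed.
    """
    X = as_matrix(measurements)
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 individuals and >= 2 sessions")
    if not np.isfinite(X).all():
        raise ValueError("non-finite measurements")
    if np.allclose(X, X.flat[0]):
        raise ValueError("zero total variance")
    grand = X.mean()
    row_means = X.mean(axis=1)
    ms_between = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_within = ((X - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    if form == "icc1":
        return float((ms_between - ms_within) / (ms_between + (k - 1) * ms_within))
    if form == "icc2":
        col_means = X.mean(axis=0)
        ms_cols = n * ((col_means - grand) ** 2).sum() / (k - 1)
        ss_err = ((X - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
        ms_err = ss_err / ((n - 1) * (k - 1))
        return float(
            (ms_between - ms_err)
            / (ms_between + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)
        )
    raise ValueError(f"unknown ICC form {form!r}")


def _session_assignments(
    session_maps: np.ndarray, maps: np.ndarray, covariates: Sequence[str], phenotypes
) -> np.ndarray:
    """Residualize one session independently, then score against subtype maps."""
    resid = ConfoundRegressor(covariates=covariates).fit_transform(session_maps, phenotypes)
    return continuous_assignments(resid, maps)


def icc_session_analysis(
    session_fc: Sequence[np.ndarray],
    subtype_source: str = "within_sample",
    model: SubtypeModel | None = None,
    theta: float = 1.0,
    min_size: int = 20,
    covariates: Sequence[str] = (),
    phenotypes=None,
    form: str = "icc1",
) -> np.ndarray:
    """Test-retest ICC of continuous assignments across two scan sessions.

    ``session_fc`` holds one individuals x features FC matrix per session with
    aligned rows. With ``subtype_source='within_sample'`` subtypes are fitted
    on session 0 and assignments computed on sessions 1 and 2; with
    ``'out_of_sample'`` a discovery ``model`` supplies the subtype maps and
    sessions 0 and 1 are scored. Each test session is centered/residualized
    independently before scoring. Returns one ICC per subtype.
    """
    session_fc = [as_matrix(s) for s in session_fc]
    if subtype_source == "within_sample":
        if len(session_fc) < 3:
            raise ValueError("within-sample mode needs >= 3 sessions (1 fit + 2 test)")
        resid0 = ConfoundRegressor(covariates=covariates).fit_transform(session_fc[0], phenotypes)
        maps = FCSubtyper(theta=theta, min_size=min_size).fit(resid0).subtype_maps_
        test = session_fc[1:3]
    elif subtype_source == "out_of_sample":
        if model is None:
            raise ValueError("out-of-sample mode requires a discovery SubtypeModel")
        if len(session_fc) < 2:
            raise ValueError("out-of-sample mode needs >= 2 sessions")
        maps = model.maps
        test = session_fc[:2]
    else:
        raise ValueError(f"unknown subtype_source {subtype_source!r}")
    A = [_session_assignments(s, maps, covariates, phenotypes) for s in test]
    return np.array(
        [icc(np.column_stack([A[0][:, s], A[1][:, s]]), form=form) for s in range(maps.shape[0])]
    )


def icc_frame_budget_analysis(
    sessions: Sequence[Sequence[FrameSeries]],
    M: int,
    K: int,
    n_frame_min: int,
    theta: float = 1.0,
    min_size: int = 20,
    covariates: Sequence[str] = (),
    scrub: bool = False,
    form: str = "icc1",
) -> np.ndarray:
    """ICC under session averaging with a fixed frame budget.

    ``sessions[i]`` is the session list of individual i. Session 0 fits the
    subtypes; from the remaining sessions, two non-overlapping sets of M
    sessions are each truncated to round(K/M * n_frame_min) frames, averaged
    into one FC map per individual per set, residualized independently, and
    scored. Returns one ICC per subtype.
    """
    n_ses = len(sessions[0])
    if n_ses < 1 + 2 * M:
        raise ValueError(f"need {1 + 2 * M} sessions for M={M}, got {n_ses}")

    def fc_of(session_list: Sequence[FrameSeries]) -> np.ndarray:
        return truncate_and_average(list(session_list), M=M, K=K, n_frame_min=n_frame_min, scrub=scrub)

    fit_maps = np.vstack(
        [truncate_and_average([s[0]], M=1, K=1, n_frame_min=n_frame_min, scrub=scrub) for s in sessions]
    )
    resid0 = ConfoundRegressor(covariates=covariates).fit_transform(fit_maps)
    maps = FCSubtyper(theta=theta, min_size=min_size).fit(resid0).subtype_maps_

    set_a = np.vstack([fc_of(s[1 : 1 + M]) for s in sessions])
    set_b = np.vstack([fc_of(s[1 + M : 1 + 2 * M]) for s in sessions])
    A = [_session_assignments(x, maps, covariates, None) for x in (set_a, set_b)]
    return np.array(
        [icc(np.column_stack([A[0][:, s], A[1][:, s]]), form=form) for s in range(maps.shape[0])]
    )
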