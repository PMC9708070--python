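"""Group-level centering and nuisance regression of seed-FC maps.

Before subtyping, each sample's seed-FC maps are centered feature-wise to the
sample mean and linear effects of covariates of non-interest (imaging site,
age, in-scanner head motion, optionally whole-brain FC) are regressed out per
feature by ordinary least squares. Site is deviation-coded so the intercept
remains the grand mean. A replication sample is residualized by re-fitting the
same model within that sample, never by applying discovery coefficients.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import as_matrix

__all__ = [
    "ConfoundModel",
    "ConfoundRegressor",
    "fit_confound_model",
    "residual_maps",
    "whole_brain_fc_covariate",
]

logger = logging.getLogger(__name__)

MAX_MISSING_FRACTION = 0.05


def _deviation_code(site: pd.Series, levels: list[str]) -> np.ndarray:
    """Deviation (sum-to-zero) coding: k-1 columns, last level coded -1 everywhere."""
    codes = np.zeros((len(site), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        codes[(site == lev).to_numpy(), j] = 1.0
    codes[(site == levels[-1]).to_numpy(), :] = -1.0
    return codes


def build_design(
    phenotypes: pd.DataFrame, covariates: Sequence[str], site_levels: list[str] | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + deviation-coded site + numeric covariate columns.

    Returns (design, column_names, site_levels).
    """
    n = len(phenotypes)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for cov in covariates:
        if cov not in phenotypes.columns:
            raise ValueError(f"covariate {cov!r} missing from the phenotype table")
        if cov == "site":
            if site_levels is None:
                site_levels = sorted(phenotypes["site"].astype(str).unique())
            if len(site_levels) < 2:
                continue  # single site carries no variance
            codes = _deviation_code(phenotypes["site"].astype(str), site_levels)
            cols.append(codes)
            names.extend(f"site[{lev}]" for lev in site_levels[:-1])
        else:
            x = phenotypes[cov].to_numpy(dtype=float)
            if not np.isfinite(x).all():
                raise ValueError(f"covariate {cov!r} contains non-finite values")
            cols.append(x[:, None] if x.ndim == 1 else x)
            names.append(cov)
    X = np.column_stack(cols)
    return X, names, site_levels or []


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name columns lying in the span of their predecessors
    collinear = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        beta, *_ = np.linalg.lstsq(prev, X[:, j], rcond=None)
        if np.allclose(prev @ beta, X[:, j], atol=1e-8 * max(1.0, np.abs(X[:, j]).max())):
            collinear.append(names[j])
    raise ValueError(f"rank-deficient design (rank {rank} < {X.shape[1]}); collinear columns: {collinear}")


@dataclasses.dataclass
class ConfoundModel:
    """Per-feature OLS fit of seed-FC values on the confound design."""

    covariates: list[str]
    design_columns: list[str]
    site_levels: list[str]
    coef: np.ndarray  # (n_design_columns, n_features)
    feature_ids: list[str] | None = None
    dropped_features: list[int] = dataclasses.field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "covariates": self.covariates,
                    "design_columns": self.design_columns,
                    "site_levels": self.site_levels,
                    "coef": self.coef.tolist(),
                    "feature_ids": self.feature_ids,
                    "dropped_features": self.dropped_features,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "ConfoundModel":
        d = json.loads(Path(path).read_text())
        d["coef"] = np.asarray(d["coef"], dtype=float)
        return cls(**d)


class ConfoundRegressor(BaseEstimator):
    """Sklearn-style transformer for group-level residualization.

    Parameters
    ----------
    covariates : list of str, default ()
        Phenotype columns to regress per feature. ``"site"`` is treated as a
        deviation-coded categorical; all others as numeric. An empty list
        reduces to feature-wise grand-mean centering.

    Attributes (after ``fit``)
    --------------------------
    model_ : ConfoundModel
        Fitted coefficients and design description.
    """

    def __init__(self, covariates: Sequence[str] = ()):
        self.covariates = list(covariates)

    def fit(self, X, phenotypes: pd.DataFrame | None = None) -> "ConfoundRegressor":
        X = as_matrix(X)
        if phenotypes is None:
            phenotypes = pd.DataFrame(index=range(X.shape[0]))
        if len(phenotypes) != X.shape[0]:
            raise ValueError("phenotype rows do not match FC matrix rows")
        D, names, site_levels = build_design(phenotypes, self.covariates)
        if X.shape[0] <= D.shape[1]:
            raise ValueError(f"N={X.shape[0]} individuals <= {D.shape[1]} design columns")
        _check_full_rank(D, names)

        n, F = X.shape
        coef = np.full((D.shape[1], F), np.nan)
        dropped: list[int] = []
        missing = ~np.isfinite(X)
        frac = missing.mean(axis=0)
        complete = ~missing.any(axis=0)
        if complete.all():
            coef = np.linalg.lstsq(D, X, rcond=None)[0]
        else:
            if complete.any():
                coef[:, complete] = np.linalg.lstsq(D, X[:, complete], rcond=None)[0]
            for f in np.flatnonzero(~complete):
                if frac[f] > MAX_MISSING_FRACTION:
                    dropped.append(int(f))
                    continue
                ok = ~missing[:, f]
                if ok.sum() <= D.shape[1]:
                    dropped.append(int(f))
                    continue
                coef[:, f] = np.linalg.lstsq(D[ok], X[ok, f], rcond=None)[0]
            if dropped:
                logger.warning(
                    "dropped %d feature(s) missing in > %.0f%% of individuals",
                    len(dropped), 100 * MAX_MISSING_FRACTION,
                )
        self.model_ = ConfoundModel(
            covariates=list(self.covariates),
            design_columns=names,
            site_levels=site_levels,
            coef=coef,
            dropped_features=dropped,
        )
        return self

    def transform(self, X, phenotypes: pd.DataFrame | None = None) -> np.ndarray:
        """Residuals (observed - fitted) about the group mean."""
        model = self.model_  # AttributeError if unfitted, as in sklearn
        X = as_matrix(X)
        if X.shape[1] != model.coef.shape[1]:
            raise ValueError(
                f"feature mismatch: {X.shape[1]} features vs model {model.coef.shape[1]}"
            )
        if phenotypes is None:
            phenotypes = pd.DataFrame(index=range(X.shape[0]))
        D, _, _ = build_design(phenotypes, self.covariates, site_levels=model.site_levels or None)
        resid = X - D @ model.coef
        if model.dropped_features:
            resid[:, model.dropped_features] = np.nan
        return resid

    def fit_transform(self, X, phenotypes: pd.DataFrame | None = None) -> np.ndarray:
        return self.fit(X, phenotypes).transform(X, phenotypes)


def fit_confound_model(fc, phenotypes, covariates: Sequence[str]) -> ConfoundModel:
    """Functional wrapper over :class:`ConfoundRegressor`. Returns the fitted model."""
    reg = ConfoundRegressor(covariates=covariates).fit(fc, phenotypes)
    return reg.model_


def residual_maps(fc, model: ConfoundModel, phenotypes=None) -> np.ndarray:
    """Residuals of ``fc`` under a fitted confound model (same-sample use).

    For a new sample (replication), re-fit within that sample via
    :class:`ConfoundRegressor` instead of re-using discovery coefficients.
    """
    reg = ConfoundRegressor(covariates=model.covariates)
    reg.model_ = model
    return reg.transform(fc, phenotypes)


def whole_brain_fc_covariate(fc_by_network: dict) -> np.ndarray:
    """Per-individual mean FC across all features of all seed networks.

    A scalar summary of global FC shifts, appended as an extra nuisance
    covariate in the whole-brain-FC regression variant of the pipeline.
    """
    mats = [as_matrix(v) for v in fc_by_network.values()]
    if not mats:
        raise ValueError("no FC matrices supplied")
    stacked = np.hstack(mats)
    if (~np.isfinite(stacked)).all(axis=1).any():
        bad = np.flatnonzero((~np.isfinite(stacked)).all(axis=1)).tolist()
        raise ValueError(f"all-missing maps for individuals {bad}")
    return np.nanmean(stacked, axis=1)
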