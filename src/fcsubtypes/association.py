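"""Diagnosis and symptom association of continuous subtype assignments.

Each subtype's continuous assignments are compared between ASD and NTC
individuals with a pooled-variance two-sample t-test (no unequal-variance
correction; the design keeps the groups equal sized), corrected across all
subtypes of all networks at a false discovery rate of 5% (Benjamini-Hochberg).
Effect sizes are Cohen's d = (mean_ASD - mean_NTC) / pooled SD, so subtypes
with stronger NTC assignments get d < 0 (negASD) and stronger ASD assignments
get d > 0 (posASD). Replication transfers the discovery subtype maps to an
independent residualized cohort and grades each discovery-significant subtype
on a four-rung ladder: FDR-significant, p < 0.05, effect within the discovery
CI, and same direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import as_matrix
from .subtyping import SubtypeModel, continuous_assignments

__all__ = [
    "diagnosis_association",
    "fdr_adjust",
    "effect_ci",
    "symptom_association",
    "replication_transfer",
    "replication_ladder",
]


def fdr_adjust(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[1]


def _cohens_d(x_asd: np.ndarray, x_ntc: np.ndarray) -> float:
    n1, n2 = len(x_asd), len(x_ntc)
    pooled = np.sqrt(
        ((n1 - 1) * x_asd.var(ddof=1) + (n2 - 1) * x_ntc.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        return 0.0
    return float((x_asd.mean() - x_ntc.mean()) / pooled)


def effect_ci(d: float, n1: int, n2: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for Cohen's d: d ± z * sqrt((n1+n2)/(n1 n2) + d²/(2(n1+n2)))."""
    if not (0 < level < 1):
        raise ValueError(f"invalid confidence level {level}")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    z = stats.norm.ppf(0.5 + level / 2)
    return float(d - z * se), float(d + z * se)


def diagnosis_association(
    assignments,
    diagnosis,
    fdr_q: float = 0.05,
    ci_level: float = 0.95,
    subtype_ids=None,
) -> pd.DataFrame:
    """Per-subtype association of continuous assignments with ASD diagnosis.

    Returns a table with t statistic, raw and BH-adjusted p (pooled across all
    supplied subtypes — pass all networks' assignments together), Cohen's d
    with its CI, direction, and group sizes.
    """
    A = as_matrix(assignments)
    diagnosis = np.asarray(diagnosis).astype(str)
    if len(diagnosis) != A.shape[0]:
        raise ValueError("diagnosis labels do not match assignment rows")
    asd, ntc = diagnosis == "ASD", diagnosis == "NTC"
    if asd.sum() < 2 or ntc.sum() < 2:
        raise ValueError("both diagnosis groups need >= 2 individuals")
    rows = []
    ids = subtype_ids if subtype_ids is not None else [f"s{j}" for j in range(A.shape[1])]
    for j in range(A.shape[1]):
        x1, x2 = A[asd, j], A[ntc, j]
        t, p = stats.ttest_ind(x1, x2, equal_var=True)
        d = _cohens_d(x1, x2)
        lo, hi = effect_ci(d, asd.sum(), ntc.sum(), level=ci_level)
        rows.append(
            {
                "subtype": ids[j],
                "t_statistic": float(t),
                "p_raw": float(p),
                "cohen_d": d,
                "d_ci_low": lo,
                "d_ci_high": hi,
                "direction": "posASD" if d > 0 else "negASD",
                "n_ASD": int(asd.sum()),
                "n_NTC": int(ntc.sum()),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = fdr_adjust(table["p_raw"].to_numpy(), q=fdr_q)
    table["significant"] = table["p_adj"] < fdr_q
    return table


def symptom_association(
    assignments,
    scores,
    subset_mask=None,
    fdr_q: float = 0.05,
    subtype_ids=None,
) -> pd.DataFrame:
    """Pearson correlation of continuous assignments with a symptom total score.

    ``subset_mask`` restricts the tested individuals (e.g. ASD-only for ADOS;
    all individuals with available scores for SRS). Missing scores are dropped.
    BH-FDR is applied across the tested subtypes (a separate family from the
    diagnosis tests).
    """
    A = as_matrix(assignments)
    scores = np.asarray(scores, dtype=float).ravel()
    if len(scores) != A.shape[0]:
        raise ValueError("score vector does not match assignment rows")
    mask = np.ones(A.shape[0], dtype=bool) if subset_mask is None else np.asarray(subset_mask, bool)
    mask = mask & np.isfinite(scores)
    if mask.sum() < 3:
        raise ValueError("need >= 3 individuals with scores after the subset rule")
    s = scores[mask]
    if np.allclose(s, s[0]):
        raise ValueError("constant symptom scores")
    ids = subtype_ids if subtype_ids is not None else [f"s{j}" for j in range(A.shape[1])]
    rows = []
    for j in range(A.shape[1]):
        r, p = stats.pearsonr(A[mask, j], s)
        rows.append({"subtype": ids[j], "r": float(r), "p_raw": float(p), "n": int(mask.sum())})
    table = pd.DataFrame(rows)
    table["p_adj"] = fdr_adjust(table["p_raw"].to_numpy(), q=fdr_q)
    table["significant"] = table["p_adj"] < fdr_q
    return table


def replication_transfer(
    replication_residuals,
    discovery_model: SubtypeModel,
    diagnosis,
    discovery_table: pd.DataFrame | None = None,
    fdr_q: float = 0.05,
    ci_level: float = 0.95,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Score a replication cohort against discovery subtype maps and re-test.

    The replication residuals must have been centered/residualized within the
    replication sample. When a discovery association table is supplied, the
    replication test (and its FDR correction) is restricted to the
    discovery-significant subtypes, as in the replication ladder.
    """
    A = continuous_assignments(replication_residuals, discovery_model.maps)
    ids = [f"s{j}" for j in range(A.shape[1])]
    if discovery_table is not None:
        keep_ids = discovery_table.loc[discovery_table["significant"], "subtype"].tolist()
        keep = [ids.index(i) for i in keep_ids]
        if not keep:
            raise ValueError("no discovery-significant subtypes to replicate")
        table = diagnosis_association(
            A[:, keep], diagnosis, fdr_q=fdr_q, ci_level=ci_level, subtype_ids=keep_ids
        )
    else:
        table = diagnosis_association(A, diagnosis, fdr_q=fdr_q, ci_level=ci_level, subtype_ids=ids)
    return A, table


def replication_ladder(
    discovery_table: pd.DataFrame,
    replication_table: pd.DataFrame,
    ci_level: float = 0.90,
    fdr_q: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Four replication flags per discovery-significant subtype + effect concordance.

    Flags, each computed independently: ``fdr_replicated`` (replication p_adj
    < q), ``p05_replicated`` (replication p_raw < 0.05), ``within_ci``
    (replication d inside the discovery d's CI at ``ci_level``),
    ``same_direction``. Concordance is the Pearson correlation of the d
    vectors, reported for the discovery-significant subtypes and across all
    common subtypes.
    """
    common = discovery_table.merge(
        replication_table, on="subtype", suffixes=("_disc", "_repl")
    )
    if common.empty:
        raise ValueError("no common subtypes between discovery and replication tables")
    rows = []
    for _, row in common[common["significant_disc"].astype(bool)].iterrows():
        lo, hi = effect_ci(row["cohen_d_disc"], row["n_ASD_disc"], row["n_NTC_disc"], level=ci_level)
        rows.append(
            {
                "subtype": row["subtype"],
                "d_discovery": row["cohen_d_disc"],
                "d_replication": row["cohen_d_repl"],
                "fdr_replicated": bool(row["p_adj_repl"] < fdr_q),
                "p05_replicated": bool(row["p_raw_repl"] < 0.05),
                "within_ci": bool(lo <= row["cohen_d_repl"] <= hi),
                "same_direction": bool(np.sign(row["cohen_d_repl"]) == np.sign(row["cohen_d_disc"])),
            }
        )
    ladder = pd.DataFrame(rows)
    sig = common["significant_disc"].to_numpy(dtype=bool)
    d_disc = common["cohen_d_disc"].to_numpy()
    d_repl = common["cohen_d_repl"].to_numpy()

    def _corr(x, y):
        if len(x) < 2 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
            return float("nan")
        return float(stats.pearsonr(x, y)[0])

    concordance = {
        "r_significant": _corr(d_disc[sig], d_repl[sig]) if sig.sum() >= 2 else (
            1.0 if sig.sum() == 1 and np.sign(d_disc[sig]) == np.sign(d_repl[sig]) else float("nan")
        ),
        "r_all": _corr(d_disc, d_repl),
    }
    return ladder, concordance
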