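"""Orchestration of the discovery → stability → association → replication workflow."""

from __future__ import annotations

import datetime
import importlib.metadata
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .association import (
    diagnosis_association,
    replication_ladder,
    replication_transfer,
)
from .config import ConfigError, PipelineConfig
from .io import SeedFCMatrix, read_fc_matrix, read_phenotypes, write_fc_matrix
from .residualize import ConfoundRegressor, whole_brain_fc_covariate
from .stability import dice_discrete_stability, half_split_subsamples, map_match_stability
from .subtyping import FCSubtyper, SubtypeModel

__all__ = ["run_pipeline", "run_discovery", "run_stability", "generate_report", "load_cohort"]

logger = logging.getLogger(__name__)


def load_cohort(input_dir) -> tuple[dict[str, SeedFCMatrix], pd.DataFrame]:
    """Read fc_<network>.tsv matrices + phenotypes.csv from a directory."""
    input_dir = Path(input_dir)
    fc_paths = sorted(input_dir.glob("fc_*.tsv"))
    if not fc_paths:
        raise ConfigError(f"no fc_*.tsv matrices under {input_dir}")
    phen = read_phenotypes(input_dir / "phenotypes.csv")
    fc = {}
    for p in fc_paths:
        net = p.stem.removeprefix("fc_")
        mat = read_fc_matrix(p, network_id=net)
        if mat.subject_ids != list(phen["subject_id"]):
            raise ConfigError(f"{p}: subject ids do not match phenotypes.csv")
        fc[net] = mat
    return fc, phen


def _residualize_all(
    fc: dict[str, SeedFCMatrix], phen: pd.DataFrame, config: PipelineConfig
) -> dict[str, np.ndarray]:
    covariates = [c for c in config.covariates if c in phen.columns or c == "site"]
    phen = phen.copy()
    if config.whole_brain_fc:
        phen["whole_brain_fc"] = whole_brain_fc_covariate({k: v.values for k, v in fc.items()})
        covariates = list(covariates) + ["whole_brain_fc"]
    return {
        net: ConfoundRegressor(covariates=covariates).fit_transform(mat.values, phen)
        for net, mat in fc.items()
    }


def run_discovery(
    fc: dict[str, SeedFCMatrix],
    phen: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[dict[str, SubtypeModel], dict[str, np.ndarray], pd.DataFrame]:
    """Residualize, subtype every network, score assignments, test diagnosis.

    Returns (models per network, residuals per network, pooled association
    table with FDR across all subtypes of all networks; subtype ids are
    ``<network>/s<j>``).
    """
    residuals = _residualize_all(fc, phen, config)
    models: dict[str, SubtypeModel] = {}
    assign_cols, ids = [], []
    for net, resid in residuals.items():
        st = FCSubtyper(theta=config.theta, min_size=config.min_size).fit(resid)
        models[net] = st.to_model(
            network_id=net,
            subject_ids=fc[net].subject_ids,
            feature_ids=fc[net].feature_ids,
        )
        if st.n_subtypes_:
            assign_cols.append(st.transform(resid))
            ids.extend(f"{net}/s{j}" for j in range(st.n_subtypes_))
    if not ids:
        raise ConfigError("no subtypes found in any network; nothing to test")
    A = np.hstack(assign_cols)
    table = diagnosis_association(
        A, phen["diagnosis"], fdr_q=config.fdr_q, ci_level=config.ci_level_bars, subtype_ids=ids
    )
    return models, residuals, table


def run_stability(
    fc: dict[str, SeedFCMatrix],
    phen: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Split-half stability: per pair and network, mean Dice and best-match map r."""
    pairs = half_split_subsamples(
        phen, n_subsamples=config.n_subsamples, n_pairs=config.n_pairs, seed=config.rng_seed
    )
    rows = []
    for net, mat in fc.items():
        for pair in pairs:
            sub = {}
            for tag, idx in (("a", pair.indices_a), ("b", pair.indices_b)):
                sub_fc = mat.values[idx]
                sub_phen = phen.iloc[idx].reset_index(drop=True)
                covs = [c for c in config.covariates if c in sub_phen.columns or c == "site"]
                resid = ConfoundRegressor(covariates=covs).fit_transform(sub_fc, sub_phen)
                sub[tag] = FCSubtyper(theta=config.theta, min_size=config.min_size).fit(resid)
            row = {"network": net, "pair_id": pair.pair_id}
            if sub["a"].n_subtypes_ and sub["b"].n_subtypes_:
                row["map_match_r"] = map_match_stability(
                    sub["a"].subtype_maps_, sub["b"].subtype_maps_
                )
                _, row["dice_mean"] = dice_discrete_stability(
                    sub["a"].labels_, sub["b"].labels_, pair
                )
            else:
                row["map_match_r"] = np.nan
                row["dice_mean"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    input_dir,
    out_dir,
    replication_dir=None,
    with_stability: bool = False,
) -> Path:
    """End-to-end run over an on-disk cohort; writes a results directory.

    Every run writes a JSON provenance record (config + hash, package version,
    timestamp) so it can be reproduced exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fc, phen = load_cohort(input_dir)

    models, residuals, table = run_discovery(fc, phen, config)
    for net, model in models.items():
        model.save(out / "subtypes" / net)
    for net, resid in residuals.items():
        write_fc_matrix(
            SeedFCMatrix(resid, fc[net].subject_ids, fc[net].feature_ids, net),
            out / f"residuals_{net}.tsv",
        )
    table.to_csv(out / "association.csv", index=False)

    if with_stability:
        run_stability(fc, phen, config).to_csv(out / "stability.csv", index=False)

    if replication_dir is not None:
        repl_fc, repl_phen = load_cohort(replication_dir)
        repl_resid = _residualize_all(repl_fc, repl_phen, config)
        repl_rows = []
        for net, model in models.items():
            if model.n_subtypes == 0 or net not in repl_resid:
                continue
            disc_net = table[table["subtype"].str.startswith(f"{net}/")].copy()
            disc_net["subtype"] = disc_net["subtype"].str.removeprefix(f"{net}/")
            if not disc_net["significant"].any():
                continue
            _, repl_table = replication_transfer(
                repl_resid[net], model, repl_phen["diagnosis"],
                discovery_table=disc_net, fdr_q=config.fdr_q, ci_level=config.ci_level_bars,
            )
            repl_table["subtype"] = f"{net}/" + repl_table["subtype"]
            repl_rows.append(repl_table)
        if repl_rows:
            repl_all = pd.concat(repl_rows, ignore_index=True)
            repl_all.to_csv(out / "replication.csv", index=False)
            ladder, concordance = replication_ladder(
                table, repl_all, ci_level=config.ci_level_ladder, fdr_q=config.fdr_q
            )
            ladder.to_csv(out / "replication_ladder.csv", index=False)
            (out / "concordance.json").write_text(json.dumps(concordance, indent=2))

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "package_version": importlib.metadata.version("fcsubtypes"),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out


def generate_report(results_dir) -> str:
    """Markdown summary of a completed run; lists missing stages if incomplete."""
    results_dir = Path(results_dir)
    missing = [f for f in ("association.csv", "provenance.json") if not (results_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run under {results_dir}: missing {missing}")
    table = pd.read_csv(results_dir / "association.csv")
    lines = ["# FC subtype analysis report", ""]
    lines.append(f"Subtypes tested: {len(table)}; FDR-significant: {int(table['significant'].sum())}")
    lines.append("")
    lines.append(table.to_markdown(index=False))
    stab_path = results_dir / "stability.csv"
    if stab_path.exists():
        stab = pd.read_csv(stab_path)
        lines.append("")
        lines.append("## Stability (split-half)")
        lines.append(
            stab.groupby("network")[["map_match_r", "dice_mean"]].mean().to_markdown()
        )
    ladder_path = results_dir / "replication_ladder.csv"
    if ladder_path.exists():
        lines.append("")
        lines.append("## Replication ladder")
        lines.append(pd.read_csv(ladder_path).to_markdown(index=False))
    report = "\n".join(lines) + "\n"
    (results_dir / "report.md").write_text(report)
    return report
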