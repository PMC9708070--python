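"""On-disk exchange formats.

Canonical formats are plain text: seed-FC matrices as TSV (individuals as rows,
header row of feature ids), phenotype tables as CSV, model parameters as JSON.
Parcel-level NIfTI input/output is optional and requires nibabel.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SeedFCMatrix",
    "read_fc_matrix",
    "write_fc_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_fc_nifti",
    "write_map_nifti",
]

DIAGNOSIS_LEVELS = ("ASD", "NTC")


@dataclasses.dataclass
class SeedFCMatrix:
    """Individuals x spatial-features matrix of seed-FC values for one seed network.

    ``values[i, f]`` is the Pearson correlation between the seed-network mean
    time course of individual ``subject_ids[i]`` and the time course at spatial
    feature ``feature_ids[f]`` (a parcel or a flattened gray-matter voxel).
    Values lie in [-1, 1] before residualization and are unrestricted after.
    """

    values: np.ndarray
    subject_ids: list[str]
    feature_ids: list[str]
    network_id: str = "network"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, f = self.values.shape
        if n != len(self.subject_ids):
            raise ValueError(
                f"{n} rows but {len(self.subject_ids)} subject ids ({self.network_id})"
            )
        if f != len(self.feature_ids):
            raise ValueError(
                f"{f} columns but {len(self.feature_ids)} feature ids ({self.network_id})"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, network_id: str = "network") -> "SeedFCMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            subject_ids=list(df.index.astype(str)),
            feature_ids=list(df.columns.astype(str)),
            network_id=network_id,
        )


def write_fc_matrix(fc: SeedFCMatrix, path) -> None:
    df = fc.to_frame()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


def read_fc_matrix(path, network_id: str | None = None) -> SeedFCMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty or truncated FC matrix")
    if df.isna().all(axis=1).any():
        bad = df.index[df.isna().all(axis=1)].tolist()
        raise ValueError(f"{path}: all-missing rows for subjects {bad}")
    return SeedFCMatrix.from_frame(df, network_id=network_id or path.stem)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path, required: Sequence[str] = ("subject_id", "diagnosis")) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {missing}")
    if "diagnosis" in df.columns:
        bad = set(df["diagnosis"].dropna().unique()) - set(DIAGNOSIS_LEVELS)
        if bad:
            raise ValueError(f"{path}: diagnosis values outside {DIAGNOSIS_LEVELS}: {sorted(bad)}")
    if "session" in df.columns:
        dup = df.duplicated(subset=["subject_id", "session"]).any()
    else:
        dup = df["subject_id"].duplicated().any()
    if dup:
        raise ValueError(f"{path}: duplicate subject ids")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_fc_nifti(img_path, parcellation_path, network_id: str = "network") -> SeedFCMatrix:
    """Read a single 3-D FC map, averaged within the parcels of an integer volume.

    Parcels whose label never occurs inside the volume mask are dropped (logged
    through the returned feature id list simply not containing them).
    """
    import nibabel as nib  # optional dependency

    img = nib.load(str(img_path))
    parc = nib.load(str(parcellation_path))
    data = np.asarray(img.dataobj, dtype=float)
    labels = np.asarray(parc.dataobj)
    if data.shape != labels.shape:
        raise ValueError(f"shape mismatch: map {data.shape} vs parcellation {labels.shape}")
    parcel_ids = [int(p) for p in np.unique(labels) if p != 0]
    means, kept = [], []
    for p in parcel_ids:
        mask = labels == p
        if not mask.any():
            continue
        kept.append(str(p))
        means.append(float(np.nanmean(data[mask])))
    return SeedFCMatrix(
        values=np.asarray(means)[None, :],
        subject_ids=[Path(img_path).stem],
        feature_ids=kept,
        network_id=network_id,
    )


def write_map_nifti(map_values: np.ndarray, parcellation_path, out_path) -> None:
    """Project a parcel-level feature vector back into a 3-D NIfTI volume."""
    import nibabel as nib

    parc = nib.load(str(parcellation_path))
    labels = np.asarray(parc.dataobj)
    parcel_ids = [int(p) for p in np.unique(labels) if p != 0]
    if len(parcel_ids) != len(map_values):
        raise ValueError(
            f"{len(map_values)} values for {len(parcel_ids)} parcels in {parcellation_path}"
        )
    vol = np.zeros(labels.shape, dtype=float)
    for p, v in zip(parcel_ids, map_values):
        vol[labels == p] = v
    nib.save(nib.Nifti1Image(vol, parc.affine), str(out_path))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
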