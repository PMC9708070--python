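"""Synthetic cohorts with the statistical structure the subtyping analysis assumes.

Cross-sectional cohorts are built from K latent subtype prototypes per seed
network (smooth low-rank patterns from a small cosine basis, mutually
orthogonal), with each individual's map a loading on its own prototype plus
additive site offsets, linear age and head-motion effects, and Gaussian
residual noise. The diagnosis effect is injected on the continuous prototype
loading of designated (network, subtype) targets, shifted for ASD individuals
by ``diag_effect_d`` standard deviations of the realized loading distribution
— diagnosis modulates assignment strength, it does not create a separate
cluster. Longitudinal data are frame-level: for every feature f the target
signal is y_t = rho_f x_t + sqrt(1 - rho_f^2) eps_t against the seed signal
x_t, so the sample seed correlation over T frames converges to the subject's
true FC value rho_f, with per-session perturbations of rho on the Fisher-z
scale providing stable-subject/noisy-session structure.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SeedFCMatrix, write_fc_matrix, write_phenotypes
from .timeseries import FrameSeries, write_frame_series

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "LongitudinalCohort",
    "generate_cross_sectional",
    "generate_longitudinal",
    "synthesize_frames",
    "make_toy_fixture",
    "write_cohort",
]

N_BASIS = 10  # cosine basis functions underlying the smooth prototypes
FD_MEDIAN_MM = 0.15
FD_LOG_SD = 0.4
AGE_RANGE_YEARS = (8.0, 40.0)
GRAND_MEAN_SCALE = 0.3
FC_Z_SCALE = 0.25  # maps the latent subject pattern onto the Fisher-z FC scale
FRAME_COMMON_NOISE = 0.95  # shared fraction of frame-level target noise (structured artifacts)
FRAME_NOISE_RANK = 10  # number of smooth spatial profiles carrying the shared frame noise


@dataclasses.dataclass
class SyntheticSpec:
    """Generator configuration. Defaults are the desk-scale study conditions."""

    n_individuals: int = 200
    n_features: int = 200
    n_networks: int = 2
    k_subtypes: int = 3
    prototype_scale: float = 1.0
    loading_sd: float = 0.15
    noise_sd: float = 0.5
    n_sites: int = 3
    site_sd: float = 0.2
    beta_age: float = 0.005
    beta_motion: float = 0.2
    diag_effect_d: float = 0.5
    diag_target_subtypes: tuple = ((0, 0),)
    n_sessions: int = 3
    session_noise_sd: float = 1.5
    frames_per_session: int = 238
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_individuals", "n_features", "n_networks", "k_subtypes",
                     "n_sites", "n_sessions", "frames_per_session"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("prototype_scale", "loading_sd", "noise_sd", "site_sd",
                     "session_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_individuals < 2 * self.k_subtypes:
            raise ValueError(
                f"infeasible spec: {self.k_subtypes} subtypes need at least "
                f"{2 * self.k_subtypes} individuals, got {self.n_individuals}"
            )

    def network_ids(self) -> list[str]:
        return [f"net{i}" for i in range(self.n_networks)]


@dataclasses.dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort, for recovery checks."""

    true_membership: dict[str, np.ndarray]
    true_prototypes: dict[str, np.ndarray]
    true_diagnosis: np.ndarray
    true_subject_maps: dict[str, np.ndarray]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "true_membership": {k: v.tolist() for k, v in self.true_membership.items()},
                    "true_prototypes": {k: v.tolist() for k, v in self.true_prototypes.items()},
                    "true_diagnosis": self.true_diagnosis.tolist(),
                    "true_subject_maps": {k: v.tolist() for k, v in self.true_subject_maps.items()},
                }
            )
        )


def _cosine_basis(n_features: int, n_basis: int = N_BASIS) -> np.ndarray:
    x = (np.arange(n_features) + 0.5) / n_features
    return np.column_stack([np.cos(np.pi * (k + 1) * x) for k in range(n_basis)])


def _make_prototypes(rng: np.random.Generator, k: int, n_features: int, scale: float) -> np.ndarray:
    """k mutually orthogonal smooth patterns, each with per-feature SD = scale."""
    if k > N_BASIS:
        raise ValueError(f"at most {N_BASIS} prototypes supported per network")
    B = _cosine_basis(n_features)
    coeffs = rng.standard_normal((N_BASIS, k))
    P = (B @ coeffs).T  # (k, F)
    Q, _ = np.linalg.qr(P.T)  # orthogonalize in feature space
    P = Q[:, :k].T
    sd = P.std(axis=1, keepdims=True)
    return P / sd * scale


def _standardized_diff(x: np.ndarray, group: np.ndarray) -> float:
    """Cohen's d of x between group=True and group=False (pooled SD)."""
    a, b = x[group], x[~group]
    pooled = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    )
    return float((a.mean() - b.mean()) / pooled)


def _calibrated_diag_shift(
    maps: np.ndarray,
    prototypes: np.ndarray,
    membership: np.ndarray,
    asd: np.ndarray,
    target: int,
    effect_d: float,
) -> np.ndarray:
    """Additive ASD map shift along the centered target prototype.

    The shift magnitude is solved so that the standardized group difference
    (Cohen's d) of the true continuous assignments — spatial correlations of
    the shifted maps with the centered target prototype — equals ``effect_d``
    exactly. Planting the effect on the assignment scale keeps the planted d
    directly comparable with the d the association stage estimates.
    """
    from scipy.optimize import brentq

    counts = np.bincount(membership, minlength=prototypes.shape[0]).astype(float)
    q = prototypes[target] - (counts / counts.sum()) @ prototypes  # centered target map
    u = q / np.linalg.norm(q)

    def planted_d(delta: float) -> float:
        shifted = maps + delta * np.outer(asd.astype(float), u)
        shifted = shifted - shifted.mean(axis=0, keepdims=True)  # group-mean centering
        sc = shifted - shifted.mean(axis=1, keepdims=True)
        a = (sc @ (q - q.mean())) / (np.linalg.norm(sc, axis=1) * np.linalg.norm(q - q.mean()))
        return _standardized_diff(a, asd)

    scale = float(np.linalg.norm(maps, axis=1).mean())
    delta = brentq(lambda d: planted_d(d) - effect_d, -2 * scale, 2 * scale, xtol=1e-10)
    return delta * np.outer(asd.astype(float), u)


def _phenotypes(rng: np.random.Generator, spec: SyntheticSpec) -> pd.DataFrame:
    n = spec.n_individuals
    diagnosis = np.where(np.arange(n) % 2 == 0, "ASD", "NTC")
    site = np.array([f"site{i % spec.n_sites}" for i in range(n)])
    age = rng.uniform(*AGE_RANGE_YEARS, size=n)
    fd = np.exp(rng.normal(np.log(FD_MEDIAN_MM), FD_LOG_SD, size=n))
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "site": site,
            "diagnosis": diagnosis,
            "age": age,
            "mean_fd": fd,
        }
    )


def _balanced_membership(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    labels = np.arange(n) % k
    return rng.permutation(labels)


def generate_cross_sectional(
    spec: SyntheticSpec,
    prototypes: dict[str, np.ndarray] | None = None,
    seed: int | None = None,
) -> tuple[dict[str, SeedFCMatrix], pd.DataFrame, GroundTruth]:
    """Cross-sectional cohort: one seed-FC matrix per network + phenotypes + truth.

    ``prototypes`` lets a replication cohort share the discovery cohort's
    latent prototypes (pass ``ground_truth.true_prototypes``) while drawing
    fresh individuals; ``seed`` overrides ``spec.rng_seed`` for that draw.
    """
    ss = np.random.SeedSequence(spec.rng_seed if seed is None else seed)
    proto_ss, cohort_ss = ss.spawn(2)
    proto_rng = np.random.default_rng(proto_ss)
    rng = np.random.default_rng(cohort_ss)

    phen = _phenotypes(rng, spec)
    asd = (phen["diagnosis"] == "ASD").to_numpy()
    age_c = phen["age"].to_numpy() - phen["age"].mean()
    fd_c = phen["mean_fd"].to_numpy() - phen["mean_fd"].mean()
    site_idx = phen["site"].str.removeprefix("site").astype(int).to_numpy()

    n, F, k = spec.n_individuals, spec.n_features, spec.k_subtypes
    fc: dict[str, SeedFCMatrix] = {}
    membership: dict[str, np.ndarray] = {}
    protos: dict[str, np.ndarray] = {}
    subject_maps: dict[str, np.ndarray] = {}
    feature_ids = [f"f{j}" for j in range(F)]

    for net_i, net in enumerate(spec.network_ids()):
        if prototypes is not None:
            P = np.asarray(prototypes[net], dtype=float)
            # keep the prototype stream in sync so cohorts are comparable
            _ = _make_prototypes(proto_rng, k, F, spec.prototype_scale)
        else:
            P = _make_prototypes(proto_rng, k, F, spec.prototype_scale)
        z = _balanced_membership(rng, n, k)
        L = rng.normal(0.0, spec.loading_sd, size=(n, k)) if spec.loading_sd > 0 else np.zeros((n, k))
        L[np.arange(n), z] += 1.0

        grand = GRAND_MEAN_SCALE * _make_prototypes(proto_rng, 1, F, 1.0)[0]
        site_off = rng.normal(0.0, spec.site_sd, size=(spec.n_sites, F)) if spec.site_sd > 0 else np.zeros((spec.n_sites, F))
        b_age = rng.normal(0.0, spec.beta_age, size=F) if spec.beta_age > 0 else np.zeros(F)
        b_fd = rng.normal(0.0, spec.beta_motion, size=F) if spec.beta_motion > 0 else np.zeros(F)

        clean = (
            grand[None, :]
            + L @ P
            + site_off[site_idx]
            + age_c[:, None] * b_age[None, :]
            + fd_c[:, None] * b_fd[None, :]
        )
        noise = rng.normal(0.0, spec.noise_sd, size=(n, F)) if spec.noise_sd > 0 else 0.0
        maps = clean + noise
        for tgt_net, tgt_sub in spec.diag_target_subtypes:
            if tgt_net == net_i and spec.diag_effect_d != 0:
                shift = _calibrated_diag_shift(maps, P, z, asd, tgt_sub, spec.diag_effect_d)
                maps = maps + shift
                clean = clean + shift
        fc[net] = SeedFCMatrix(
            values=maps,
            subject_ids=list(phen["subject_id"]),
            feature_ids=feature_ids,
            network_id=net,
        )
        membership[net] = z
        protos[net] = P
        subject_maps[net] = clean

    truth = GroundTruth(
        true_membership=membership,
        true_prototypes=protos,
        true_diagnosis=phen["diagnosis"].to_numpy(),
        true_subject_maps=subject_maps,
    )
    return fc, phen, truth


def synthesize_frames(
    rho: np.ndarray,
    n_frames: int,
    rng: np.random.Generator,
    fd_median: float = FD_MEDIAN_MM,
    common_noise: float = 0.0,
    common_profiles: np.ndarray | None = None,
) -> FrameSeries:
    """Frame-level series whose sample seed-FC converges to ``rho`` as T grows.

    ``common_noise`` in [0, 1) mixes frame-level noise components shared
    across target features into the residual term (emulating spatially
    structured physiological/artifact noise); ``common_profiles`` (r x F)
    gives their spatial weights (a single flat profile when omitted). The
    mixture is variance-normalized per feature, so the limiting correlation
    is exactly rho; only the finite-T sampling errors become spatially
    correlated.
    """
    rho = np.asarray(rho, dtype=float)
    if (np.abs(rho) >= 1).any():
        raise ValueError("true FC values must satisfy |rho| < 1")
    if not (0 <= common_noise < 1):
        raise ValueError("common_noise must lie in [0, 1)")
    x = rng.standard_normal(n_frames)
    eps = rng.standard_normal((n_frames, rho.size))
    if common_noise > 0:
        V = np.ones((1, rho.size)) if common_profiles is None else np.asarray(common_profiles, float)
        r = V.shape[0]
        G = rng.standard_normal((n_frames, r))
        mixed = np.sqrt(1 - common_noise) * eps + np.sqrt(common_noise / r) * (G @ V)
        scale = np.sqrt((1 - common_noise) + common_noise / r * (V**2).sum(axis=0))
        eps = mixed / scale[None, :]
    y = x[:, None] * rho[None, :] + np.sqrt(1.0 - rho[None, :] ** 2) * eps
    fd = np.exp(rng.normal(np.log(fd_median), FD_LOG_SD, size=n_frames))
    return FrameSeries(seed_signal=x, target_signals=y, fd=fd)


@dataclasses.dataclass
class LongitudinalCohort:
    """Per-individual, per-session frame-level data for one seed network."""

    sessions: list[list[FrameSeries]]  # [individual][session]
    true_fc: np.ndarray  # (N, F) stable subject FC maps (tanh scale)
    phenotypes: pd.DataFrame
    truth: GroundTruth

    @property
    def n_individuals(self) -> int:
        return len(self.sessions)

    @property
    def n_sessions(self) -> int:
        return len(self.sessions[0])


def generate_longitudinal(
    spec: SyntheticSpec,
    prototypes: dict[str, np.ndarray] | None = None,
    seed: int | None = None,
) -> LongitudinalCohort:
    """Longitudinal cohort for the first seed network of the spec.

    Each individual has a stable true FC map rho = tanh(z) with z the latent
    prototype pattern on the Fisher-z scale. Each session adds a smooth
    spatially structured perturbation (a fresh cosine-basis pattern of
    amplitude ``session_noise_sd`` relative to the prototype scale) before
    frame synthesis, so per-session FC estimates are noisy realizations of a
    stable subject map — both the number of sessions averaged and the number
    of frames per session then genuinely limit test-retest reliability.
    """
    if spec.n_sessions < 2:
        raise ValueError("need n_sessions >= 2")
    if spec.frames_per_session < 10:
        raise ValueError("need frames_per_session >= 10")
    ss = np.random.SeedSequence(spec.rng_seed if seed is None else seed)
    proto_ss, cohort_ss = ss.spawn(2)
    proto_rng = np.random.default_rng(proto_ss)
    rng = np.random.default_rng(cohort_ss)

    n, F, k = spec.n_individuals, spec.n_features, spec.k_subtypes
    net = spec.network_ids()[0]
    if prototypes is not None:
        P = np.asarray(prototypes[net], dtype=float)
    else:
        P = _make_prototypes(proto_rng, k, F, spec.prototype_scale)
    phen = _phenotypes(rng, spec)
    z_lab = _balanced_membership(rng, n, k)
    L = rng.normal(0.0, spec.loading_sd, size=(n, k)) if spec.loading_sd > 0 else np.zeros((n, k))
    L[np.arange(n), z_lab] += 1.0
    z_maps = FC_Z_SCALE * (L @ P)  # latent subject pattern, Fisher-z scale
    true_fc = np.tanh(z_maps)

    B = _cosine_basis(F)
    sessions: list[list[FrameSeries]] = []
    for i in range(n):
        per_subject = []
        for _s in range(spec.n_sessions):
            if spec.session_noise_sd > 0:
                pat = B @ rng.standard_normal(N_BASIS)
                pat *= spec.prototype_scale / pat.std()
                z_ses = z_maps[i] + FC_Z_SCALE * spec.session_noise_sd * pat
            else:
                z_ses = z_maps[i]
            V = (B @ rng.standard_normal((N_BASIS, FRAME_NOISE_RANK))).T
            V /= V.std(axis=1, keepdims=True)
            per_subject.append(
                synthesize_frames(
                    np.tanh(z_ses), spec.frames_per_session, rng,
                    common_noise=FRAME_COMMON_NOISE, common_profiles=V,
                )
            )
        sessions.append(per_subject)

    truth = GroundTruth(
        true_membership={net: z_lab},
        true_prototypes={net: P},
        true_diagnosis=phen["diagnosis"].to_numpy(),
        true_subject_maps={net: true_fc},
    )
    return LongitudinalCohort(sessions=sessions, true_fc=true_fc, phenotypes=phen, truth=truth)


def make_toy_fixture() -> tuple[SeedFCMatrix, np.ndarray]:
    """Tiny deterministic dataset: 12 individuals x 8 features, 2 planted subtypes.

    The two prototypes are near-anticorrelated, so the two blocks have
    within-block dissimilarity < 0.3 and between-block dissimilarity > 1.5 and
    the fixture splits into exactly 2 subtypes even at theta = 1.
    """
    rng = np.random.default_rng(20220715)
    p1 = np.array([1.0, 0.8, 0.2, -0.4, -1.0, -0.6, 0.3, 0.7])
    p2 = -p1 + np.array([0.05, -0.05, 0.1, 0.0, -0.1, 0.05, 0.0, -0.05])
    labels = np.array([0] * 6 + [1] * 6)
    maps = np.where(labels[:, None] == 0, p1[None, :], p2[None, :])
    maps = maps + 0.03 * rng.standard_normal(maps.shape)
    maps = maps - maps.mean(axis=0, keepdims=True)
    fc = SeedFCMatrix(
        values=maps,
        subject_ids=[f"toy-{i:02d}" for i in range(12)],
        feature_ids=[f"f{j}" for j in range(8)],
        network_id="toy",
    )
    return fc, labels


def write_cohort(
    out_dir,
    fc: dict[str, SeedFCMatrix],
    phenotypes: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> None:
    """Write a cohort as TSV matrices + CSV phenotypes (+ JSON ground truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for net, mat in fc.items():
        write_fc_matrix(mat, out / f"fc_{net}.tsv")
    write_phenotypes(phenotypes, out / "phenotypes.csv")
    if truth is not None:
        truth.to_json(out / "ground_truth.json")


def write_longitudinal(out_dir, cohort: LongitudinalCohort) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, per_subject in enumerate(cohort.sessions):
        for s, series in enumerate(per_subject):
            write_frame_series(series, out / f"sub-{i:04d}_ses-{s}.tsv")
    write_phenotypes(cohort.phenotypes, out / "phenotypes.csv")
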