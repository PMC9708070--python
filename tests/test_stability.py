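import numpy as np
import pandas as pd
import pytest

from fcsubtypes import SyntheticSpec, generate_longitudinal
from fcsubtypes.stability import (
    SubsamplePair,
    dice_coefficient,
    dice_discrete_stability,
    half_split_subsamples,
    icc,
    icc_session_analysis,
    map_match_stability,
)
from fcsubtypes.subtyping import UNASSIGNED, FCSubtyper
from fcsubtypes.timeseries import truncate_and_average
from fcsubtypes._utils import pearson_rows


def _phen(n_asd, n_ntc):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n_asd + n_ntc)],
            "diagnosis": ["ASD"] * n_asd + ["NTC"] * n_ntc,
        }
    )


class TestHalfSplitSubsamples:
    def test_equal_groups_split_evenly(self):
        pairs = half_split_subsamples(_phen(194, 194), n_subsamples=20, n_pairs=10, seed=0)
        phen = _phen(194, 194)
        for pair in pairs:
            for idx in (pair.indices_a, pair.indices_b):
                diag = phen["diagnosis"].iloc[idx]
                assert (diag == "ASD").sum() == 97 and (diag == "NTC").sum() == 97

    def test_ratio_preserved_within_one_for_odd_groups(self):
        phen = _phen(101, 88)
        pairs = half_split_subsamples(phen, n_subsamples=10, n_pairs=5, seed=1)
        for pair in pairs:
            diag = phen["diagnosis"].iloc[pair.indices_a]
            assert len(pair.indices_a) == 94  # floor(189/2)
            assert abs((diag == "ASD").sum() - 101 / 2) <= 1

    def test_deterministic_and_unique_pairs(self):
        a = half_split_subsamples(_phen(20, 20), n_subsamples=30, n_pairs=20, seed=42)
        b = half_split_subsamples(_phen(20, 20), n_subsamples=30, n_pairs=20, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.indices_a, y.indices_a)
            assert np.array_equal(x.indices_b, y.indices_b)

    def test_too_many_pairs_rejected(self):
        with pytest.raises(ValueError, match="unique pairs"):
            half_split_subsamples(_phen(10, 10), n_subsamples=3, n_pairs=10, seed=0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="diagnosis"):
            half_split_subsamples(_phen(10, 0), n_subsamples=2, n_pairs=1, seed=0)


class TestDice:
    def test_hand_sets_match_brute_force_arithmetic(self):
        assert dice_coefficient({1, 2, 3}, {2, 3, 4}) == pytest.approx(2 * 2 / 6)
        assert dice_coefficient({1, 2}, {1, 2}) == 1.0
        assert dice_coefficient({1}, {2}) == 0.0

    def test_identical_communities_score_one(self):
        pair = SubsamplePair(np.arange(6), np.arange(6), 0)
        labels = np.array([0, 0, 0, 1, 1, 1])
        df, mean = dice_discrete_stability(labels, labels, pair)
        assert mean == 1.0
        assert (df["dice"] == 1.0).all()

    def test_disjoint_neighbourhoods_score_zero(self):
        # individual 0 keeps different companions in A and B
        pair = SubsamplePair(np.arange(5), np.arange(5), 0)
        labels_a = np.array([0, 0, 1, 1, 1])  # neighbours of 0 in A: {1}
        labels_b = np.array([0, 1, 0, 1, 1])  # neighbours of 0 in B: {2}
        df, _ = dice_discrete_stability(labels_a, labels_b, pair)
        assert df.loc[df["individual"] == 0, "dice"].item() == 0.0

    def test_symmetric_and_renumbering_invariant(self, rng):
        idx = np.arange(12)
        pair = SubsamplePair(idx, idx, 0)
        la = rng.integers(0, 3, 12)
        lb = rng.integers(0, 3, 12)
        _, m_ab = dice_discrete_stability(la, lb, pair)
        _, m_ba = dice_discrete_stability(lb, la, pair)
        assert m_ab == pytest.approx(m_ba)
        relabel = np.array([2, 0, 1])
        _, m_renum = dice_discrete_stability(la, relabel[lb], pair)
        assert m_renum == pytest.approx(m_ab)

    def test_restricted_to_intersection_and_unassigned_excluded(self):
        pair = SubsamplePair(np.array([0, 1, 2, 3]), np.array([1, 2, 3, 4]), 0)
        labels_a = np.array([0, 0, 0, UNASSIGNED])
        labels_b = np.array([0, 0, 0, 0])
        df, mean = dice_discrete_stability(labels_a, labels_b, pair)
        assert set(df["individual"]) == {1, 2, 3}
        assert not df.loc[df["individual"] == 3, "assigned_in_both"].item()
        # neighbours of 1 within the intersection: {2} in A vs {2, 3} in B
        assert mean == pytest.approx(2 / 3)

    def test_empty_intersection_rejected(self):
        pair = SubsamplePair(np.array([0, 1]), np.array([2, 3]), 0)
        with pytest.raises(ValueError, match="intersection"):
            dice_discrete_stability(np.zeros(2, int), np.zeros(2, int), pair)


class TestMapMatch:
    def test_self_match_is_one(self, rng):
        maps = rng.standard_normal((4, 9))
        assert map_match_stability(maps, maps) == pytest.approx(1.0, abs=1e-12)

    def test_forced_negative_match(self, rng):
        m = rng.standard_normal((1, 9))
        assert map_match_stability(m, -m) == pytest.approx(-1.0, abs=1e-12)

    def test_directional_mean_of_maxima_with_replacement(self, rng):
        A, B = rng.standard_normal((3, 10)), rng.standard_normal((2, 10))
        R = pearson_rows(A, B)
        assert map_match_stability(A, B) == pytest.approx(R.max(axis=1).mean(), abs=1e-12)

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            map_match_stability(np.empty((0, 5)), rng.standard_normal((2, 5)))


def brute_force_icc1(X):
    """One-way ANOVA oracle computed from raw sums of squares."""
    X = np.asarray(X, float)
    n, k = X.shape
    grand = X.mean()
    ss_between = k * sum((X[i].mean() - grand) ** 2 for i in range(n))
    ss_within = sum((X[i, j] - X[i].mean()) ** 2 for i in range(n) for j in range(k))
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestICC:
    def test_identical_sessions_give_one(self, rng):
        x = rng.standard_normal(10)
        assert icc(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        X = rng.standard_normal((1000, 2))
        assert abs(icc(X)) < 0.1

    def test_hand_table_matches_anova_oracle(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        assert icc(X) == pytest.approx(77 / 83, abs=1e-12)
        assert icc(X) == pytest.approx(brute_force_icc1(X), abs=1e-12)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(30):
            X = rng.standard_normal((int(rng.integers(3, 30)), int(rng.integers(2, 5))))
            assert icc(X) == pytest.approx(brute_force_icc1(X), abs=1e-10)

    def test_matches_pingouin_reference(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.standard_normal((25, 2)) + rng.standard_normal((25, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(25), 2),
                "rater": np.tile([0, 1], 25),
                "score": X.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        ref = ref.set_index("Type")["ICC"]
        assert icc(X) == pytest.approx(ref["ICC(1,1)"], abs=1e-8)
        assert icc(X, form="icc2") == pytest.approx(ref["ICC(A,1)"], abs=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc(np.ones((5, 2)))

    def test_negative_values_reported_as_computed(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        assert icc(X) < 0


@pytest.fixture(scope="module")
def longitudinal_fc():
    spec = SyntheticSpec(
        n_individuals=24, n_features=50, n_networks=1, k_subtypes=2,
        n_sessions=3, frames_per_session=120, rng_seed=5,
    )
    lc = generate_longitudinal(spec)
    session_fc = [
        np.vstack([
            truncate_and_average([lc.sessions[i][s]], M=1, K=1, n_frame_min=120, scrub=False)
            for i in range(lc.n_individuals)
        ])
        for s in range(3)
    ]
    return lc, session_fc


class TestSessionAnalysis:
    def test_identical_test_sessions_give_unit_icc(self, longitudinal_fc):
        _, session_fc = longitudinal_fc
        vals = icc_session_analysis(
            [session_fc[0], session_fc[1], session_fc[1]],
            subtype_source="within_sample", theta=0.8, min_size=5,
        )
        assert len(vals) >= 1
        assert np.allclose(vals, 1.0, atol=1e-10)

    def test_within_sample_icc_in_unit_interval_band(self, longitudinal_fc):
        _, session_fc = longitudinal_fc
        vals = icc_session_analysis(session_fc, subtype_source="within_sample", theta=0.8, min_size=5)
        assert len(vals) >= 1
        assert np.all(vals <= 1.0)

    def test_out_of_sample_transfer_penalty_on_average(self):
        within_all, out_all = [], []
        for seed in range(6):
            spec = SyntheticSpec(
                n_individuals=24, n_features=50, n_networks=1, k_subtypes=2,
                n_sessions=3, frames_per_session=120, rng_seed=seed,
            )
            lc = generate_longitudinal(spec)
            other = generate_longitudinal(spec, prototypes=lc.truth.true_prototypes, seed=seed + 100)

            def fc_of(cohort, s):
                return np.vstack([
                    truncate_and_average([cohort.sessions[i][s]], M=1, K=1, n_frame_min=120, scrub=False)
                    for i in range(cohort.n_individuals)
                ])

            sessions = [fc_of(lc, s) for s in range(3)]
            within = icc_session_analysis(sessions, "within_sample", theta=0.8, min_size=5)
            from fcsubtypes.residualize import ConfoundRegressor

            resid_other = ConfoundRegressor().fit_transform(fc_of(other, 0))
            model = FCSubtyper(theta=0.8, min_size=5).fit(resid_other).to_model()
            if model.n_subtypes == 0 or len(within) == 0:
                continue
            out = icc_session_analysis(sessions[1:], "out_of_sample", model=model)
            within_all.append(np.mean(within))
            out_all.append(np.mean(out))
        assert len(within_all) >= 4
        assert np.mean(out_all) <= np.mean(within_all) + 0.05

    def test_mode_preconditions(self, longitudinal_fc):
        _, session_fc = longitudinal_fc
        with pytest.raises(ValueError, match="3 sessions"):
            icc_session_analysis(session_fc[:2], "within_sample")
        with pytest.raises(ValueError, match="SubtypeModel"):
            icc_session_analysis(session_fc, "out_of_sample")
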