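import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fcsubtypes.association import (
    diagnosis_association,
    effect_ci,
    fdr_adjust,
    replication_ladder,
    replication_transfer,
    symptom_association,
)
from fcsubtypes.subtyping import FCSubtyper


def brute_force_bh(p):
    """Step-up BH oracle: adj_(i) = min_{j>=i} (m p_(j) / j), clipped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestDiagnosisAssociation:
    def test_identical_groups_give_null_statistics(self):
        A = np.tile(np.array([[0.1], [0.1], [0.4], [0.4]]), (5, 1))
        diag = np.array(["ASD", "NTC"] * 10)
        table = diagnosis_association(A, diag)
        assert table["t_statistic"].item() == pytest.approx(0.0, abs=1e-12)
        assert table["cohen_d"].item() == pytest.approx(0.0, abs=1e-12)

    def test_hand_table_matches_pooled_formula(self):
        A = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        diag = np.array(["ASD"] * 3 + ["NTC"] * 3)
        table = diagnosis_association(A, diag)
        assert table["cohen_d"].item() == pytest.approx((2.0 - 5.0) / 1.0, abs=1e-12)
        assert table["direction"].item() == "negASD"

    def test_label_swap_negates_t_and_d(self, rng):
        A = rng.standard_normal((40, 3))
        diag = np.array(["ASD", "NTC"] * 20)
        swapped = np.where(diag == "ASD", "NTC", "ASD")
        t1 = diagnosis_association(A, diag)
        t2 = diagnosis_association(A, swapped)
        assert np.allclose(t1["t_statistic"], -t2["t_statistic"], atol=1e-12)
        assert np.allclose(t1["cohen_d"], -t2["cohen_d"], atol=1e-12)

    def test_planted_standardized_shift_recovered(self, rng):
        ds = []
        for _ in range(50):
            a = rng.standard_normal(200) + 0.5
            b = rng.standard_normal(200)
            A = np.concatenate([a, b])[:, None]
            diag = np.array(["ASD"] * 200 + ["NTC"] * 200)
            ds.append(diagnosis_association(A, diag)["cohen_d"].item())
        se = np.sqrt(2 / 200 + 0.25 / 800)
        assert abs(np.mean(ds) - 0.5) < 3 * se / np.sqrt(50)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            diagnosis_association(np.zeros((4, 1)), np.array(["ASD"] * 4))

    def test_bh_monotonicity_invariant(self, rng):
        A = rng.standard_normal((60, 8))
        diag = np.array(["ASD", "NTC"] * 30)
        table = diagnosis_association(A, diag).sort_values("p_raw")
        assert (table["p_adj"].to_numpy() >= table["p_raw"].to_numpy() - 1e-15).all()
        assert (np.diff(table["p_adj"]) >= -1e-15).all()


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_hand_example(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_ones_stay_ones(self):
        assert np.allclose(fdr_adjust(np.ones(7)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_stepup(self, p):
        assert np.allclose(fdr_adjust(p), brute_force_bh(p), atol=1e-12)


class TestEffectCI:
    def test_null_effect_halfwidth(self):
        lo, hi = effect_ci(0.0, 194, 194, 0.95)
        half = 1.959963984540054 * np.sqrt(2 / 194)
        assert hi == pytest.approx(half, abs=1e-9)
        assert lo == pytest.approx(-half, abs=1e-9)

    def test_narrower_with_larger_n_and_contains_d(self, rng):
        for _ in range(10):
            d = rng.normal(0, 1)
            lo1, hi1 = effect_ci(d, 20, 20)
            lo2, hi2 = effect_ci(d, 200, 200)
            assert (hi2 - lo2) < (hi1 - lo1)
            assert lo1 < d < hi1

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            effect_ci(0.2, 10, 10, level=1.5)


class TestSymptomAssociation:
    def test_scores_equal_to_assignments_give_unit_r(self, rng):
        a = rng.standard_normal(30)
        table = symptom_association(a[:, None], a)
        assert table["r"].item() == pytest.approx(1.0)

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            symptom_association(rng.standard_normal((10, 1)), np.ones(10))

    def test_subset_rule_and_missing_scores(self, rng):
        A = rng.standard_normal((40, 2))
        scores = rng.standard_normal(40)
        scores[:10] = np.nan
        asd = np.zeros(40, bool)
        asd[15:] = True
        table = symptom_association(A, scores, subset_mask=asd)
        assert (table["n"] == 25).all()

    def test_planted_linear_coupling_recovered(self, rng):
        r_target, n = 0.3, 200
        rs = []
        for _ in range(20):
            a = rng.standard_normal(n)
            scores = r_target * a + np.sqrt(1 - r_target**2) * rng.standard_normal(n)
            rs.append(symptom_association(a[:, None], scores)["r"].item())
        assert abs(np.mean(rs) - r_target) < 0.05


class TestReplication:
    @pytest.fixture()
    def discovery(self, residuals, cohort):
        _, fc, phen, _ = cohort
        X = residuals["net0"]
        st = FCSubtyper(theta=0.5, min_size=20).fit(X)
        table = diagnosis_association(st.transform(X), phen["diagnosis"])
        return X, st.to_model(), phen, table

    def test_self_transfer_reproduces_discovery_effects(self, discovery):
        X, model, phen, table = discovery
        if not table["significant"].any():
            pytest.skip("no significant discovery subtype in this draw")
        _, repl = replication_transfer(X, model, phen["diagnosis"], discovery_table=table)
        merged = table.merge(repl, on="subtype", suffixes=("_d", "_r"))
        assert np.allclose(merged["cohen_d_d"], merged["cohen_d_r"], atol=1e-12)

    def test_feature_mismatch_rejected(self, discovery, rng):
        _, model, phen, _ = discovery
        with pytest.raises(ValueError):
            replication_transfer(rng.standard_normal((10, 3)), model, phen["diagnosis"][:10])

    def test_identical_tables_pass_every_rung(self):
        table = pd.DataFrame(
            {
                "subtype": ["s0", "s1", "s2"],
                "p_raw": [0.001, 0.03, 0.2],
                "p_adj": [0.003, 0.045, 0.2],
                "cohen_d": [0.5, -0.4, 0.1],
                "n_ASD": [100] * 3,
                "n_NTC": [100] * 3,
                "significant": [True, True, False],
            }
        )
        ladder, conc = replication_ladder(table, table)
        assert ladder[["fdr_replicated", "p05_replicated", "within_ci", "same_direction"]].all().all()
        assert conc["r_all"] == pytest.approx(1.0)
        assert conc["r_significant"] == pytest.approx(1.0)

    def test_hand_built_flag_truth_table(self):
        disc = pd.DataFrame(
            {
                "subtype": ["s0", "s1", "s2"],
                "p_raw": [0.001, 0.002, 0.003],
                "p_adj": [0.003, 0.004, 0.005],
                "cohen_d": [0.5, -0.4, 0.3],
                "n_ASD": [100] * 3,
                "n_NTC": [100] * 3,
                "significant": [True, True, True],
            }
        )
        repl = pd.DataFrame(
            {
                "subtype": ["s0", "s1", "s2"],
                "p_raw": [0.001, 0.04, 0.5],
                "p_adj": [0.003, 0.08, 0.5],
                "cohen_d": [0.45, -0.35, -0.05],
                "n_ASD": [100] * 3,
                "n_NTC": [100] * 3,
                "significant": [True, False, False],
            }
        )
        ladder, _ = replication_ladder(disc, repl, ci_level=0.90)
        row = ladder.set_index("subtype")
        assert row.loc["s0", ["fdr_replicated", "p05_replicated", "within_ci", "same_direction"]].all()
        assert not row.loc["s1", "fdr_replicated"] and row.loc["s1", "p05_replicated"]
        assert not row.loc["s2", "same_direction"]
        # fdr implies p05 numerically on every row
        assert (~ladder["fdr_replicated"] | ladder["p05_replicated"]).all()

    def test_no_common_subtypes_rejected(self):
        t1 = pd.DataFrame({"subtype": ["a"], "p_raw": [0.1], "p_adj": [0.1], "cohen_d": [0.1],
                           "n_ASD": [10], "n_NTC": [10], "significant": [False]})
        t2 = t1.assign(subtype=["b"])
        with pytest.raises(ValueError, match="common"):
            replication_ladder(t1, t2)


def test_null_fdr_calibration_over_many_cohorts(rng):
    """Under the global null the FDR-significant proportion stays near or below q."""
    hits, total = 0, 0
    for _ in range(200):
        A = rng.standard_normal((80, 10))
        diag = np.array(["ASD", "NTC"] * 40)
        table = diagnosis_association(A, diag)
        hits += int(table["significant"].sum())
        total += len(table)
    prop = hits / total
    assert prop <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / total)
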