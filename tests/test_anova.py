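"""RRPP Procrustes ANOVA, allometry adjustment, repeatability and
nested variance partitioning."""
import numpy as np
import pandas as pd
import pytest

import gmrepro as g
from gmrepro.anova import DesignError


class TestProcrustesANOVA:
    def test_pure_group_shift_explains_everything(self):
        Y = np.zeros((20, 6))
        groups = np.repeat(["a", "b"], 10)
        Y[groups == "b"] += 1.0
        res = g.procrustes_anova(Y, pd.DataFrame({"group": groups}), ["group"],
                                 n_permutations=199, seed=0)
        assert res.table.loc["group", "Rsq"] == pytest.approx(1.0)
        assert res.table.loc["group", "P"] == pytest.approx(1 / 200)

    def test_p_value_floor(self, rng):
        Y = rng.normal(size=(30, 4))
        Y[15:] += 10.0
        data = pd.DataFrame({"group": np.repeat(["a", "b"], 15)})
        res = g.procrustes_anova(Y, data, ["group"], n_permutations=99, seed=1)
        assert res.table.loc["group", "P"] >= 1 / 100

    def test_ss_partition_sums_to_total(self, rng):
        Y = rng.normal(size=(40, 8))
        data = pd.DataFrame({
            "group": np.repeat(["a", "b"], 20),
            "x": rng.normal(size=40),
        })
        res = g.procrustes_anova(Y, data, ["x", "group"], n_permutations=99, seed=2)
        t = res.table
        assert (t.loc["x", "SS"] + t.loc["group", "SS"] + t.loc["Residuals", "SS"]
                ) == pytest.approx(t.loc["Total", "SS"], rel=1e-10)
        assert t.loc["Total", "Rsq"] == pytest.approx(1.0)

    def test_effect_detected_with_small_p_and_positive_z(self, rng):
        Y = rng.normal(size=(60, 10))
        groups = np.repeat(["a", "b"], 30)
        Y[groups == "b", 0] += 2.0
        res = g.procrustes_anova(Y, pd.DataFrame({"group": groups}), ["group"],
                                 n_permutations=499, seed=3)
        assert res.table.loc["group", "P"] <= 0.01
        assert res.table.loc["group", "Z"] > 2.0

    def test_aliased_term_rejected(self, rng):
        Y = rng.normal(size=(20, 4))
        data = pd.DataFrame({"g1": np.repeat(["a", "b"], 10)})
        data["g2"] = data["g1"]
        with pytest.raises(DesignError, match="aliased"):
            g.procrustes_anova(Y, data, ["g1", "g2"], n_permutations=99, seed=0)

    def test_low_permutation_count_warns(self, rng):
        Y = rng.normal(size=(20, 4))
        data = pd.DataFrame({"group": np.repeat(["a", "b"], 10)})
        with pytest.warns(UserWarning, match="low"):
            g.procrustes_anova(Y, data, ["group"], n_permutations=49, seed=0)

    def test_seeded_determinism(self, rng):
        Y = rng.normal(size=(30, 6))
        data = pd.DataFrame({"group": np.repeat(["a", "b"], 15)})
        a = g.procrustes_anova(Y, data, ["group"], n_permutations=199, seed=42)
        b = g.procrustes_anova(Y, data, ["group"], n_permutations=199, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestAllometryAdjust:
    def test_zero_slope_is_identity(self, rng):
        Y = rng.normal(size=(40, 6))
        log_cs = rng.normal(size=40)
        groups = np.repeat(["a", "b"], 20)
        # construct data with exactly zero fitted slope by orthogonalising
        X = np.column_stack([np.ones(40), log_cs,
                             (groups == "b").astype(float)])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        Y0 = Y - np.outer(X[:, 1], beta[1])
        adjusted = g.allometry_adjust(Y0, log_cs, groups)
        np.testing.assert_allclose(adjusted, Y0, atol=1e-8)

    def test_removes_known_allometric_vector(self, rng):
        a = rng.normal(size=10)
        log_cs = rng.normal(size=200)
        groups = np.repeat(["a", "b"], 100)
        Y = rng.normal(0, 0.05, size=(200, 10)) + np.outer(log_cs, a)
        adjusted = g.allometry_adjust(Y, log_cs, groups)
        X = np.column_stack([np.ones(200), log_cs])
        beta, *_ = np.linalg.lstsq(X, adjusted, rcond=None)
        assert np.linalg.norm(beta[1]) < 0.01 * np.linalg.norm(a)

    def test_group_difference_preserved_in_balanced_design(self, rng):
        """When size distributions match across groups, the group mean
        difference survives adjustment unchanged."""
        log_cs_half = rng.normal(size=50)
        log_cs = np.concatenate([log_cs_half, log_cs_half])
        groups = np.repeat(["a", "b"], 50)
        a = rng.normal(size=8)
        delta = rng.normal(size=8)
        Y = np.outer(log_cs, a) + rng.normal(0, 0.01, size=(100, 8))
        Y[groups == "b"] += delta
        before = Y[groups == "b"].mean(0) - Y[groups == "a"].mean(0)
        adjusted = g.allometry_adjust(Y, log_cs, groups)
        after = adjusted[groups == "b"].mean(0) - adjusted[groups == "a"].mean(0)
        np.testing.assert_allclose(after, before, atol=1e-8)

    def test_constant_size_warns_and_passes_through(self, rng):
        Y = rng.normal(size=(10, 4))
        with pytest.warns(UserWarning, match="constant"):
            adjusted = g.allometry_adjust(Y, np.ones(10), np.repeat(["a", "b"], 5))
        np.testing.assert_array_equal(adjusted, Y)


class TestRepeatability:
    def test_identical_replicates_give_one(self, rng):
        base = rng.normal(size=(20, 6))
        Y = np.repeat(base, 3, axis=0)
        ind = np.repeat(np.arange(20), 3)
        res = g.repeatability(Y, ind, m=3)
        assert res.R == 1.0
        assert res.ms_within == 0.0

    def test_null_variance_ratio_near_zero(self, rng):
        """No among-individual variance: R should be near zero."""
        n, m, d = 200, 3, 8
        Y = rng.normal(size=(n * m, d))
        ind = np.repeat(np.arange(n), m)
        res = g.repeatability(Y, ind, m=m)
        assert abs(res.R) < 0.05

    def test_recovers_nine_to_one_ratio(self, rng):
        n, m, d = 100, 3, 10
        among = rng.normal(0, 3.0, size=(n, d))
        Y = np.repeat(among, m, axis=0) + rng.normal(0, 1.0, size=(n * m, d))
        res = g.repeatability(Y, np.repeat(np.arange(n), m), m=m)
        assert res.R == pytest.approx(0.9, abs=0.03)

    def test_unbalanced_rejected(self, rng):
        Y = rng.normal(size=(5, 4))
        ind = np.array([0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="unbalanced"):
            g.repeatability(Y, ind, m=3)


class TestNestedPartition:
    def test_pure_individual_signal(self, rng):
        base = rng.normal(size=(10, 6))
        ids = np.repeat(np.arange(10), 6)
        ops = np.tile(np.repeat(["A", "B"], 3), 10)
        Y = base[ids]
        table = g.nested_variance_partition(Y, ids, ops)
        assert table.set_index("term").loc["ID", "fraction"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, rng):
        ids = np.repeat(np.arange(8), 6)
        ops = np.tile(np.repeat(["A", "B"], 3), 8)
        Y = rng.normal(size=(48, 5))
        table = g.nested_variance_partition(Y, ids, ops)
        assert table["fraction"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_recovers_generator_truth_fractions(self, small_data, small_spec):
        """Pipeline fractions (after unbend + GPA) agree with the oracle
        decomposition computed on the raw shape-space observations."""
        ds, truth = small_data
        rep_ids = set(
            truth.specimens.loc[truth.specimens["replicate"], "specimen_id"]
        )
        mask = ds.factors["specimen_id"].isin(rep_ids).to_numpy()
        oracle_obs = truth.shape_space_observations[mask]
        fac = ds.factors[mask]
        oracle = g.nested_variance_partition(
            oracle_obs.reshape(oracle_obs.shape[0], -1),
            fac["specimen_id"].to_numpy(), fac["operator"].to_numpy(),
        )
        sub = g.unbend(ds.subset(mask)).drop_excluded()
        fit = g.gpa(sub)
        measured = g.nested_variance_partition(
            fit.flat, fit.factors["specimen_id"].to_numpy(),
            fit.factors["operator"].to_numpy(),
        )
        np.testing.assert_allclose(
            measured["fraction"], oracle["fraction"], atol=0.05
        )

    def test_incomplete_crossing_rejected(self, rng):
        Y = rng.normal(size=(5, 4))
        ids = np.array([0, 0, 1, 1, 1])
        ops = np.array(["A", "B", "A", "A", "B"])
        with pytest.raises(ValueError):
            g.nested_variance_partition(Y, ids, ops)
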