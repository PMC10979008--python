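"""ANOVA, BH adjustment, fold change, DE calling and the late-stage rule."""

import numpy as np
import pandas as pd
import pytest

from psdremodel import synthetic
from psdremodel.de import (
    anova_per_protein,
    bh_adjust,
    call_de,
    classic_anova,
    late_de,
    max_fold_change,
    welch_anova,
)

from test_quant import make_table


def brute_force_bh(p):
    """Independent BH step-up: q_(i) = min_{j>=i} m * p_(j) / j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(m * p[order[j - 1]] / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


class TestWelchANOVA:
    def test_identical_groups_give_p_one(self):
        vals = np.array([[5.0] * 12])
        assert welch_anova(vals, [4, 4, 4])[0] == 1.0

    def test_identical_distributions_give_p_one(self):
        vals = np.array([[1, 2, 3] * 4], dtype=float)
        assert welch_anova(vals, [3, 3, 3, 3])[0] == 1.0

    def test_separated_pairs_match_reference_value(self):
        # {10,11},{10,11},{20,21},{20,21}: Welch p frozen from R oneway.test
        vals = np.array([[10, 11, 10, 11, 20, 21, 20, 21]], dtype=float)
        p = welch_anova(vals, [2, 2, 2, 2])[0]
        assert p == pytest.approx(0.00803311187798, rel=1e-9)
        assert p < 0.01

    def test_matches_pingouin_on_random_data(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 2, size=(20, 12))
        ours = welch_anova(vals, [4, 4, 4])
        for i in range(20):
            frame = pd.DataFrame(
                {"y": vals[i], "g": np.repeat(["a", "b", "c"], 4)}
            )
            ref = pingouin.welch_anova(frame, dv="y", between="g")["p_unc"][0]
            assert ours[i] == pytest.approx(ref, rel=1e-9)

    def test_zero_variance_unequal_means_smallest_p(self):
        vals = np.array([[1, 1, 2, 2]], dtype=float)
        p = welch_anova(vals, [2, 2])[0]
        assert 0 < p <= 5e-324

    def test_classic_matches_scipy(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(5)
        vals = rng.normal(size=(10, 12))
        ours = classic_anova(vals, [4, 4, 4])
        ref = f_oneway(vals[:, :4], vals[:, 4:8], vals[:, 8:], axis=1).pvalue
        assert np.allclose(ours, ref)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(7)
        vals = rng.lognormal(3, 0.5, size=(50, 16))
        p1 = welch_anova(vals, [4, 4, 4, 4])
        p2 = welch_anova(vals * 7.3, [4, 4, 4, 4])
        assert np.allclose(p1, p2)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_spec_example_vector(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_capped(self):
        assert (bh_adjust([1.0] * 5) == 1.0).all()

    def test_against_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.max(np.abs(bh_adjust(p) - brute_force_bh(p))) < 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()


class TestFoldChange:
    def test_direct_ratio(self):
        means = pd.DataFrame([[100, 150, 80, 120]], index=["p"])
        assert max_fold_change(means)["p"] == pytest.approx(1.875)

    def test_constant_means_give_one(self):
        means = pd.DataFrame([[5, 5, 5]], index=["p"])
        assert max_fold_change(means)["p"] == 1.0

    def test_direction_free(self):
        up = pd.DataFrame([[1, 2]], index=["p"])
        down = pd.DataFrame([[2, 1]], index=["p"])
        assert max_fold_change(up)["p"] == max_fold_change(down)["p"] == 2.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            max_fold_change(pd.DataFrame([[0.0, 1.0]]))


class TestCallDE:
    def _inputs(self):
        idx = pd.Index(["a", "b", "c", "d"])
        p = pd.Series([1e-6, 0.04, 1e-6, 0.5], index=idx)
        fc = pd.Series([2.0, 1.4, 3.0, 4.0], index=idx)
        clusters = pd.Series([1, 1, 3, 2], index=idx)
        return p, fc, clusters

    def test_both_criteria_required(self):
        p, fc, clusters = self._inputs()
        res = call_de(p, fc, clusters)
        # "b": q = 0.053 and FC 1.4 -> fails both; "d": p large -> not DE
        assert res.table.loc["a", "de"] and res.table.loc["c", "de"]
        assert not res.table.loc["b", "de"]
        assert not res.table.loc["d", "de"]

    def test_group_assignment_follows_clusters(self):
        p, fc, clusters = self._inputs()
        res = call_de(p, fc, clusters)
        assert res.table.loc["a", "group"] == "DDP"
        assert res.table.loc["c", "group"] == "DIP"
        assert res.table.loc["b", "group"] == ""

    def test_flat_cluster_de_stays_unlabelled(self):
        idx = pd.Index(["x"])
        res = call_de(
            pd.Series([1e-8], index=idx),
            pd.Series([5.0], index=idx),
            pd.Series([2], index=pd.Index(["x"])),
        )
        # single protein in a middle cluster of a 3-cluster solution would
        # be unlabelled; with max cluster 2 it is the increasing end
        assert res.table.loc["x", "de"]

    def test_missing_cluster_label_rejected(self):
        p, fc, clusters = self._inputs()
        with pytest.raises(ValueError, match="cluster"):
            call_de(p, fc, clusters.drop("a"))

    def test_recall_on_planted_effects(self):
        """DE recall >= 0.9 for non-flat proteins over 10 small studies."""
        hits, total = 0, 0
        for seed in range(10):
            cfg = synthetic.SimulationConfig(
                n_proteins=300, frac_ddp=0.2, frac_dip=0.2,
                frac_stage_specific=0.0, dropout_midpoint=-100.0, seed=seed,
            )
            table, truth = synthetic.simulate_quant_table(cfg)
            from psdremodel.quant import compute_stage_summary

            p = anova_per_protein(table)
            q = pd.Series(bh_adjust(p.to_numpy()), index=p.index)
            fc = max_fold_change(compute_stage_summary(table).mean)
            de = (q < 0.05) & (fc > 1.5)
            planted = truth.classes.isin(["decreasing", "increasing"])
            hits += (de & planted).sum()
            total += planted.sum()
        assert hits / total >= 0.9


class TestLateDE:
    def test_boundary_ratio_is_neither(self):
        table = make_table(
            {"p1": [10, 10, 5, 5, 5, 5, 20, 20]},
            stages=("0M", "2M", "6M", "24M"), reps=2,
        )
        out = late_de(table, "2M", "24M", fold=2.0)
        assert out.loc["p1", "ratio"] == 4.0
        table2 = make_table(
            {"p1": [10, 10, 5, 5, 5, 5, 10, 10]},
            stages=("0M", "2M", "6M", "24M"), reps=2,
        )
        assert late_de(table2, "2M", "24M").loc["p1", "late_group"] == ""

    def test_two_and_half_fold_decrease_is_late_ddp(self):
        table = make_table(
            {"p1": [10, 10, 10, 10, 6, 6, 4, 4]},
            stages=("0M", "2M", "6M", "24M"), reps=2,
        )
        assert late_de(table, "2M", "24M").loc["p1", "late_group"] == "Late DDP"

    def test_missing_stage_rejected(self):
        table = make_table({"p1": [1, 2, 3, 4]}, stages=("0M", "2M"), reps=2)
        with pytest.raises(ValueError, match="24M"):
            late_de(table, "2M", "24M")
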