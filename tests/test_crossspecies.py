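"""Time-course handling, homolog mapping, the concordance cascade,
perinatal ratios and dataset comparisons."""

import numpy as np
import pandas as pd
import pytest

from psdremodel import synthetic
from psdremodel.crossspecies import (
    ExpressionTimeCourse,
    HomologMap,
    asd_comparison,
    assign_concordant_groups,
    assign_primate_groups,
    change_correlation,
    dataset_overlap,
    perinatal_ratio,
    proteome_similarity,
    read_timecourse,
    write_timecourse,
)


def make_course(values: dict, ages, birth_index=None, species="mouse"):
    frame = pd.DataFrame(
        values, index=[f"t{i}" for i in range(len(ages))]
    ).T
    return ExpressionTimeCourse(
        values=frame, ages=np.asarray(ages, float), birth_index=birth_index,
        species=species, name="test",
    )


class TestTimeCourse:
    def test_unordered_ages_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            make_course({"g1": [1, 2, 3]}, ages=[1.0, 3.0, 2.0])

    def test_bad_birth_index_rejected(self):
        with pytest.raises(ValueError, match="birth"):
            make_course({"g1": [1, 2]}, ages=[-1.0, 1.0], birth_index=2)

    def test_zero_genes_dropped_before_ratios(self):
        course = make_course(
            {"g1": [1, 0, 2], "g2": [1, 2, 4]}, ages=[0.0, 1.0, 2.0]
        )
        ratio = course.log_ratio(0, -1)
        assert list(ratio.index) == ["g2"]
        assert ratio["g2"] == pytest.approx(2.0)

    def test_round_trip(self, tmp_path, small_study):
        course = next(c for c in small_study["courses"] if c.species == "human")
        write_timecourse(course, tmp_path / "c.tsv", tmp_path / "c.meta.tsv")
        back = read_timecourse(tmp_path / "c.tsv", tmp_path / "c.meta.tsv")
        assert back.species == "human"
        assert back.birth_index == course.birth_index
        np.testing.assert_allclose(back.ages, course.ages)
        np.testing.assert_allclose(
            back.values.to_numpy(), course.values.to_numpy(), rtol=1e-4
        )


class TestHomologMap:
    def test_duplicate_source_resolved_deterministically(self):
        mapping = pd.Series(
            ["B2", "B1"], index=pd.Index(["a", "a"], name="source")
        )
        hm = HomologMap(mapping)
        assert hm.mapping["a"] == "B1"  # lexicographically smallest target

    def test_case_insensitive_fallback_and_unmapped_count(self):
        hm = HomologMap(pd.Series(["T1"], index=pd.Index(["Gene1"])))
        with pytest.warns(UserWarning, match="could not be mapped"):
            out = hm.map_genes(["GENE1", "nope"])
        assert out["GENE1"] == "T1"
        assert hm.unmapped == ["nope"]


class TestChangeCorrelation:
    def test_perfect_concordance(self):
        course = make_course(
            {f"g{i}": [1.0, 2.0 ** (i + 1)] for i in range(5)}, ages=[0, 1]
        )
        changes = pd.Series(
            np.arange(1.0, 6.0), index=[f"g{i}" for i in range(5)]
        )
        rho, n, dropped = change_correlation(changes, course, 0)
        assert rho == pytest.approx(1.0) and n == 5 and dropped == 0

    def test_reversed_ranks(self):
        course = make_course(
            {f"g{i}": [1.0, 2.0 ** (i + 1)] for i in range(5)}, ages=[0, 1]
        )
        changes = pd.Series(
            -np.arange(1.0, 6.0), index=[f"g{i}" for i in range(5)]
        )
        assert change_correlation(changes, course, 0)[0] == pytest.approx(-1.0)

    def test_earliest_timepoint_beats_latest_on_lead_lag_data(self, small_study):
        """With an mRNA step that leads the protein change, the mRNA
        ratio from the earliest timepoint captures the full change and
        correlates better than from a post-step timepoint."""
        truth = small_study["truth"]
        course = small_study["courses"][0]
        gene_class = pd.Series(
            truth.classes.to_numpy(), index=truth.gene_of.to_numpy()
        )
        sign = gene_class.map(
            {"decreasing": -1.0, "increasing": 1.0}
        ).fillna(0.0)
        protein_change = sign * small_study["config"].effect_log2fc
        rho_first, _, _ = change_correlation(protein_change, course, 0)
        rho_late, _, _ = change_correlation(
            protein_change, course, len(course.ages) - 2
        )
        assert rho_first > rho_late

    def test_too_few_shared_genes_rejected(self):
        course = make_course({"g1": [1, 2]}, ages=[0, 1])
        with pytest.raises(ValueError, match="3"):
            change_correlation(pd.Series({"g1": 1.0}), course, 0)


class TestConcordance:
    def test_discordant_gene_excluded(self):
        up = make_course({"g1": [1, 2], "g2": [1, 2]}, ages=[0, 1])
        down = make_course({"g1": [2, 1], "g2": [1, 2]}, ages=[0, 1])
        ddp_m, dip_m, _ = assign_concordant_groups([], ["g1", "g2"], [up, down])
        assert list(dip_m) == ["g2"]

    def test_zero_noise_planted_de_fully_concordant(self):
        cfg = synthetic.SimulationConfig(
            n_proteins=100, noise_cv_percent=0.0, seed=3
        )
        _, truth = synthetic.simulate_quant_table(cfg)
        courses = synthetic.simulate_transcriptomes(cfg, truth)
        mouse = [c for c in courses if c.species == "mouse"]
        ddp = truth.gene_of[truth.classes == "decreasing"]
        dip = truth.gene_of[truth.classes == "increasing"]
        ddp_m, dip_m, n_excl = assign_concordant_groups(ddp, dip, mouse)
        assert set(ddp_m) == set(ddp) and set(dip_m) == set(dip)
        assert n_excl == 0

    def test_missing_gene_counted_as_excluded(self):
        up = make_course({"g1": [1, 2]}, ages=[0, 1])
        _, dip_m, n_excl = assign_concordant_groups([], ["g1", "gX"], [up])
        assert list(dip_m) == ["g1"] and n_excl == 1


class TestPerinatalRatio:
    def test_doubling_across_birth(self):
        course = make_course(
            {"g1": [10, 10, 20, 20]}, ages=[-1.0, -0.5, 0.5, 1.0], birth_index=2
        )
        assert perinatal_ratio(course)["g1"] == pytest.approx(2.0)

    def test_constant_gene_at_boundary(self):
        course = make_course(
            {"g1": [7, 7, 7]}, ages=[-1.0, 0.5, 1.0], birth_index=1
        )
        assert perinatal_ratio(course)["g1"] == pytest.approx(1.0)

    def test_rescaling_invariance(self):
        a = make_course(
            {"g1": [10, 30, 20]}, ages=[-1.0, 0.5, 1.0], birth_index=1
        )
        b = make_course(
            {"g1": [1, 3, 2]}, ages=[-1.0, 0.5, 1.0], birth_index=1
        )
        assert perinatal_ratio(a)["g1"] == pytest.approx(perinatal_ratio(b)["g1"])

    def test_missing_birth_marker_rejected(self):
        course = make_course({"g1": [1, 2]}, ages=[0, 1])
        with pytest.raises(ValueError, match="birth"):
            perinatal_ratio(course)


class TestPrimateGroups:
    def test_zero_noise_recovery(self):
        cfg = synthetic.SimulationConfig(
            n_proteins=100, noise_cv_percent=0.0, seed=5
        )
        _, truth = synthetic.simulate_quant_table(cfg)
        courses = synthetic.simulate_transcriptomes(cfg, truth)
        human = next(c for c in courses if c.species == "human")
        macaque = next(c for c in courses if c.species == "macaque")
        ddp = truth.gene_of[truth.classes == "decreasing"]
        dip = truth.gene_of[truth.classes == "increasing"]
        out = assign_primate_groups(ddp, dip, human, macaque)
        assert set(out["ddp_mh"]) == set(ddp)
        assert set(out["dip_mm"]) == set(dip)

    def test_ratio_exactly_one_excluded(self):
        human = make_course(
            {"g1": [5, 5, 5]}, ages=[-1.0, 0.5, 1.0], birth_index=1
        )
        out = assign_primate_groups(["g1"], ["g1"], human)
        assert len(out["ddp_mh"]) == 0 and len(out["dip_mh"]) == 0


class TestDatasetComparisons:
    def test_self_similarity_diagonal_one(self):
        frame = pd.DataFrame(
            np.random.default_rng(0).lognormal(size=(30, 3)),
            index=[f"g{i}" for i in range(30)], columns=["a", "b", "c"],
        )
        sim = proteome_similarity(frame, frame, "pearson_lfq")
        assert np.allclose(np.diag(sim.to_numpy(dtype=float)), 1.0)

    def test_anticorrelated_changes_negative(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        a = pd.DataFrame({"ch": x}, index=[f"g{i}" for i in range(40)])
        b = pd.DataFrame({"ch": -x}, index=[f"g{i}" for i in range(40)])
        sim = proteome_similarity(a, b, "spearman_changes")
        assert sim.iloc[0, 0] < 0

    def test_too_few_shared_genes(self):
        a = pd.DataFrame({"x": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="shared"):
            proteome_similarity(a, a, "pearson_lfq")

    def test_overlap_counts_and_fractions(self):
        out = dataset_overlap({"A", "B", "C"}, {"B", "C", "D"})
        assert out["n_shared"] == 2
        assert out["frac_a"] == pytest.approx(2 / 3)
        assert dataset_overlap({"A"}, {"B"})["n_shared"] == 0


class TestASDComparison:
    def _dev(self, genes):
        return pd.Series(np.linspace(-1, 1, len(genes)), index=genes)

    def test_all_down_group_has_full_down_fraction(self):
        genes = [f"g{i}" for i in range(20)]
        asd = pd.DataFrame(
            {"gene": genes, "log2fc_asd": -1.0, "p_value": 0.01}
        )
        out = asd_comparison(
            {"grp": set(genes[:5])}, genes, self._dev(genes), asd
        )
        assert out["groups"]["grp"]["frac_down"] == 1.0

    def test_planted_risk_list_fully_recovered(self):
        genes = [f"g{i}" for i in range(30)]
        risk = set(genes[:18])
        asd = pd.DataFrame(
            {"gene": genes, "log2fc_asd": 1.0, "p_value": 0.5}
        )
        out = asd_comparison(
            {"a": set(genes[:10]), "b": set(genes[10:20])},
            genes, self._dev(genes), asd, risk_genes=risk,
        )
        assert out["risk_overlap_total"] == 18

    def test_missing_column_rejected(self):
        asd = pd.DataFrame({"gene": ["g1"], "log2fc_asd": [1.0]})
        with pytest.raises(ValueError, match="p_value"):
            asd_comparison({}, ["g1"], pd.Series({"g1": 0.0}), asd)
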