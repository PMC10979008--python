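"""Parsing, QC criteria, gene collapse and stage-specific detection."""

import numpy as np
import pandas as pd
import pytest

from psdremodel import quant, synthetic
from psdremodel.quant import (
    QuantTable,
    compute_stage_summary,
    filter_major_proteins,
    read_quant_table,
    stage_specific_proteins,
    write_quant_table,
)


def make_table(rows, stages=("2w", "3w", "6w", "12w"), reps=2, peptides=None):
    """Build a small QuantTable from {protein: [per-sample intensities]}."""
    names = [f"{s}_rep{r}" for s in stages for r in range(1, reps + 1)]
    data = pd.DataFrame(
        {
            "protein_id": list(rows),
            "gene_symbol": [f"g_{p}" for p in rows],
            "unique_peptides": peptides or [5] * len(rows),
        }
    )
    data = pd.concat(
        [data, pd.DataFrame([rows[p] for p in rows], columns=names)], axis=1
    )
    samples = pd.DataFrame(
        {
            "stage": [s for s in stages for _ in range(reps)],
            "age": [i * 10.0 for i, s in enumerate(stages) for _ in range(reps)],
            "replicate": [r for s in stages for r in range(1, reps + 1)],
        },
        index=pd.Index(names, name="sample"),
    )
    return QuantTable(data, samples)


class TestReadValidate:
    def test_round_trip(self, tmp_path, small_study):
        table = small_study["table"]
        write_quant_table(table, tmp_path / "q.tsv", tmp_path / "m.tsv")
        back = read_quant_table(tmp_path / "q.tsv", tmp_path / "m.tsv")
        assert back.n_proteins == table.n_proteins
        assert back.stage_order == table.stage_order
        assert len(back.sample_names) == 16

    def test_unmapped_sample_column_error_names_it(self, tmp_path, small_study):
        table = small_study["table"]
        write_quant_table(table, tmp_path / "q.tsv", tmp_path / "m.tsv")
        meta = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        meta[meta["sample"] != "6w_rep2"].to_csv(
            tmp_path / "m2.tsv", sep="\t", index=False
        )
        with pytest.raises(ValueError, match="6w_rep2"):
            read_quant_table(tmp_path / "q.tsv", tmp_path / "m2.tsv")

    def test_missing_required_column(self):
        data = pd.DataFrame({"protein_id": ["p"], "2w_rep1": [1.0]})
        samples = pd.DataFrame(
            {"stage": ["2w"], "age": [14.0], "replicate": [1]},
            index=pd.Index(["2w_rep1"], name="sample"),
        )
        with pytest.raises(ValueError, match="gene_symbol"):
            QuantTable(data, samples)

    def test_duplicate_sample_names_rejected(self):
        data = pd.DataFrame(
            {"protein_id": ["p"], "gene_symbol": ["g"], "unique_peptides": [3],
             "2w_rep1": [1.0]}
        )
        samples = pd.DataFrame(
            {"stage": ["2w", "2w"], "age": [14.0, 14.0], "replicate": [1, 1]},
            index=pd.Index(["2w_rep1", "2w_rep1"], name="sample"),
        )
        with pytest.raises(ValueError, match="duplicate"):
            QuantTable(data, samples)

    def test_duplicate_protein_rows_accepted(self):
        table = make_table({"p1": [1, 2, 3, 4, 5, 6, 7, 8]})
        dup = QuantTable(
            pd.concat([table.data, table.data]).reset_index(drop=True),
            table.samples,
        )
        assert dup.n_proteins == 2
        filtered = filter_major_proteins(dup)
        assert filtered.n_proteins == 1  # collapsed per gene

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_table({"p1": [1, 2, 3, -4, 5, 6, 7, 8]})


class TestStageSummary:
    def test_direct_formula(self):
        table = make_table({"p1": [5, 10, 15, 1, 1, 1, 1, 1]},
                           stages=("a", "b"), reps=4)
        # stage "a" replicates {5,10,15,1}: check against numpy directly
        s = compute_stage_summary(table)
        vals = np.array([5.0, 10.0, 15.0, 1.0])
        assert s.mean.loc["p1", "a"] == pytest.approx(vals.mean())
        assert s.sd.loc["p1", "a"] == pytest.approx(vals.std(ddof=1))
        assert s.cv.loc["p1", "a"] == pytest.approx(
            100 * vals.std(ddof=1) / vals.mean()
        )

    def test_three_replicates_mean10_sd5_cv50(self):
        table = make_table({"p1": [5, 10, 15]}, stages=("a",), reps=3)
        s = compute_stage_summary(table)
        assert s.mean.loc["p1", "a"] == 10
        assert s.sd.loc["p1", "a"] == 5
        assert s.cv.loc["p1", "a"] == 50

    def test_constant_replicates_cv_zero(self):
        table = make_table({"p1": [10, 10, 10, 10]}, stages=("a",), reps=4)
        assert compute_stage_summary(table).cv.loc["p1", "a"] == 0

    def test_all_zero_stage_cv_undefined(self):
        table = make_table({"p1": [0, 0, 0, 0]}, stages=("a",), reps=4)
        s = compute_stage_summary(table)
        assert s.mean.loc["p1", "a"] == 0
        assert np.isnan(s.cv.loc["p1", "a"])
        assert s.detected.loc["p1", "a"] == 0


class TestMajorProteinFilter:
    def test_single_peptide_protein_removed(self):
        table = make_table(
            {"p1": [10] * 8, "p2": [10] * 8}, peptides=[1, 2]
        )
        kept = filter_major_proteins(table).data["protein_id"].tolist()
        assert kept == ["p2"]

    def test_missing_in_one_sample_removed(self):
        table = make_table({"p1": [10, 10, 10, 0, 10, 10, 10, 10],
                            "p2": [10] * 8})
        kept = filter_major_proteins(table).data["protein_id"].tolist()
        assert kept == ["p2"]

    def test_high_cv_removed(self):
        # stage a replicates {1, 1000}: CV = 141% > 100
        table = make_table({"p1": [1, 1000, 10, 10, 10, 10, 10, 10],
                            "p2": [10] * 8})
        kept = filter_major_proteins(table).data["protein_id"].tolist()
        assert kept == ["p2"]

    def test_gene_collapse_keeps_highest_total(self):
        table = make_table({"p1": [10] * 8, "p2": [12] * 8})
        table.data["gene_symbol"] = "shared"
        kept = filter_major_proteins(table).data["protein_id"].tolist()
        assert kept == ["p2"]

    def test_gene_collapse_tie_breaks_lexicographically(self):
        table = make_table({"pB": [10] * 8, "pA": [10] * 8})
        table.data["gene_symbol"] = "shared"
        kept = filter_major_proteins(table).data["protein_id"].tolist()
        assert kept == ["pA"]

    def test_idempotent(self, small_study):
        once = filter_major_proteins(small_study["table"])
        twice = filter_major_proteins(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_retained_proteins_satisfy_criteria_post_hoc(self, small_study):
        filtered = filter_major_proteins(small_study["table"])
        assert (filtered.data["unique_peptides"] >= 2).all()
        assert (filtered.intensities > 0).all().all()
        cv = compute_stage_summary(filtered).cv
        assert (cv < 100).all().all()
        assert not filtered.data["gene_symbol"].duplicated().any()

    def test_empty_result_warns_not_fails(self):
        table = make_table({"p1": [10] * 8}, peptides=[1])
        with pytest.warns(UserWarning, match="no proteins"):
            out = filter_major_proteins(table)
        assert out.n_proteins == 0


class TestStageSpecific:
    def test_full_early_none_late_is_young(self):
        table = make_table({"p1": [9, 9, 5, 5, 3, 0, 0, 0]})
        out = stage_specific_proteins(table)
        assert out.loc["p1", "stage_specific"]
        assert out.loc["p1", "group"] == "Young"

    def test_full_late_none_early_is_adult(self):
        table = make_table({"p1": [0, 0, 0, 3, 5, 5, 9, 9]})
        assert stage_specific_proteins(table).loc["p1", "group"] == "Adult"

    def test_partial_detection_everywhere_not_specific(self):
        table = make_table({"p1": [9, 0, 5, 0, 3, 0, 2, 0]})
        out = stage_specific_proteins(table)
        assert not out.loc["p1", "stage_specific"]

    def test_full_at_both_ends_counts_in_neither_group(self):
        table = make_table({"p1": [9, 9, 0, 0, 0, 0, 9, 9]})
        out = stage_specific_proteins(table)
        assert out.loc["p1", "stage_specific"]
        assert out.loc["p1", "group"] == ""

    def test_zero_noise_recall_is_complete(self):
        cfg = synthetic.SimulationConfig(
            n_proteins=200, frac_stage_specific=0.2, noise_cv_percent=0.0,
            dropout_midpoint=-100.0, seed=1,
        )
        table, truth = synthetic.simulate_quant_table(cfg)
        out = stage_specific_proteins(table)
        planted = truth.classes[truth.classes.str.endswith("specific")]
        found = out.loc[planted.index]
        assert found["stage_specific"].all()
        assert (found.loc[planted == "young-specific", "group"] == "Young").all()
        assert (found.loc[planted == "adult-specific", "group"] == "Adult").all()
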