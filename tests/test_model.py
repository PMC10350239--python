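"""Tests for pairing, filtering, the reliability scan and the model API."""

import numpy as np
import pandas as pd
import pytest

import dupicc
from dupicc.model import RELIABILITY_COLUMNS


class TestBuildPairMap:
    def test_three_clean_pairs(self, toy_beta_and_sheet):
        _, sheet = toy_beta_and_sheet
        pm = dupicc.build_pair_map(sheet)
        assert pm.n_subjects == 3
        assert pm.pairs["a"] == ("A1", "A2")
        assert pm.excluded == ()

    def test_cross_plate_requirement_drops_same_plate_subject(self, toy_beta_and_sheet):
        _, sheet = toy_beta_and_sheet
        sheet = sheet.copy()
        sheet.loc[sheet["sample_id"] == "B2", "plate"] = "P1"  # b now same-plate
        with pytest.warns(UserWarning, match="excluding subject 'b'"):
            pm = dupicc.build_pair_map(sheet, require_cross_plate=True)
        assert pm.n_subjects == 2
        assert pm.excluded[0][0] == "b"

    def test_subject_with_three_replicates_excluded(self, toy_beta_and_sheet):
        _, sheet = toy_beta_and_sheet
        extra = pd.DataFrame(
            [{"sample_id": "A3", "subject_id": "a", "replicate": 3, "plate": "P3"}]
        )
        sheet3 = pd.concat([sheet, extra], ignore_index=True)
        with pytest.warns(UserWarning, match="3 replicates"):
            pm = dupicc.build_pair_map(sheet3)
        assert "a" not in pm.pairs
        with pytest.raises(dupicc.DataError):
            dupicc.build_pair_map(sheet3, strict=True)

    def test_duplicate_sample_ids_error(self, toy_beta_and_sheet):
        _, sheet = toy_beta_and_sheet
        sheet = sheet.copy()
        sheet.loc[1, "sample_id"] = "A1"
        with pytest.raises(dupicc.DataError, match="duplicate sample IDs"):
            dupicc.build_pair_map(sheet)

    def test_cross_plate_needs_plate_column(self, toy_beta_and_sheet):
        _, sheet = toy_beta_and_sheet
        with pytest.raises(dupicc.DataError, match="plate"):
            dupicc.build_pair_map(sheet.drop(columns="plate"), require_cross_plate=True)


class TestMissingnessFilter:
    def test_no_missing_is_identity(self):
        bm = dupicc.BetaMatrix(pd.DataFrame(np.full((3, 4), 0.5),
                                            index=list("abc"), columns=list("wxyz")))
        out, removed = dupicc.filter_probes_by_missingness(bm)
        assert removed == 0
        assert out.probe_ids == ["a", "b", "c"]

    def test_probe_over_threshold_removed(self):
        data = pd.DataFrame(np.full((2, 10), 0.5), index=["keep", "drop"])
        data.iloc[1, 0] = np.nan  # 10% missing > 5%
        out, removed = dupicc.filter_probes_by_missingness(dupicc.BetaMatrix(data), 0.05)
        assert removed == 1
        assert out.probe_ids == ["keep"]

    def test_threshold_one_keeps_everything(self):
        data = pd.DataFrame(np.nan, index=["a"], columns=["x", "y"])
        out, removed = dupicc.filter_probes_by_missingness(dupicc.BetaMatrix(data), 1.0)
        assert removed == 0

    def test_boundary_is_inclusive(self):
        data = pd.DataFrame(np.full((1, 20), 0.5), index=["p"])
        data.iloc[0, 0] = np.nan  # exactly 5%
        _, removed = dupicc.filter_probes_by_missingness(dupicc.BetaMatrix(data), 0.05)
        assert removed == 0


class TestReliabilityScan:
    def test_duplicated_replicates_all_excellent(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        pm = dupicc.build_pair_map(sheet)
        r1, r2 = pm.replicate_columns()
        data = bm.data.copy()
        data[r2] = data[r1].to_numpy()  # make replicate 2 an exact copy
        table = dupicc.reliability_scan(dupicc.BetaMatrix(data.dropna()), pm, min_pairs=2)
        assert (table["icc"] == 1.0).all()
        assert (table["class_icc"] == "Excellent").all()
        assert (table["hola"] == 0.0).all()

    def test_column_contract_and_core_equivalence(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        pm = dupicc.build_pair_map(sheet)
        table = dupicc.reliability_scan(bm, pm, min_pairs=2)
        assert tuple(table.columns) == RELIABILITY_COLUMNS
        # per-probe rows equal calling the core chain directly
        row = table.set_index("probe_id").loc["cg01"]
        dup = dupicc.DuplicateSet(
            np.column_stack([bm.data.loc["cg01", ["A1", "B1", "C1"]],
                             bm.data.loc["cg01", ["A2", "B2", "C2"]]])
        )
        direct = dupicc.reliability_statistics(dup)
        for key in ("icc", "sigma_b2", "sigma_w2", "sd_diff", "hola", "micc"):
            assert row[key] == pytest.approx(direct[key], abs=1e-12)
        assert row["class_icc"] == direct["class_icc"]

    def test_incomplete_pairs_dropped_and_min_pairs(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        pm = dupicc.build_pair_map(sheet)
        table = dupicc.reliability_scan(bm, pm, min_pairs=3).set_index("probe_id")
        # cg04 has subject a incomplete -> only 2 pairs < min_pairs=3
        assert table.loc["cg04", "n_pairs"] == 2
        assert np.isnan(table.loc["cg04", "icc"])
        assert table.loc["cg04", "class_icc"] == "Undefined"
        # with min_pairs=2 it gets statistics from the 2 complete pairs
        t2 = dupicc.reliability_scan(bm, pm, min_pairs=2).set_index("probe_id")
        assert np.isfinite(t2.loc["cg04", "icc"])

    def test_all_missing_replicate_column_undefined(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        pm = dupicc.build_pair_map(sheet)
        data = bm.data.copy()
        data.loc["cg01", ["A2", "B2", "C2"]] = np.nan
        table = dupicc.reliability_scan(dupicc.BetaMatrix(data), pm).set_index("probe_id")
        assert table.loc["cg01", "n_pairs"] == 0
        assert table.loc["cg01", "class_icc"] == "Undefined"
        assert table.loc["cg01", "class_micc"] == "Undefined"

    def test_column_permutation_invariance(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        pm = dupicc.build_pair_map(sheet)
        base = dupicc.reliability_scan(bm, pm, min_pairs=2)
        shuffled = dupicc.BetaMatrix(bm.data[["C2", "A1", "B2", "A2", "C1", "B1"]])
        again = dupicc.reliability_scan(shuffled, pm, min_pairs=2)
        pd.testing.assert_frame_equal(base, again)

    def test_n_pairs_bounded_by_subjects(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        pm = dupicc.build_pair_map(sheet)
        table = dupicc.reliability_scan(bm, pm, min_pairs=2)
        assert (table["n_pairs"] <= pm.n_subjects).all()

    def test_zero_variance_probe_undefined(self):
        data = pd.DataFrame(
            {"A1": [0.5], "A2": [0.5], "B1": [0.5], "B2": [0.5], "C1": [0.5], "C2": [0.5]},
            index=["flat"],
        )
        sheet = pd.DataFrame(
            {
                "sample_id": ["A1", "A2", "B1", "B2", "C1", "C2"],
                "subject_id": ["a", "a", "b", "b", "c", "c"],
                "replicate": [1, 2, 1, 2, 1, 2],
            }
        )
        pm = dupicc.build_pair_map(sheet)
        table = dupicc.reliability_scan(dupicc.BetaMatrix(data), pm)
        assert table.loc[0, "class_icc"] == "Undefined"
        assert np.isnan(table.loc[0, "icc"])


class TestProbeMeanSd:
    def test_identical_replicates_seed_independent(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        pm = dupicc.build_pair_map(sheet)
        data = bm.data.copy().dropna()
        r1, r2 = pm.replicate_columns()
        data[r2] = data[r1].to_numpy()
        bm2 = dupicc.BetaMatrix(data)
        _, sd_a = dupicc.probe_mean_sd(bm2, pm, seed=1)
        _, sd_b = dupicc.probe_mean_sd(bm2, pm, seed=99)
        pd.testing.assert_series_equal(sd_a, sd_b)

    def test_hand_enumerated_selection(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        pm = dupicc.build_pair_map(sheet)
        seed = 7
        mean, sd = dupicc.probe_mean_sd(bm, pm, seed=seed)
        # mean over all six samples
        assert mean["cg01"] == pytest.approx(bm.data.loc["cg01"].mean())
        # reproduce the replicate selection by the same documented rule
        pick = np.random.default_rng(seed).integers(0, 2, size=3)
        r1, r2 = pm.replicate_columns()
        chosen = [b if p else a for a, b, p in zip(r1, r2, pick)]
        expected_sd = bm.data.loc["cg01", chosen].std(ddof=1)
        assert sd["cg01"] == pytest.approx(expected_sd)

    def test_mean_is_seed_independent(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        pm = dupicc.build_pair_map(sheet)
        mean_a, _ = dupicc.probe_mean_sd(bm, pm, seed=0)
        mean_b, _ = dupicc.probe_mean_sd(bm, pm, seed=123)
        pd.testing.assert_series_equal(mean_a, mean_b)

    def test_constant_probe(self):
        data = pd.DataFrame({"A1": [0.3], "A2": [0.3], "B1": [0.3], "B2": [0.3]}, index=["p"])
        sheet = pd.DataFrame(
            {"sample_id": ["A1", "A2", "B1", "B2"],
             "subject_id": ["a", "a", "b", "b"],
             "replicate": [1, 2, 1, 2]}
        )
        mean, sd = dupicc.probe_mean_sd(dupicc.BetaMatrix(data), dupicc.build_pair_map(sheet))
        assert mean["p"] == pytest.approx(0.3)
        assert sd["p"] == pytest.approx(0.0)


class TestModelResults:
    def test_fit_applies_filter_and_matches_scan(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        model = dupicc.ProbeReliabilityModel.from_frames(bm.data, sheet, min_pairs=2)
        res = model.fit()
        # cg04 is 1/6 missing (16.7% > 5%) -> filtered out
        assert res.n_probes_filtered == 1
        assert "cg04" not in set(res.table["probe_id"])
        direct = dupicc.reliability_scan(
            dupicc.filter_probes_by_missingness(bm, 0.05)[0],
            model.pairs, min_pairs=2,
        )
        pd.testing.assert_frame_equal(res.table, direct)

    def test_summary_and_class_counts(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        res = dupicc.ProbeReliabilityModel.from_frames(bm.data, sheet, min_pairs=2).fit()
        counts = res.class_counts("icc")
        assert counts.sum() == res.n_probes
        text = res.summary()
        assert "probes analysed" in text and "Excellent" in text

    def test_config_overrides(self, toy_beta_and_sheet):
        bm, sheet = toy_beta_and_sheet
        model = dupicc.ProbeReliabilityModel.from_frames(bm.data, sheet, z=2.58, seed=5)
        assert model.config.z == 2.58
        assert model.config.seed == 5
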