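"""Comparative-Ct scoring: parsing, ΔCt, calibrator pooling, RQ, median score."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ifnscore as ifs
from ifnscore.errors import FormatError, ParseError, ValidationError
from ifnscore.panel import GenePanel


class TestReadCtTable:
    def test_round_trip(self, ct_csv, small_ct_frame, panel):
        path = ct_csv(small_ct_frame.to_dict(orient="list"))
        ct = ifs.read_ct_table(path)
        assert list(ct.index) == ["s1", "s2"]
        for gene in panel.all_genes:
            assert gene in ct.columns
        np.testing.assert_allclose(
            ct["IFI27"].to_numpy(), small_ct_frame["IFI27"].to_numpy()
        )

    def test_missing_panel_gene_names_it(self, ct_csv, small_ct_frame):
        frame = small_ct_frame.drop(columns=["SIGLEC1"])
        with pytest.raises(FormatError, match="SIGLEC1"):
            ifs.read_ct_table(ct_csv(frame.to_dict(orient="list")))

    def test_undetermined_and_empty_are_missing(self, ct_csv, small_ct_frame):
        frame = small_ct_frame.astype(object)
        frame.loc[0, "IFI27"] = "Undetermined"
        frame.loc[1, "RSAD2"] = ""
        ct = ifs.read_ct_table(ct_csv(frame.to_dict(orient="list")))
        assert np.isnan(ct.loc["s1", "IFI27"])
        assert np.isnan(ct.loc["s2", "RSAD2"])

    def test_non_numeric_cell_locates_error(self, ct_csv, small_ct_frame):
        frame = small_ct_frame.astype(object)
        frame.loc[1, "ISG15"] = "oops"
        with pytest.raises(ParseError, match=r"s2.*ISG15"):
            ifs.read_ct_table(ct_csv(frame.to_dict(orient="list")))

    def test_out_of_range_ct_rejected(self, ct_csv, small_ct_frame):
        frame = small_ct_frame.astype(object)
        frame.loc[0, "HPRT1"] = 99.0
        with pytest.raises(ParseError, match="range"):
            ifs.read_ct_table(ct_csv(frame.to_dict(orient="list")))

    def test_duplicate_sample_ids_rejected(self, ct_csv, small_ct_frame):
        frame = small_ct_frame.copy()
        frame["sample_id"] = ["s1", "s1"]
        with pytest.raises(FormatError, match="duplicate"):
            ifs.read_ct_table(ct_csv(frame.to_dict(orient="list")))


class TestNormalizeCt:
    def test_delta_is_target_minus_housekeeper_mean(self, panel):
        ct = pd.DataFrame(
            {g: [25.0] for g in panel.targets} | {"HPRT1": [20.0], "G6PD": [22.0]},
            index=["s1"],
        )
        delta = ifs.normalize_ct(ct)
        assert delta.loc["s1", "IFI27"] == pytest.approx(4.0)

    def test_single_available_housekeeper_used_alone(self, panel, caplog):
        ct = pd.DataFrame(
            {g: [25.0] for g in panel.targets}
            | {"HPRT1": [21.0], "G6PD": [np.nan]},
            index=["s1"],
        )
        with caplog.at_level(logging.WARNING, logger="ifnscore.qpcr"):
            delta = ifs.normalize_ct(ct)
        assert delta.loc["s1", "IFI27"] == pytest.approx(4.0)
        assert "subset of housekeepers" in caplog.text

    def test_no_housekeeper_flags_sample(self, panel, caplog):
        ct = pd.DataFrame(
            {g: [25.0] for g in panel.targets}
            | {"HPRT1": [np.nan], "G6PD": [np.nan]},
            index=["s1"],
        )
        with caplog.at_level(logging.WARNING, logger="ifnscore.qpcr"):
            delta = ifs.normalize_ct(ct)
        assert delta.loc["s1"].isna().all()
        assert "no housekeeper" in caplog.text

    @given(shift=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_invariance(self, shift):
        """Adding a constant to every Ct of a sample leaves ΔCt unchanged."""
        panel = GenePanel()
        rng = np.random.default_rng(3)
        base = pd.DataFrame(
            rng.uniform(18, 30, (1, len(panel.all_genes))),
            index=["s1"], columns=panel.all_genes,
        )
        d0 = ifs.normalize_ct(base)
        d1 = ifs.normalize_ct(base + shift)
        np.testing.assert_allclose(d0.to_numpy(), d1.to_numpy(), atol=1e-10)


class TestVirtualCalibrator:
    def test_single_control_is_identity(self, panel):
        delta = pd.DataFrame(
            [[1.0, 2, 3, 4, 5, 6]], index=["c1"], columns=panel.targets
        )
        cal = ifs.make_virtual_calibrator(delta)
        np.testing.assert_allclose(cal.delta_ct.to_numpy(), delta.iloc[0].to_numpy())
        assert cal.n_controls_pooled == 1

    def test_mean_of_two_controls(self, panel):
        delta = pd.DataFrame(
            {g: [3.0, 5.0] for g in panel.targets}, index=["c1", "c2"]
        )
        cal = ifs.make_virtual_calibrator(delta)
        assert cal.delta_ct["IFI27"] == pytest.approx(4.0)

    def test_all_missing_target_names_gene(self, panel):
        delta = pd.DataFrame({g: [1.0, 2.0] for g in panel.targets}, index=["c1", "c2"])
        delta["RSAD2"] = np.nan
        with pytest.raises(ValidationError, match="RSAD2"):
            ifs.make_virtual_calibrator(delta)

    def test_pool_mean_matches_sampling_distribution(self, panel):
        # ΔCt ~ Normal(4, 0.5), 20 controls: pooled value within 3σ/√20 of 4
        rng = np.random.default_rng(42)
        delta = pd.DataFrame(
            rng.normal(4.0, 0.5, (20, len(panel.targets))), columns=panel.targets
        )
        cal = ifs.make_virtual_calibrator(delta)
        assert np.all(np.abs(cal.delta_ct.to_numpy() - 4.0) < 3 * 0.5 / np.sqrt(20))


class TestRelativeQuantification:
    @pytest.mark.parametrize(
        "sample_dct, cal_dct, expected",
        [(4.0, 4.0, 1.0), (3.0, 4.0, 2.0), (6.0, 4.0, 0.25)],
    )
    def test_two_power_minus_ddct(self, panel, sample_dct, cal_dct, expected):
        delta = pd.DataFrame({g: [sample_dct] for g in panel.targets}, index=["s1"])
        cal = ifs.CalibratorProfile(
            delta_ct=pd.Series(cal_dct, index=list(panel.targets))
        )
        rq = ifs.relative_quantification(delta, cal)
        assert rq.loc["s1", "IFIT1"] == pytest.approx(expected)

    def test_calibrator_identity_score_is_one(self, panel):
        """Scoring the calibrator's own profile gives rq = 1 and score = 1 exactly."""
        rng = np.random.default_rng(5)
        delta = pd.DataFrame(
            rng.uniform(1, 8, (4, len(panel.targets))), columns=panel.targets,
            index=[f"c{i}" for i in range(4)],
        )
        cal = ifs.make_virtual_calibrator(delta)
        self_profile = pd.DataFrame([cal.delta_ct], index=["cal"])
        rq = ifs.relative_quantification(self_profile, cal)
        assert (rq.to_numpy() == 1.0).all()
        assert ifs.ifn_score(rq).loc["cal", "score"] == 1.0

    def test_missing_delta_propagates(self, panel):
        delta = pd.DataFrame({g: [4.0] for g in panel.targets}, index=["s1"])
        delta.loc["s1", "IFI27"] = np.nan
        cal = ifs.CalibratorProfile(delta_ct=pd.Series(4.0, index=list(panel.targets)))
        rq = ifs.relative_quantification(delta, cal)
        assert np.isnan(rq.loc["s1", "IFI27"])
        assert rq.loc["s1", "ISG15"] == 1.0


class TestIfnScore:
    def test_unit_fold_changes_score_one(self, panel):
        fc = pd.DataFrame({g: [1.0] for g in panel.targets}, index=["s1"])
        assert ifs.ifn_score(fc).loc["s1", "score"] == 1.0

    def test_even_count_median(self, panel):
        fc = pd.DataFrame(
            [[0.5, 1, 2, 4, 8, 16]], index=["s1"], columns=panel.targets
        )
        assert ifs.ifn_score(fc).loc["s1", "score"] == pytest.approx(3.0)

    def test_below_min_genes_reported_missing_with_reason(self, panel):
        fc = pd.DataFrame(
            [[2.0, 3.0, 4.0, np.nan, np.nan, np.nan]],
            index=["s1"], columns=panel.targets,
        )
        out = ifs.ifn_score(fc)
        assert np.isnan(out.loc["s1", "score"])
        assert out.loc["s1", "n_genes_used"] == 3
        assert "fewer than 4" in out.loc["s1", "reason"]

    def test_median_matches_brute_force_all_missingness_patterns(self, panel):
        """Sort-based median oracle over every missingness pattern of 6 genes."""
        rng = np.random.default_rng(9)
        values = rng.lognormal(0, 1, 6)
        loose = GenePanel(min_genes_for_score=1)
        for mask in itertools.product([True, False], repeat=6):
            present = [v if keep else np.nan for v, keep in zip(values, mask)]
            fc = pd.DataFrame([present], index=["s1"], columns=panel.targets)
            got = ifs.ifn_score(fc, loose).loc["s1", "score"]
            kept = sorted(v for v in present if not np.isnan(v))
            if not kept:
                assert np.isnan(got)
                continue
            k = len(kept)
            expected = (
                kept[k // 2] if k % 2 else (kept[k // 2 - 1] + kept[k // 2]) / 2
            )
            assert got == pytest.approx(expected)

    def test_score_invariant_under_gene_permutation(self, panel):
        rng = np.random.default_rng(13)
        values = rng.lognormal(0, 1, 6)
        ref = None
        for perm in itertools.permutations(range(6)):
            fc = pd.DataFrame(
                [values[list(perm)]], index=["s1"], columns=panel.targets
            )
            score = ifs.ifn_score(fc).loc["s1", "score"]
            ref = score if ref is None else ref
            assert score == ref

    def test_nonpositive_fold_change_rejected(self, panel):
        fc = pd.DataFrame([[1, 1, 1, 1, 1, -2.0]], columns=panel.targets)
        with pytest.raises(ValidationError, match="positive"):
            ifs.ifn_score(fc)


class TestPipelineProperties:
    def test_more_expression_never_decreases_score(self, panel):
        """Lowering one target's Ct (more template) raises its rq and never
        lowers the sample's median score."""
        rng = np.random.default_rng(21)
        ct = pd.DataFrame(
            rng.uniform(20, 30, (3, len(panel.all_genes))),
            columns=panel.all_genes, index=["c1", "c2", "s"],
        )
        scores0, rq0 = ifs.score_ct_table(ct, ["c1", "c2"])
        bumped = ct.copy()
        bumped.loc["s", "IFI44L"] -= 2.0
        scores1, rq1 = ifs.score_ct_table(bumped, ["c1", "c2"])
        assert rq1.loc["s", "IFI44L"] > rq0.loc["s", "IFI44L"]
        assert scores1.loc["s", "score"] >= scores0.loc["s", "score"]

    def test_full_pipeline_shift_invariance(self, panel):
        rng = np.random.default_rng(23)
        ct = pd.DataFrame(
            rng.uniform(20, 30, (4, len(panel.all_genes))),
            columns=panel.all_genes, index=["c1", "c2", "c3", "s"],
        )
        shifted = ct.copy()
        shifted.loc["s"] += 3.7
        s0, _ = ifs.score_ct_table(ct, ["c1", "c2", "c3"])
        s1, _ = ifs.score_ct_table(shifted, ["c1", "c2", "c3"])
        assert s1.loc["s", "score"] == pytest.approx(s0.loc["s", "score"], rel=1e-12)

    def test_lod_substitution_fills_undetermined_targets(self, panel):
        rng = np.random.default_rng(29)
        ct = pd.DataFrame(
            rng.uniform(20, 28, (3, len(panel.all_genes))),
            columns=panel.all_genes, index=["c1", "c2", "s"],
        )
        ct.loc["s", "IFI27"] = np.nan
        default_scores, default_rq = ifs.score_ct_table(ct, ["c1", "c2"])
        assert np.isnan(default_rq.loc["s", "IFI27"])  # excluded, not imputed
        lod_scores, lod_rq = ifs.score_ct_table(ct, ["c1", "c2"], lod_ct=40.0)
        assert np.isfinite(lod_rq.loc["s", "IFI27"])
        assert lod_scores.loc["s", "n_genes_used"] == len(panel.targets)
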