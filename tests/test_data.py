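import math

import numpy as np
import pandas as pd
import pytest

from varmeta.data import (
    GroupSummary, REGION_SYNONYMS, REGIONS, adjust_control_n, assign_region,
    read_study_table, records_to_frame, rescale_metabolite, write_study_table,
)


class TestAssignRegion:
    @pytest.mark.parametrize("label,region", [
        ("anterior cingulate cortex", "MFC"),
        ("hippocampus", "temporal_lobe"),
        ("caudate", "basal_ganglia"),
        ("Medial Prefrontal Cortex", "MFC"),
        ("DLPFC", "DLPFC"),
        ("frontal_white_matter", "frontal_white_matter"),
    ])
    def test_synonyms(self, label, region):
        assert assign_region(label) == region

    def test_total_on_table(self):
        for label, region in REGION_SYNONYMS.items():
            assert assign_region(label) == region in REGIONS

    def test_unknown_label_raises_listing_table(self):
        with pytest.raises(KeyError) as exc:
            assign_region("cerebellum")
        assert "caudate" in str(exc.value)  # table listed, no default bucket

    def test_empty_label(self):
        with pytest.raises(ValueError):
            assign_region("  ")


class TestAdjustControlN:
    @pytest.mark.parametrize("n,g,expected", [(30, 2, 15.0), (30, 1, 30.0)])
    def test_division(self, n, g, expected):
        assert adjust_control_n(n, g) == expected

    def test_below_two_returned_for_flagging(self):
        assert adjust_control_n(3, 2) == 1.5  # caller flags unusable

    def test_rounded_mode_half_down_with_floor(self):
        assert adjust_control_n(31, 2, mode="rounded") == 15.0  # 15.5 -> 15
        assert adjust_control_n(5, 2, mode="rounded") == 2.0    # floor at 2

    def test_invalid(self):
        with pytest.raises(ValueError):
            adjust_control_n(0, 1)


class TestRescale:
    def test_multiplication(self):
        m, s = rescale_metabolite(0.00123, 0.00031, 1e3, "j_edited")
        assert m == pytest.approx(1.23) and s == pytest.approx(0.31)

    def test_standard_acquisition_rejected(self):
        with pytest.raises(ValueError):
            rescale_metabolite(1.0, 0.1, 1e3, "standard")

    def test_factor_class_enforced(self):
        with pytest.raises(ValueError):
            rescale_metabolite(1.0, 0.1, 10.0, "epsi")

    @pytest.mark.parametrize("factor", [1e3, 1e5])
    def test_effect_sizes_scale_invariant(self, factor):
        from varmeta.effects import hedges_g, ln_cvr
        p0, c0 = GroupSummary(0.0021, 0.0004, 18), GroupSummary(0.0019, 0.0003, 21)
        mp, sp = rescale_metabolite(p0.mean, p0.sd, factor, "epsi")
        mc, sc = rescale_metabolite(c0.mean, c0.sd, factor, "epsi")
        p1, c1 = GroupSummary(mp, sp, 18), GroupSummary(mc, sc, 21)
        assert ln_cvr(p1, c1).estimate == pytest.approx(ln_cvr(p0, c0).estimate, abs=1e-12)
        assert hedges_g(p1, c1).estimate == pytest.approx(hedges_g(p0, c0).estimate, abs=1e-12)


class TestReadStudyTable:
    def test_well_formed_pass_through(self, small_table):
        path, _ = small_table
        res = read_study_table(path)
        assert len(res.records) == 3 and len(res.rejects) == 0
        assert res.records[0].region == "MFC"
        assert res.records[0].moderators["mean_age"] == 31.5

    def test_zero_sd_rejected(self, small_table, tmp_path):
        path, df = small_table
        df.loc[1, "sd_patients"] = 0.0
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        res = read_study_table(p)
        assert len(res.records) == 2
        assert "non-positive SD" in res.rejects["reason"].iloc[0]

    def test_nc_one_rejected(self, small_table, tmp_path):
        path, df = small_table
        df.loc[0, "n_controls"] = 1
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        res = read_study_table(p)
        assert len(res.records) == 2
        assert "n < 2" in " ".join(res.rejects["reason"])

    def test_missing_mandatory_column_hard_error(self, small_table, tmp_path):
        path, df = small_table
        p = tmp_path / "bad.csv"
        df.drop(columns=["sd_controls"]).to_csv(p, index=False)
        with pytest.raises(ValueError, match="sd_controls"):
            read_study_table(p)

    def test_non_numeric_rejected_with_reason(self, small_table, tmp_path):
        path, df = small_table
        df.loc[2, "mean_patients"] = "n/a"
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        res = read_study_table(p)
        assert len(res.records) == 2
        assert "non-numeric mean_patients" in " ".join(res.rejects["reason"])

    def test_first_timepoint_filter(self, tmp_path):
        df = pd.DataFrame({
            "study_id": ["x", "x"], "timepoint": [1, 2],
            "region": ["thalamus", "thalamus"], "metabolite": ["Glx", "Glx"],
            "n_patients": [10, 10], "mean_patients": [5, 5],
            "sd_patients": [1, 1], "n_controls": [10, 10],
            "mean_controls": [5, 5], "sd_controls": [1, 1]})
        p = tmp_path / "tp.csv"
        df.to_csv(p, index=False)
        res = read_study_table(p)
        assert len(res.records) == 1
        assert "not first timepoint" in res.rejects["reason"].iloc[0]

    def test_shared_control_adjustment(self, tmp_path):
        df = pd.DataFrame({
            "study_id": ["x", "x"], "cohort_id": ["fep", "chronic"],
            "region": ["MFC", "MFC"], "metabolite": ["glutamate"] * 2,
            "n_patients": [12, 14], "mean_patients": [5, 5.2],
            "sd_patients": [1, 1.1], "n_controls": [30, 30],
            "mean_controls": [5, 5], "sd_controls": [1, 1],
            "n_clinical_groups": [2, 2]})
        p = tmp_path / "shared.csv"
        df.to_csv(p, index=False)
        res = read_study_table(p)
        assert [r.control.n for r in res.records] == [15.0, 15.0]
        res_r = read_study_table(p, control_n_mode="rounded")
        assert [r.control.n for r in res_r.records] == [15.0, 15.0]

    def test_round_trip(self, small_table, tmp_path):
        path, _ = small_table
        recs = read_study_table(path).records
        out = tmp_path / "roundtrip.tsv"
        write_study_table(recs, out)
        back = read_study_table(out).records
        for a, b in zip(recs, back):
            assert a.study_id == b.study_id and a.region == b.region
            for arm in ("patient", "control"):
                ga, gb = getattr(a, arm), getattr(b, arm)
                assert gb.mean == pytest.approx(ga.mean, rel=1e-9)
                assert gb.sd == pytest.approx(ga.sd, rel=1e-9)
                assert gb.n == pytest.approx(ga.n, rel=1e-9)
            assert records_to_frame([a]).equals(records_to_frame([b]))


class TestGroupSummary:
    @pytest.mark.parametrize("kw", [
        dict(mean=10, sd=1, n=1.5), dict(mean=10, sd=0, n=10),
        dict(mean=-1, sd=1, n=10), dict(mean=10, sd=-0.5, n=10)])
    def test_invariants(self, kw):
        with pytest.raises(ValueError):
            GroupSummary(**kw)

    def test_fractional_n_allowed(self):
        assert GroupSummary(10, 1, 7.5).n == 7.5
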