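import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isopull.errors import ConfigError, TuningError
from isopull.filter_engine import (
    FilterAudit,
    FilterParams,
    apply_control_fc_filter,
    apply_ion_filters,
    apply_protein_filters,
    protein_filter_table,
    tune_filters,
)
from isopull.pipeline import merge_sample_sheet
from isopull.ratio_quant import normalize_runs
from isopull.report_io import ProteinDB, ProteinRecord


def _ion_frame(rows):
    """rows: (protein, peptide, sample_type, replicate, ratio_lh_norm, q, cv_norm)."""
    return pd.DataFrame(
        rows,
        columns=["protein_id", "peptide_seq", "sample_type", "replicate",
                 "ratio_lh_norm", "q_value", "cv_norm"],
    ).assign(condition="control", fa_level="fa_0.2")


class TestFilterParams:
    def test_defaults_match_the_standard_initial_values(self):
        p = FilterParams()
        assert (p.control_fc, p.q_value_max, p.ion_cv_max) == (2.0, 0.01, 0.2)
        assert (p.data_completeness, p.seq_coverage_min, p.num_peptides_min) == (1.0, 40.0, 2)

    @pytest.mark.parametrize("kwargs", [
        {"control_fc": 0.5}, {"q_value_max": 0.0}, {"q_value_max": 2.0},
        {"ion_cv_max": -1}, {"data_completeness": 0.0}, {"num_peptides_min": 0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            FilterParams(**kwargs)


class TestIonFilters:
    def test_pass_and_fail_cases(self):
        df = _ion_frame([
            ("P1", "AAAAA", "BAIT_WT", 1, 1.0, 0.005, 0.10),  # passes
            ("P1", "CCCCC", "BAIT_WT", 1, 1.0, 0.020, 0.10),  # fails q
            ("P1", "DDDDD", "BAIT_WT", 1, 1.0, 0.005, 0.25),  # fails cv
            ("P1", "EEEEE", "BAIT_WT", 1, 1.0, 0.005, np.nan),  # undefined cv fails
        ])
        out, audit = apply_ion_filters(df, FilterParams())
        assert list(out["ion_pass"]) == [True, False, False, False]
        frame = audit.frame()
        assert list(frame["surviving"]) == [3, 1]  # non-increasing ledger

    def test_audit_counts_on_ten_ion_fixture(self):
        # ten ions, three with cv above the threshold -> seven survive
        rows = [(f"P{i}", f"PEP{i:02d}", "BAIT_WT", 1, 1.0, 0.001,
                 0.3 if i < 3 else 0.1) for i in range(10)]
        out, audit = apply_ion_filters(_ion_frame(rows), FilterParams())
        assert int(out["ion_pass"].sum()) == 7
        cv_entry = audit.frame().set_index("filter").loc["ion_cv"]
        assert cv_entry["failed"] == 3

    @given(
        q=st.floats(0.0, 0.05), cv=st.floats(0.0, 0.4),
        q_max=st.sampled_from([0.01, 0.05]), cv_max=st.sampled_from([0.2, 0.3]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_tightening_never_adds_survivors(self, q, cv, q_max, cv_max):
        df = _ion_frame([("P1", "AAAAA", "BAIT_WT", 1, 1.0, q, cv)])
        loose, _ = apply_ion_filters(df, FilterParams(q_value_max=q_max, ion_cv_max=cv_max))
        tight, _ = apply_ion_filters(
            df, FilterParams(q_value_max=q_max / 2, ion_cv_max=cv_max / 2)
        )
        assert tight["ion_pass"].sum() <= loose["ion_pass"].sum()


class TestControlFCFilter:
    def _frame(self, control_ratio, control_type="BAIT_BAIT"):
        return _ion_frame([
            ("P1", "AAAAA", control_type, 1, control_ratio, 0.001, 0.05),
            ("P1", "AAAAA", "BAIT_WT", 1, 8.0, 0.001, 0.05),
            ("P2", "CCCCC", "BAIT_WT", 1, 8.0, 0.001, 0.05),
        ]).pipe(lambda d: apply_ion_filters(d, FilterParams())[0])

    def test_well_behaved_control_kept(self):
        out, _ = apply_control_fc_filter(self._frame(1.0), 2.0)
        assert out["control_kept"].all()

    def test_deviant_control_excludes_the_peptide_globally(self):
        out, _ = apply_control_fc_filter(self._frame(2.5), 2.0)
        assert not out.loc[out["peptide_seq"] == "AAAAA", "control_kept"].any()
        assert out.loc[out["peptide_seq"] == "CCCCC", "control_kept"].all()

    def test_boundary_is_strict(self):
        out, _ = apply_control_fc_filter(self._frame(2.0), 2.0)
        assert out["control_kept"].all()

    def test_low_side_deviation_also_excludes(self):
        out, _ = apply_control_fc_filter(self._frame(0.3, "WT_WT"), 2.0)
        assert not out.loc[out["peptide_seq"] == "AAAAA", "control_kept"].any()


def _protein_rows(n_reps, n_peps, protein="P1", stype="BAIT_WT"):
    rows = []
    for r in range(1, n_reps + 1):
        for k in range(n_peps):
            rows.append((protein, f"PEPTIDE{k:02d}", stype, r, 1.0, 0.001, 0.05))
    return rows


class TestProteinFilters:
    def _db(self, protein="P1", n_peps=5, pep_len=9, tail=0):
        peps = [f"PEPTIDE{k:02d}" for k in range(n_peps)]
        seq = "".join(peps) + "W" * tail
        return ProteinDB({protein: ProteinRecord(protein, seq)})

    def _flag(self, df):
        df, _ = apply_ion_filters(df, FilterParams())
        df, _ = apply_control_fc_filter(df, 2.0)
        return df

    def test_full_evidence_survives_defaults(self):
        df = self._flag(_ion_frame(_protein_rows(4, 5)))
        surv, _ = apply_protein_filters(df, FilterParams(), self._db(), 4)
        assert list(surv["protein_id"]) == ["P1"]
        assert surv.loc[0, "seq_coverage"] == 100.0

    def test_missing_replicate_fails_completeness(self):
        df = self._flag(_ion_frame(_protein_rows(3, 5)))
        surv, audit = apply_protein_filters(df, FilterParams(), self._db(), 4)
        assert surv.empty
        assert audit.frame().set_index("filter").loc["data_completeness", "failed"] == 1

    def test_single_peptide_fails_num_peptides(self):
        df = self._flag(_ion_frame(_protein_rows(4, 1)))
        surv, _ = apply_protein_filters(df, FilterParams(), self._db(n_peps=1), 4)
        assert surv.empty

    def test_low_coverage_fails_and_boundary_is_strict(self):
        # 5 peptides x 9 residues = 45 covered; tail pads to exactly 45%
        db = self._db(tail=55)
        df = self._flag(_ion_frame(_protein_rows(4, 5)))
        surv, _ = apply_protein_filters(df, FilterParams(seq_coverage_min=45.0), db, 4)
        assert surv.empty  # 45 is not strictly greater than 45
        surv, _ = apply_protein_filters(df, FilterParams(seq_coverage_min=40.0), db, 4)
        assert list(surv["protein_id"]) == ["P1"]

    def test_unknown_accession_raises_config_error(self):
        df = self._flag(_ion_frame(_protein_rows(4, 5, protein="GHOST")))
        with pytest.raises(ConfigError, match="GHOST"):
            apply_protein_filters(df, FilterParams(), self._db("P1"), 4)

    def test_completeness_fraction_scales_with_design(self):
        df = self._flag(_ion_frame(_protein_rows(3, 5)))
        surv, _ = apply_protein_filters(
            df, FilterParams(data_completeness=0.75), self._db(), 4
        )
        assert list(surv["protein_id"]) == ["P1"]


class TestTuneFilters:
    def _normalized(self, tuning_data):
        report, sheet, db = tuning_data
        return normalize_runs(merge_sample_sheet(report, sheet)), db

    def test_bait_with_cv_028_cov_35_tunes_to_03_and_30(self, tuning_data):
        norm, db = self._normalized(tuning_data)
        tuned, trace = tune_filters(norm, "SIGA_TS", protein_db=db, n_replicates=4)
        assert tuned.ion_cv_max == 0.3
        assert tuned.seq_coverage_min == 30.0
        # the walk is exhaustive and ordered most-to-least stringent
        assert len(trace) == 9
        assert trace["bait_survives"].tolist() == [False] * 8 + [True]

    def test_bait_surviving_defaults_returns_them_unchanged(self):
        db = ProteinDB({
            "BAIT": ProteinRecord("BAIT", "".join(f"PEPTIDE{k:02d}" for k in range(5))),
            "BG": ProteinRecord("BG", "".join(f"BACKGND{k:02d}" for k in range(5))),
        })
        rows = _protein_rows(4, 5, "BAIT", "BAIT_WT") + [
            ("BG", f"BACKGND{k:02d}", "BAIT_WT", r, 1.0, 0.001, 0.02)
            for r in range(1, 5) for k in range(5)
        ]
        df = _ion_frame(rows)
        df["sample_id"] = df["sample_type"] + "_BR" + df["replicate"].astype(str)
        df["ratio_hl"] = 1.0 / df["ratio_lh_norm"]
        norm = normalize_runs(df.drop(columns=["ratio_lh_norm", "cv_norm"]))
        tuned, _ = tune_filters(norm, "BAIT", protein_db=db, n_replicates=4)
        assert (tuned.ion_cv_max, tuned.seq_coverage_min) == (0.2, 40.0)

    def test_coverage_only_failure_relaxes_only_coverage(self, tuning_data):
        report, sheet, db = tuning_data
        # damp the bait's Bait/WT spread so its ion CV is small (~0); only
        # the 35% coverage then blocks it
        bait = (report["protein_id"] == "SIGA_TS")
        in_exp = bait & report["sample_id"].str.startswith("BAIT_WT")
        report = report.copy()
        report.loc[in_exp, "ratio_hl"] = 1.0 / 50.0
        norm = normalize_runs(merge_sample_sheet(report, sheet))
        tuned, _ = tune_filters(norm, "SIGA_TS", protein_db=db, n_replicates=4)
        assert tuned.ion_cv_max == 0.2
        assert tuned.seq_coverage_min == 30.0

    def test_hopeless_bait_raises_with_trace(self, tuning_data):
        report, sheet, db = tuning_data
        report = report[report["protein_id"] != "SIGA_TS"]
        norm = normalize_runs(merge_sample_sheet(report, sheet))
        with pytest.raises(TuningError) as exc:
            tune_filters(norm, "SIGA_TS", protein_db=db, n_replicates=4)
        assert len(exc.value.trace) == 9


def test_filter_audit_survivors_non_increasing(decoy_result):
    frame = decoy_result.audit.frame()
    assert (frame["surviving"].diff().dropna() <= 0).all() or len(frame) <= 1
    assert (frame["surviving"] == frame["tested"] - frame["failed"]).all()
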