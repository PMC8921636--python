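"""Clonotype-table parsing, spike-in matching, and QC statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tcrdetect import (
    ClonotypeRecord,
    ModelParameterError,
    SpikeInReference,
    TableFormatError,
    dispersion_index,
    exclude_fully_undetected,
    false_positive_analysis,
    linearity_r2,
    match_spikeins,
    read_clonotype_table,
    trim_cdr3_to_imgt,
)


def write_tsv(path, rows, columns=("cloneCount", "cloneFraction", "nSeqCDR3")):
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path


class TestReadClonotypeTable:
    def test_well_formed_table(self, tmp_path):
        path = write_tsv(tmp_path / "t.tsv", [
            (10, 0.5, "TGTGCAAGCTTT"),
            (6, 0.3, "TGTAGCTGGAAA"),
            (4, 0.2, "TGTAAACCCGGG"),
        ])
        records = read_clonotype_table(path, chain="TRB", set_id="S1", replicate_id="1a")
        assert len(records) == 3
        assert records[0] == ClonotypeRecord("TGTGCAAGCTTT", "TRB", 10, 0.5, "S1", "1a")

    def test_missing_count_column_raises(self, tmp_path):
        path = write_tsv(tmp_path / "t.tsv", [(0.5, "TGTGCAAGCTTT")],
                         columns=("cloneFraction", "nSeqCDR3"))
        with pytest.raises(TableFormatError, match="cloneCount"):
            read_clonotype_table(path, chain="TRB")

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(TableFormatError):
            read_clonotype_table(path, chain="TRA")

    def test_dirty_row_skipped_with_warning(self, tmp_path, caplog):
        path = write_tsv(tmp_path / "t.tsv", [
            (10, 0.5, "TGTGCAAGCTTT"),
            (5, 0.25, "TGTGCNNGCTTT"),
            (5, 0.25, "TGTAAACCCGGG"),
        ])
        with caplog.at_level("WARNING"):
            records = read_clonotype_table(path, chain="TRA")
        assert len(records) == 2
        assert "non-ACGT" in caplog.text

    def test_alternate_column_names(self, tmp_path):
        path = write_tsv(tmp_path / "t.tsv", [(7, "TGTGCAAGCTTT")],
                         columns=("readCount", "nSeqImputedCDR3"))
        records = read_clonotype_table(path, chain="TRB")
        assert records[0].read_count == 7


class TestTrimCdr3:
    @pytest.mark.parametrize("cdr3, expected", [
        ("TGTGCAAGCTTT", "GCAAGC"),
        ("TGTAGCT", "A"),
    ])
    def test_definition(self, cdr3, expected):
        assert trim_cdr3_to_imgt(cdr3) == expected

    def test_too_short_rejected(self):
        with pytest.raises(ModelParameterError):
            trim_cdr3_to_imgt("TGTAGC")

    @settings(derandomize=True, max_examples=25)
    @given(st.text(alphabet="ACGT", min_size=7, max_size=60))
    def test_length_shrinks_by_six(self, cdr3):
        assert len(trim_cdr3_to_imgt(cdr3)) == len(cdr3) - 6


REF = [
    SpikeInReference("TCC001", "TRB", "GCAAGCAAA", 1e-3),
    SpikeInReference("TCC002", "TRB", "GCAAGCCCC", 1e-4),
]


class TestMatchSpikeins:
    def test_duplicate_library_merge(self):
        records = [
            ClonotypeRecord("GCAAGCAAA", "TRB", 40, set_id="S1", replicate_id="1a"),
            ClonotypeRecord("GCAAGCAAA", "TRB", 60, set_id="S1", replicate_id="1b"),
            ClonotypeRecord("GCAAGCCCC", "TRB", 100, set_id="S1", replicate_id="1a"),
        ]
        matched = match_spikeins(records, REF)
        row = matched[matched["clone_id"] == "TCC001"].iloc[0]
        assert row["read_count"] == 100
        assert row["replicate_id"] == "1"
        assert row["measured_freq"] == pytest.approx(0.5)

    def test_absent_reference_flagged_undetected(self):
        records = [ClonotypeRecord("GCAAGCAAA", "TRB", 10, set_id="S1", replicate_id="1")]
        matched = match_spikeins(records, REF)
        missing = matched[matched["clone_id"] == "TCC002"].iloc[0]
        assert missing["read_count"] == 0
        assert not missing["detected"]

    def test_trim_then_match_equals_pretrimmed(self):
        raw = [ClonotypeRecord("TGT" + "GCAAGCAAA" + "TTT", "TRB", 10,
                               set_id="S1", replicate_id="1")]
        pre = [ClonotypeRecord("GCAAGCAAA", "TRB", 10, set_id="S1", replicate_id="1")]
        a = match_spikeins(raw, REF, trim=True)
        b = match_spikeins(pre, REF, trim=False)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_reference_rejected(self):
        dup = REF + [SpikeInReference("TCC003", "TRB", "GCAAGCAAA", 1e-5)]
        with pytest.raises(ModelParameterError, match="ambiguous"):
            match_spikeins([], dup)

    def test_measured_frequencies_sum_to_at_most_one(self, study_experiment):
        recs = study_experiment.records("TRB", "1")
        matched = match_spikeins(recs, study_experiment.reference)
        assert matched["measured_freq"].sum() <= 1.0 + 1e-12

    def test_end_to_end_frequencies_track_truth(self, study_experiment):
        matched = match_spikeins(study_experiment.all_records(),
                                 study_experiment.reference)
        sub = matched[(matched["chain"] == "TRB") & matched["detected"]]
        r2 = linearity_r2(sub["design_freq"], sub["measured_freq"])
        assert r2 > 0.8


class TestExcludeFullyUndetected:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["clone_id", "chain", "set_id",
                                           "replicate_id", "read_count"])

    def test_single_detection_retains(self):
        matched = self.frame([
            ("C1", "TRA", "S1", "1", 0),
            ("C1", "TRA", "S2", "1", 3),
            ("C1", "TRB", "S1", "1", 5),
        ])
        retained, excluded = exclude_fully_undetected(matched)
        assert excluded == []
        assert len(retained) == 3

    def test_one_dead_chain_excludes_whole_tcr(self):
        matched = self.frame([
            ("C1", "TRA", "S1", "1", 0),
            ("C1", "TRA", "S2", "1", 0),
            ("C1", "TRB", "S1", "1", 50),
        ])
        retained, excluded = exclude_fully_undetected(matched, mode="either_chain")
        assert excluded == ["C1"]
        retained, excluded = exclude_fully_undetected(matched, mode="whole_tcr")
        assert excluded == []

    def test_never_removes_clone_with_any_read(self):
        matched = self.frame([
            ("C1", "TRA", "S1", "1", 1),
            ("C1", "TRB", "S1", "1", 1),
            ("C2", "TRA", "S1", "1", 0),
            ("C2", "TRB", "S1", "1", 0),
        ])
        _, excluded = exclude_fully_undetected(matched)
        assert excluded == ["C2"]

    def test_planted_dropouts_recovered(self, truth_params):
        from tcrdetect import SpikeInDesign, generate_spikein_experiment, match_spikeins

        # Lowest tier at 5e-5 (expected count 35): natural dropout is
        # impossible in practice, so only the planted clones are all-zero.
        tiers = [(f, 5) for f in (5e-5, 1e-3, 5e-2)]
        exp = generate_spikein_experiment(
            SpikeInDesign(tiers=tiers, seed=11, background_clones=0), truth_params,
            t_read=10**6, n_dropouts=2,
        )
        matched = match_spikeins(exp.all_records(), exp.reference)
        _, excluded = exclude_fully_undetected(matched)
        assert excluded == sorted(exp.dropout_clone_ids)


class TestDispersionIndex:
    def test_constant_series(self):
        assert dispersion_index([5, 5, 5, 5]) == 0.0

    def test_simple_value(self):
        assert dispersion_index([1, 2, 3]) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, k):
        vals = np.array([1.0, 2.0, 5.0, 3.0])
        assert dispersion_index(k * vals) == pytest.approx(dispersion_index(vals), rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ModelParameterError):
            dispersion_index([0, 0, 0])


class TestLinearityR2:
    def test_exact_agreement(self):
        truth = np.array([1e-5, 1e-4, 1e-3, 1e-2])
        assert linearity_r2(truth, truth) == pytest.approx(1.0)

    def test_constant_factor_absorbed(self):
        truth = np.array([1e-5, 1e-4, 1e-3, 1e-2])
        assert linearity_r2(truth, 2 * truth) == pytest.approx(1.0)

    def test_lognormal_noise_keeps_high_r2(self):
        rng = np.random.default_rng(3)
        truth = np.logspace(-6, -2, 40)
        measured = truth * 10 ** rng.normal(0.0, 0.15, truth.size)
        assert 0.9 < linearity_r2(truth, measured) < 1.0

    def test_too_few_detected_rejected(self):
        with pytest.raises(ModelParameterError):
            linearity_r2([1e-4, 1e-3, 1e-2], [0.0, 0.0, 1e-2])


class TestFalsePositiveAnalysis:
    def make_control(self, extra=()):
        recs = [ClonotypeRecord("GCAAGCAAA", "TRB", 500, set_id="C", replicate_id="1"),
                ClonotypeRecord("GCAAGCCCC", "TRB", 50, set_id="C", replicate_id="1")]
        recs.extend(extra)
        return recs

    def test_pure_control_has_no_false_positives(self):
        report = false_positive_analysis(self.make_control(), REF, [], cutoffs=[18])
        assert report.table.empty
        assert report.removal_fraction_by_cutoff[18] == 1.0
        assert report.fp_rate_by_chain["TRB"] == 0.0

    def test_planted_counts_and_cutoff(self):
        fps = [ClonotypeRecord(f"AAACCCGG{'T' * i}A", "TRB", i, set_id="C", replicate_id="1")
               for i in range(1, 11)]
        report = false_positive_analysis(self.make_control(fps), REF, [],
                                         cutoffs=[0, 5, 10])
        assert len(report.table) == 10
        assert set(report.table["category"]) == {"exclusive"}
        assert report.removal_fraction_by_cutoff[5] == pytest.approx(0.5)
        assert report.removal_fraction_by_cutoff[0] == 0.0
        assert report.removal_fraction_by_cutoff[10] == 1.0

    def test_removal_fraction_monotone_in_cutoff(self):
        fps = [ClonotypeRecord(f"AAACCCGG{'T' * i}A", "TRB", 3 * i + 1,
                               set_id="C", replicate_id="1") for i in range(8)]
        cutoffs = list(range(0, 30, 3))
        report = false_positive_analysis(self.make_control(fps), REF, [], cutoffs=cutoffs)
        fracs = [report.removal_fraction_by_cutoff[c] for c in cutoffs]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == 1.0

    def test_index_hopping_linear_trend(self):
        rng = np.random.default_rng(9)
        source_counts = np.unique(rng.integers(2000, 200000, 15))
        fps, others = [], []
        for i, src in enumerate(source_counts):
            cdr3 = f"CCCGGGAA{'T' * (i % 5)}{'A' * (i // 5)}GG"
            others.append(ClonotypeRecord(cdr3, "TRB", int(src), set_id="S1", replicate_id="1"))
            fps.append(ClonotypeRecord(cdr3, "TRB", max(1, round(0.01 * src)),
                                       set_id="C", replicate_id="1"))
        report = false_positive_analysis(self.make_control(fps), REF, others, cutoffs=[18])
        pairs = report.hopping_pairs
        assert len(pairs) == len(source_counts)
        fit = stats.linregress(np.log10(pairs["count_elsewhere"]),
                               np.log10(pairs["count_in_control"]))
        assert fit.slope == pytest.approx(1.0, abs=0.1)

    def test_outlier_flagging(self):
        big = ClonotypeRecord("AAAACCCCGGGG", "TRB", 10_000, set_id="C", replicate_id="1")
        report = false_positive_analysis(self.make_control([big]), REF, [], cutoffs=[18])
        assert report.n_outliers == 1
        assert report.fp_rate_by_chain_excl_outliers["TRB"] == 0.0

    def test_empty_control_rejected(self):
        with pytest.raises(ModelParameterError):
            false_positive_analysis([], REF, [], cutoffs=[18])
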