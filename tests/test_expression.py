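import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from allochrony import expression as ex
from allochrony.errors import ValidationError
from allochrony.synthetic_data import CountsSimConfig, simulate_counts


def make_meta(n_reps=4, drop=True):
    _, meta, _ = simulate_counts(
        CountsSimConfig(n_transcripts=1, n_replicates=n_reps, drop_library=drop, seed=0)
    )
    return meta


class TestCpm:
    def test_single_transcript_is_full_million(self):
        counts = pd.DataFrame({"lib1": [7], "lib2": [3]}, index=["tx1"])
        assert (ex.cpm_normalize(counts).to_numpy() == 1e6).all()

    def test_one_count_in_a_million(self):
        counts = pd.DataFrame({"lib": [1, 10**6 - 1]}, index=["tx1", "tx2"])
        assert ex.cpm_normalize(counts).loc["tx1", "lib"] == pytest.approx(1.0)

    def test_column_sums(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(50, 6)) + 1,
            index=[f"t{i}" for i in range(50)],
            columns=[f"l{j}" for j in range(6)],
        )
        sums = ex.cpm_normalize(counts).sum(axis=0)
        # independent oracle: direct summation of the definition
        manual = (counts / counts.sum(axis=0).to_numpy() * 1e6).sum(axis=0)
        assert np.allclose(sums, 1e6) and np.allclose(sums, manual)

    def test_zero_total_library_named(self):
        counts = pd.DataFrame({"ok": [1], "empty": [0]}, index=["tx1"])
        with pytest.raises(ValidationError, match="empty"):
            ex.cpm_normalize(counts)

    def test_negative_entry_rejected(self):
        counts = pd.DataFrame({"lib": [-1, 3]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="negative"):
            ex.cpm_normalize(counts)


class TestFilterWeak:
    def _matrix(self, cpm_hits):
        """23-library matrix; row 'probe' exceeds 1 CPM in `cpm_hits` libs."""
        libs = [f"l{j}" for j in range(23)]
        base = pd.DataFrame(1000, index=[f"bg{i}" for i in range(9)], columns=libs)
        probe = pd.Series(0, index=libs, name="probe")
        probe.iloc[:cpm_hits] = 100  # ~1.1e4 CPM in those libraries
        return pd.concat([base, probe.to_frame().T])

    def test_kept_at_exactly_seven(self):
        filt = ex.filter_weak(self._matrix(7))
        assert "probe" in filt.counts.index

    def test_dropped_at_six(self):
        filt = ex.filter_weak(self._matrix(6))
        assert "probe" in filt.dropped

    def test_all_zero_dropped(self):
        filt = ex.filter_weak(self._matrix(0))
        assert "probe" in filt.dropped
        assert filt.log["n_dropped"] == 1

    def test_min_libraries_exceeds_libraries(self):
        with pytest.raises(ValidationError):
            ex.filter_weak(self._matrix(3), min_libraries=24)

    def test_idempotent(self, small_counts):
        counts, _, _ = small_counts
        once = ex.filter_weak(counts)
        twice = ex.filter_weak(once.counts)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestContrastTable:
    def test_has_nine_contrasts(self, small_counts):
        counts, meta, _ = small_counts
        table = ex.contrast_table(counts, meta)
        assert set(table["contrast"]) == set(ex.CONTRASTS)
        assert len(table) == 9 * counts.shape[0]

    def test_identical_group_means_zero_logfc(self):
        meta = make_meta(drop=False)
        counts = pd.DataFrame(
            np.full((3, len(meta)), 50), index=["a", "b", "c"], columns=meta.index
        )
        table = ex.contrast_table(counts, meta)
        assert np.allclose(table["log_fc"], 0.0)
        assert np.allclose(table["p_value"], 1.0)

    def test_fourfold_ratio_is_two(self):
        meta = make_meta(drop=False)
        counts = pd.DataFrame(100, index=["probe", "bg"], columns=meta.index)
        e_photo = meta.index[(meta.strain == "E") & (meta.timepoint == "photophase")]
        z_photo = meta.index[(meta.strain == "Z") & (meta.timepoint == "photophase")]
        counts.loc["probe", e_photo] = 400
        counts.loc["probe", z_photo] = 100
        # equalize depths so CPM ratio equals the count ratio
        counts.loc["bg", e_photo] = 100_000 - 400
        counts.loc["bg"] = counts.loc["bg"].where(counts.loc["bg"] != 100, 100_000 - 100)
        table = ex.contrast_table(counts, meta, prior_count=1e-9)
        row = table[(table.transcript == "probe") & (table.contrast == "strain@photophase")]
        assert row["log_fc"].iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_bh_step_up_hand_example(self):
        # q_i = min_{j>=i} p_j * m / j for p = (.01,.02,.03,.04), m = 4
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_at_least_p_and_in_unit_interval(self, small_counts):
        counts, meta, _ = small_counts
        table = ex.contrast_table(counts, meta)
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()
        assert table["q_value"].between(0, 1).all()

    def test_strain_swap_negates_logfc(self, small_counts):
        counts, meta, _ = small_counts
        flipped = meta.copy()
        flipped["strain"] = meta["strain"].map({"E": "Z", "Z": "E"})
        t1 = ex.contrast_table(counts, meta)
        t2 = ex.contrast_table(counts, flipped)
        for tp in ex.TIMEPOINTS:
            name = f"strain@{tp}"
            a = t1[t1.contrast == name].set_index("transcript")
            b = t2[t2.contrast == name].set_index("transcript")
            assert np.allclose(a["log_fc"], -b["log_fc"])
            assert np.allclose(a["p_value"], b["p_value"])

    def test_small_group_rejected(self, small_counts):
        counts, meta, _ = small_counts
        crippled = meta.drop(meta.index[(meta.strain == "E") & (meta.timepoint == "4h")][:3])
        with pytest.raises(ValidationError, match="E 4h"):
            ex.contrast_table(counts.drop(columns=meta.index.difference(crippled.index)), crippled)

    def test_orphan_library_rejected(self, small_counts):
        counts, meta, _ = small_counts
        with pytest.raises(ValidationError, match="mismatch"):
            ex.contrast_table(counts, meta.drop(meta.index[0]))


class TestMeanProfiles:
    def test_constant_transcript(self):
        meta = make_meta()
        cpm = pd.DataFrame(3.5, index=["a"], columns=meta.index)
        prof = ex.strain_timepoint_means(cpm, meta)
        assert list(prof.columns) == list(ex.PROFILE_COLUMNS)
        assert np.allclose(prof.loc["a"], 3.5)

    def test_dropped_replicate_group_averages_three(self):
        meta = make_meta(drop=True)
        z13 = meta.index[(meta.strain == "Z") & (meta.timepoint == "1.3h")]
        assert len(z13) == 3
        cpm = pd.DataFrame(0.0, index=["a"], columns=meta.index)
        cpm.loc["a", z13] = [1.0, 2.0, 6.0]
        prof = ex.strain_timepoint_means(cpm, meta)
        assert prof.loc["a", "Z:1.3h"] == pytest.approx(3.0)

    def test_replicate_order_irrelevant(self, small_counts):
        counts, meta, _ = small_counts
        cpm = ex.cpm_normalize(counts)
        perm = cpm.sample(frac=1, axis=1, random_state=0)
        pd.testing.assert_frame_equal(
            ex.strain_timepoint_means(cpm, meta),
            ex.strain_timepoint_means(perm, meta.loc[perm.columns]),
        )

    def test_empty_group_rejected(self):
        meta = make_meta().iloc[:4]  # only E photophase libraries
        cpm = pd.DataFrame(1.0, index=["a"], columns=meta.index)
        with pytest.raises(ValidationError):
            ex.strain_timepoint_means(cpm, meta)


class TestProfileCorrelations:
    def test_identical_profiles_correlate_perfectly(self):
        prof = pd.DataFrame([[1, 2, 3, 4, 5, 6]] * 2, index=["a", "b"],
                            columns=ex.PROFILE_COLUMNS, dtype=float)
        out = ex.profile_correlations(prof)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_reflection_gives_minus_one(self):
        base = np.array([1.0, 2, 3, 4, 5, 6])
        prof = pd.DataFrame([base, 2 * base.mean() - base], index=["a", "b"],
                            columns=ex.PROFILE_COLUMNS)
        assert ex.profile_correlations(prof)["r"].iloc[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("r,expected", [(-0.82, 0.046), (0.97, 0.001)])
    def test_reported_p_values(self, r, expected):
        assert round(ex.correlation_pvalue(r, 6), 3) == expected

    def test_p_matches_numeric_t_integration(self, rng):
        prof = pd.DataFrame(rng.normal(size=(6, 6)),
                            index=list("abcdef"), columns=ex.PROFILE_COLUMNS)
        out = ex.profile_correlations(prof)
        for _, row in out.iterrows():
            t = abs(row.r) * np.sqrt(4 / (1 - row.r**2))
            dens = stats.t(4).pdf
            tail, _ = integrate.quad(dens, t, np.inf)
            assert row.p_value == pytest.approx(2 * tail, abs=1e-9)

    def test_constant_profile_skipped_with_warning(self, rng):
        prof = pd.DataFrame(rng.normal(size=(3, 6)),
                            index=["a", "b", "c"], columns=ex.PROFILE_COLUMNS)
        prof.loc["b"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            out = ex.profile_correlations(prof)
        pairs = set(map(tuple, out[["transcript_a", "transcript_b"]].to_numpy()))
        assert pairs == {("a", "c")}

    def test_alpha_restricts_output(self, rng):
        prof = pd.DataFrame(rng.normal(size=(8, 6)), columns=ex.PROFILE_COLUMNS)
        out = ex.profile_correlations(prof, alpha=0.05)
        assert (out["p_value"] < 0.05).all()

    def test_too_few_profiles(self):
        prof = pd.DataFrame([[1, 2, 3, 4, 5, 6]], columns=ex.PROFILE_COLUMNS)
        with pytest.raises(ValidationError):
            ex.profile_correlations(prof)


class TestCapLogfc:
    def _table(self, fcs):
        return pd.DataFrame(
            {
                "transcript": [f"t{i}" for i in range(len(fcs))],
                "contrast": "strain@photophase",
                "log_fc": fcs,
                "p_value": 0.01,
                "q_value": [0.01, 0.5][: len(fcs)] * (len(fcs) // 2) or [0.01],
            }
        )

    @pytest.mark.parametrize("fc,capped", [(2.691, 2.0), (-2.86, -2.0), (1.4, 1.4)])
    def test_capping(self, fc, capped):
        out = ex.cap_logfc(self._table([fc, 0.0]))
        assert out["log_fc"].iloc[0] == pytest.approx(capped)

    def test_significance_flags(self):
        out = ex.cap_logfc(self._table([1.0, 1.0]))
        assert list(out["significant"]) == [True, False]

    def test_bad_bounds(self):
        with pytest.raises(ValidationError):
            ex.cap_logfc(self._table([1.0, 0.0]), lo=2, hi=-2)

    def test_original_table_untouched(self):
        table = self._table([3.0, -3.0])
        ex.cap_logfc(table)
        assert table["log_fc"].abs().max() == 3.0


class TestIO:
    def test_counts_roundtrip(self, small_counts, tmp_path):
        counts, _, _ = small_counts
        path = tmp_path / "c.tsv"
        counts.to_csv(path, sep="\t")
        pd.testing.assert_frame_equal(ex.read_counts(path), counts)

    def test_metadata_validation(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("library_id,strain,timepoint,replicate\nl1,E,photophase,1\n"
                        "l2,Q,4h,1\n")
        with pytest.raises(ValidationError, match="strain"):
            ex.read_metadata(path)

    def test_metadata_duplicate_design_cell(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("library_id,strain,timepoint,replicate\nl1,E,4h,1\nl2,E,4h,1\n")
        with pytest.raises(ValidationError, match="duplicate"):
            ex.read_metadata(path)

    def test_heatmap_written(self, small_counts, tmp_path):
        counts, meta, _ = small_counts
        table = ex.contrast_table(ex.filter_weak(counts).counts, meta)
        capped = ex.cap_logfc(table[table.transcript.isin(counts.index[:15])])
        out = tmp_path / "heatmap.png"
        ex.plot_logfc_heatmap(capped, out)
        assert out.stat().st_size > 0
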