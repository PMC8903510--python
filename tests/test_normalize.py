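"""Ratio conversion, IQR trimming, MAD normalization, reference intensities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plexbridge.normalize import (
    assemble_abundance,
    compute_ratios,
    iqr_trim,
    mad_normalize,
    normalize_plexes,
    reference_intensity,
    summarize_entry,
)
from plexbridge.types import QuantMatrix

from conftest import make_design, make_psm


@pytest.fixture(scope="module")
def design():
    return make_design()


class TestComputeRatios:
    def test_log2_ratio_to_reference(self, design):
        rep = [None] * 10
        rep[0] = 400.0
        rep[design.reference_index] = 100.0
        obs = compute_ratios([make_psm(design, reporter=rep)], design)
        assert len(obs) == 1
        assert obs["ratio"].iloc[0] == pytest.approx(2.0)  # log2(400/100)

    def test_channel_equal_to_reference_gives_zero(self, design):
        rep = [None] * 10
        rep[3] = 250.0
        rep[design.reference_index] = 250.0
        obs = compute_ratios([make_psm(design, reporter=rep)], design)
        assert obs["ratio"].iloc[0] == 0.0

    def test_missing_channels_drop_observations(self, design):
        rep = [100.0] * 10
        rep[1] = None
        rep[4] = None  # 2 of 9 sample channels missing -> 7 observations
        obs = compute_ratios([make_psm(design, reporter=rep)], design)
        assert len(obs) == 7

    def test_zero_channel_is_missing_not_neg_inf(self, design):
        rep = [100.0] * 10
        rep[2] = 0.0
        obs = compute_ratios([make_psm(design, reporter=rep)], design)
        assert len(obs) == 8
        assert np.isfinite(obs["ratio"]).all()

    def test_zero_reference_skips_psm_with_count(self, design):
        rep = [100.0] * 10
        rep[design.reference_index] = 0.0
        obs = compute_ratios([make_psm(design, reporter=rep)], design)
        assert len(obs) == 0
        assert obs.attrs["n_ref_zero"] == 1


class TestIqrTrim:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([-0.1, 0.0, 0.1, 0.2, 2.0], [-0.1, 0.0, 0.1, 0.2]),  # bounds [-0.3, 0.5]
            ([5.0], [5.0]),  # single point sits on both bounds
            ([0, 0, 0, 0, 10], [0, 0, 0, 0]),  # Q1=Q3=0 -> bounds [0,0]
        ],
    )
    def test_hand_computed_cases(self, values, expected):
        assert list(iqr_trim(values)) == expected

    def test_empty_is_domain_error(self):
        with pytest.raises(ValueError):
            iqr_trim([])

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_kept_values_subset_within_fences(self, values):
        kept = iqr_trim(values)
        v = np.asarray(values)
        q1, q3 = np.quantile(v, [0.25, 0.75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        assert kept.size >= 1
        assert ((kept >= lo) & (kept <= hi)).all()
        # exactly the in-fence values survive, in order
        assert list(kept) == [x for x in v if lo <= x <= hi]


class TestSummarize:
    def test_median_odd_and_even(self, design):
        obs = pd.DataFrame(
            {
                "entry_id": ["G1"] * 3 + ["G2"] * 2,
                "sample_id": ["plex1.ch01->S01"] * 5,
                "plex_id": ["plex1"] * 5,
                "ratio": [0.0, 0.1, 0.3, 0.0, 0.2],
            }
        )
        m = summarize_entry(obs, ["plex1.ch01->S01"])
        assert m.values.loc["G1"].iloc[0] == pytest.approx(0.1)
        assert m.values.loc["G2"].iloc[0] == pytest.approx(0.1)

    def test_entry_absent_from_second_plex_is_fully_missing(self, design):
        obs = pd.DataFrame(
            {
                "entry_id": ["G1"],
                "sample_id": ["plex1.s1"],
                "plex_id": ["plex1"],
                "ratio": [0.5],
            }
        )
        m = summarize_entry(obs, ["plex1.s1", "plex2.s1", "plex2.s2"])
        assert m.values.loc["G1", "plex1.s1"] == 0.5
        assert m.values.loc["G1", ["plex2.s1", "plex2.s2"]].isna().all()


class TestMadNormalize:
    def test_worked_two_sample_example(self):
        m = QuantMatrix(
            pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [2.0, 4.0, 6.0]},
                         index=["a", "b", "c"])
        )
        rn, params = mad_normalize(m)
        # M=(2,4), MAD=(1,2), M0=3, MAD0=1.5 -> both columns [1.5, 3.0, 4.5]
        assert params.m0 == 3.0 and params.mad0 == 1.5
        for col in ("s1", "s2"):
            assert list(rn.values[col]) == pytest.approx([1.5, 3.0, 4.5])

    def test_single_sample_identity(self):
        m = QuantMatrix(pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=list("abc")))
        rn, _ = mad_normalize(m)
        assert list(rn.values["s1"]) == pytest.approx([1.0, 2.0, 3.0])

    def test_zero_mad_sample_flagged_with_unit_scale(self):
        m = QuantMatrix(
            pd.DataFrame({"s1": [1.0, 1.0, 1.0], "s2": [0.0, 1.0, 2.0]},
                         index=list("abc"))
        )
        rn, params = mad_normalize(m)
        assert params.flagged_zero_mad == ["s1"]
        assert np.isfinite(rn.values.to_numpy()).all()

    @given(
        st.integers(3, 12),
        st.integers(2, 6),
        st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_postconditions_and_rank_preservation(self, n_entries, n_samples, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(scale=2.0, size=(n_entries, n_samples))
        mask = rng.uniform(size=vals.shape) < 0.15
        vals[mask] = np.nan
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_entries)],
                          columns=[f"s{j}" for j in range(n_samples)])
        if df.notna().sum().min() < 2:
            return
        rn, params = mad_normalize(QuantMatrix(df))
        out = rn.values
        # every sample's median is exactly M0 and MAD exactly MAD0
        med = out.median(axis=0, skipna=True)
        mad = (out - med).abs().median(axis=0, skipna=True)
        for s in df.columns:
            if params.mad_i[s] > 0:
                assert med[s] == pytest.approx(params.m0, abs=1e-12)
                assert mad[s] == pytest.approx(params.mad0, abs=1e-12)
        # missingness pattern preserved
        assert (out.isna() == df.isna()).all().all()
        # strictly increasing affine map preserves within-sample ranks
        for s in df.columns:
            a, b = df[s].dropna(), out[s].dropna()
            assert list(a.rank()) == list(b.rank())


class TestReferenceIntensity:
    def make_ref_psm(self, design, ms1, ref_share, spectrum, entry="G1"):
        # 2 channels carry signal: reference gets share, channel 0 the rest
        total = 1000.0
        rep = [None] * design.n_channels
        rep[0] = (1 - ref_share) * total
        rep[design.reference_index] = ref_share * total
        return make_psm(design, entry=entry, spectrum=spectrum, reporter=rep,
                        ms1_intensity=ms1, peptide=f"PEP{spectrum}")

    def test_top3_weighted_sum(self, design):
        psms = [
            self.make_ref_psm(design, 100, 0.1, "a"),
            self.make_ref_psm(design, 80, 0.2, "b"),
            self.make_ref_psm(design, 60, 0.3, "c"),
            self.make_ref_psm(design, 40, 0.4, "d"),
        ]
        ref_ik, ref_i, _ = reference_intensity({"plex1": psms}, [design])
        # top-3 by MS1: 100*0.1 + 80*0.2 + 60*0.3 = 44
        assert ref_ik.loc["G1", "plex1"] == pytest.approx(44.0)

    def test_single_psm(self, design):
        p = self.make_ref_psm(design, 100, 0.25, "a")
        _, ref_i, _ = reference_intensity({"plex1": [p]}, [design])
        assert ref_i["G1"] == pytest.approx(25.0)

    def test_global_min_imputation_then_mean(self):
        d1 = make_design("plex1")
        d2 = make_design("plex2")
        # G1 only in plex1 with REF 44; G2 in both with REF 4 (the global min)
        psms1 = [
            self.make_ref_psm(d1, 100, 0.44, "a", entry="G1"),
            self.make_ref_psm(d1, 100, 0.04, "b", entry="G2"),
        ]
        psms2 = [self.make_ref_psm(d2, 100, 0.04, "c", entry="G2")]
        # fix plex ids on psms2
        for p in psms2:
            p.plex_id = "plex2"
        ref_ik, ref_i, gmin = reference_intensity(
            {"plex1": psms1, "plex2": psms2}, [d1, d2]
        )
        assert gmin == pytest.approx(4.0)
        assert ref_i["G1"] == pytest.approx((44.0 + 4.0) / 2)  # imputed then averaged

    def test_mean_over_observed_only_flag(self):
        d1, d2 = make_design("plex1"), make_design("plex2")
        psms1 = [self.make_ref_psm(d1, 100, 0.44, "a", entry="G1"),
                 self.make_ref_psm(d1, 100, 0.04, "b", entry="G2")]
        _, ref_i, _ = reference_intensity(
            {"plex1": psms1, "plex2": []}, [d1, d2], impute_global_min=False
        )
        assert ref_i["G1"] == pytest.approx(44.0)


class TestAssembleAbundance:
    def test_addition_of_log2_ref(self):
        rn = QuantMatrix(
            pd.DataFrame({"s1": [1.5, np.nan]}, index=["G1", "G2"]),
            kind="normalized_ratio",
        )
        a, n_dropped = assemble_abundance(rn, pd.Series({"G1": 2.0, "G2": 2.0}))
        assert a.values.loc["G1", "s1"] == pytest.approx(2.5)  # 1.5 + log2(2)
        assert np.isnan(a.values.loc["G2", "s1"])  # missing stays missing
        assert n_dropped == 0

    def test_nonpositive_ref_drops_entry(self):
        rn = QuantMatrix(pd.DataFrame({"s1": [1.0, 2.0]}, index=["G1", "G2"]),
                         kind="normalized_ratio")
        a, n_dropped = assemble_abundance(rn, pd.Series({"G1": 1.0, "G2": 0.0}))
        assert a.entry_ids == ["G1"] and n_dropped == 1

    def test_unit_reference_means_abundance_equals_ratio(self):
        rn = QuantMatrix(pd.DataFrame({"s1": [1.5, 3.0]}, index=["G1", "G2"]),
                         kind="normalized_ratio")
        a, _ = assemble_abundance(rn, pd.Series({"G1": 1.0, "G2": 1.0}))
        assert (a.values["s1"] == rn.values["s1"]).all()


class TestPlexShiftCancellation:
    def test_multiplying_a_plex_leaves_ratios_unchanged(self, design):
        rng = np.random.default_rng(5)
        base = [
            make_psm(design, entry=f"G{i%5}", spectrum=f"s{i}", peptide=f"P{i}EPTIDEK",
                     reporter=list(rng.uniform(50, 500, 10)))
            for i in range(40)
        ]
        scaled = [
            make_psm(design, entry=p.entry_id, spectrum=p.spectrum_id, peptide=p.peptide,
                     reporter=[v * 7.5 for v in p.reporter],
                     ms1_intensity=p.ms1_intensity)
            for p in base
        ]
        r1 = compute_ratios(base, design)
        r2 = compute_ratios(scaled, design)
        assert np.allclose(r1["ratio"], r2["ratio"], atol=1e-12)
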