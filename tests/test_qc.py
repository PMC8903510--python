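"""Correlation, PCA, clustering, Z scores, dropout classes, subphenotypes."""

import numpy as np
import pandas as pd
import pytest

from plexbridge.qc import (
    annotate_blood,
    classify_subphenotype,
    dropout_accounting,
    pca_scores,
    spearman_matrix,
    ward_cluster,
    zscore_by_sample,
    DEFAULT_PLASMA_GENES,
    DEFAULT_RBC_GENES,
)
from plexbridge.types import ClinicalAnnotation, PlexChannel, PlexDesign, QuantMatrix

from conftest import make_design


def qm(data: dict, index=None) -> QuantMatrix:
    return QuantMatrix(pd.DataFrame(data, index=index), kind="abundance")


class TestSpearman:
    def test_identical_columns_one(self):
        m = qm({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert spearman_matrix(m).loc["a", "b"] == 1.0

    def test_hand_computed_minus_half(self):
        m = qm({"a": [1.0, 2, 3], "b": [3.0, 1, 2]})
        assert spearman_matrix(m).loc["a", "b"] == pytest.approx(-0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 4))
        m1 = qm({f"s{i}": base[:, i] for i in range(4)})
        transformed = base.copy()
        transformed[:, 0] = np.exp(2.0 * transformed[:, 0]) - 5  # strictly increasing
        m2 = qm({f"s{i}": transformed[:, i] for i in range(4)})
        assert np.allclose(spearman_matrix(m1), spearman_matrix(m2), atol=1e-12)

    def test_pairwise_complete_and_thin_pairs(self):
        vals = pd.DataFrame({"a": [1.0, 2, 3, np.nan], "b": [1.0, 2, np.nan, 4],
                             "c": [np.nan, np.nan, 1.0, 2.0]})
        with pytest.warns(RuntimeWarning):
            corr = spearman_matrix(QuantMatrix(vals), min_shared=3)
        assert np.isnan(corr.loc["a", "c"])  # 1 shared entry only
        assert corr.loc["a", "a"] == 1.0


class TestPca:
    def test_rank_one_data_pc1_explains_all(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0, 1.5])
        loadings = np.array([1.0, 2.0, 3.0, 4.0])
        vals = np.outer(profile, loadings)
        m = qm({f"s{j}": vals[:, j] for j in range(4)})
        _, frac = pca_scores(m, n_components=2)
        assert frac[0] == pytest.approx(1.0, abs=1e-12)

    def test_complete_entries_only(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(10, 5))
        df = pd.DataFrame(vals, columns=[f"s{j}" for j in range(5)])
        df.iloc[0, 0] = np.nan
        scores_full, _ = pca_scores(QuantMatrix(df))
        scores_sub, _ = pca_scores(QuantMatrix(df.dropna()))
        assert np.allclose(np.abs(scores_full), np.abs(scores_sub), atol=1e-9)

    def test_duplicating_sample_preserves_pairwise_geometry(self):
        # exact rank-2 data: the score plane is identical, so pairwise
        # distances between the original samples are untouched
        rng = np.random.default_rng(2)
        a = rng.normal(size=(20, 2))
        b = rng.normal(size=(2, 8))
        vals = a @ b
        m1 = qm({f"s{j}": vals[:, j] for j in range(8)})
        dup = np.hstack([vals, vals[:, [3]]])
        m2 = qm({f"s{j}": dup[:, j] for j in range(9)})
        s1, _ = pca_scores(m1, 2)
        s2, _ = pca_scores(m2, 2)
        from scipy.spatial.distance import pdist

        d1 = pdist(s1.to_numpy())
        d2 = pdist(s2.to_numpy()[:8])
        assert np.allclose(d1, d2, atol=1e-8)

    def test_strong_two_phenotype_separation(self):
        from sklearn.metrics import silhouette_score

        from plexbridge import normalize_plexes
        from plexbridge.simulate import SimConfig, simulate_experiment

        cfg = SimConfig(
            n_plexes=2, n_ctl=8, n_pdr=8, n_proteins=150, pi0=0.2,
            effect_size_sd=4.0, interplex_dropout_rate=0.0,
            intraplex_dropout_rate=0.0, n_plasma=0, n_rbc=0, seed=7,
        )
        sim = simulate_experiment(cfg)
        abundance, _, _, _ = normalize_plexes(sim.psm_tables, sim.designs)
        from plexbridge.de import trim_matrix

        trimmed = trim_matrix(abundance, sim.designs)
        scores, _ = pca_scores(trimmed, 2)
        labels = ["PDR" if "PDR" in s else "CTL" for s in scores.index]
        assert silhouette_score(scores.to_numpy(), labels) > 0.5


class TestWard:
    def test_first_merge_joins_closest_1d_points(self):
        m = qm({"s1": [0.0], "s2": [0.1], "s3": [10.0]})
        z, _, _ = ward_cluster(m, axis="samples")
        assert set(z[0, :2].astype(int)) == {0, 1}

    def test_duplicate_samples_merge_at_height_zero(self):
        m = qm({"s1": [1.0, 2.0], "s2": [1.0, 2.0], "s3": [5.0, 9.0]})
        z, _, _ = ward_cluster(m, axis="samples")
        assert z[0, 2] == 0.0

    def test_labels_invariant_to_entry_permutation(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.normal(size=(12, 6)),
                            index=[f"G{i}" for i in range(12)],
                            columns=[f"s{j}" for j in range(6)])
        _, labels1, _ = ward_cluster(QuantMatrix(vals), axis="samples")
        perm = vals.sample(frac=1.0, random_state=1)
        _, labels2, _ = ward_cluster(QuantMatrix(perm), axis="samples")
        assert (labels1 == labels2).all()

    def test_exclude_and_restrict_filters(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(rng.normal(size=(6, 5)),
                            index=["HBB", "CA1", "G1", "G2", "G3", "G4"],
                            columns=[f"s{j}" for j in range(5)])
        m = QuantMatrix(vals)
        _, labels_entries, _ = ward_cluster(m, axis="entries", restrict=["HBB", "CA1", "G1"])
        assert set(labels_entries.index) == {"HBB", "CA1", "G1"}
        _, labels2, _ = ward_cluster(m, axis="entries", exclude=["HBB", "CA1"])
        assert "HBB" not in labels2.index


class TestZscore:
    def test_hand_example(self):
        m = qm({"s1": [1.0, 2.0, 3.0]})
        z = zscore_by_sample(m)
        assert list(z.values["s1"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_moments_and_missing(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        vals.iloc[0, 0] = np.nan
        z = zscore_by_sample(QuantMatrix(vals)).values
        assert np.isnan(z.iloc[0, 0])
        for c in "abc":
            col = z[c].dropna()
            assert abs(col.mean()) < 1e-12
            assert abs(col.std(ddof=1) - 1) < 1e-12

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError):
            zscore_by_sample(qm({"s1": [1.0, 1.0, 1.0]}))


class TestDropout:
    def two_plex_designs(self):
        d1 = make_design("plex1", n_channels=4)
        ch = [PlexChannel(c.channel_label, f"B{c.sample_id}", c.role, c.phenotype)
              for c in make_design("plex2", n_channels=4).channels]
        d2 = PlexDesign("plex2", ch)
        return [d1, d2]

    def cols(self, designs):
        return [d.global_sample_id(c) for d in designs for c in d.sample_channels()]

    def test_three_classes(self):
        designs = self.two_plex_designs()
        cols = self.cols(designs)  # 3 non-ref per plex
        vals = pd.DataFrame(
            [
                [1.0] * 6,  # complete
                [1.0, 1.0, 1.0, np.nan, np.nan, np.nan],  # interplex
                [1.0, np.nan, 1.0, 1.0, 1.0, 1.0],  # intraplex
            ],
            index=["comp", "inter", "intra"],
            columns=cols,
        )
        summary, membership = dropout_accounting(QuantMatrix(vals), designs)
        assert summary.classes["comp"] == "complete"
        assert summary.classes["inter"] == "interplex"
        assert summary.classes["intra"] == "intraplex"
        assert summary.n_total == 3
        assert membership.loc["inter", "plex_pattern"] == "full|none"

    def test_intraplex_precedence_over_interplex(self):
        designs = self.two_plex_designs()
        vals = pd.DataFrame(
            [[1.0, np.nan, 1.0, np.nan, np.nan, np.nan]],
            index=["mix"], columns=self.cols(designs),
        )
        summary, _ = dropout_accounting(QuantMatrix(vals), designs)
        assert summary.classes["mix"] == "intraplex"

    def test_partition_is_exact(self, study_pipeline):
        sim, abundance, _, _, _ = study_pipeline
        summary, _ = dropout_accounting(abundance, sim.designs)
        assert summary.n_complete + summary.n_interplex + summary.n_intraplex == summary.n_total
        assert summary.n_total == abundance.values.shape[0]


class TestSubphenotype:
    @pytest.mark.parametrize(
        "hb,expected",
        [
            (1.0e-4, "PDR-L"),  # band endpoint inclusive
            (0.0, "PDR-L"),
            (2.0e-4, "PDR-M"),
            (1.7e-3, "PDR-M"),
            (4.9e-3, "PDR-H"),
            (8.4e-3, "PDR-H"),  # study maximum
        ],
    )
    def test_band_mapping(self, hb, expected):
        lab = classify_subphenotype(ClinicalAnnotation("s", "PDR", hemoglobin=hb))
        assert lab.label == expected

    @pytest.mark.parametrize("hb", [1.5e-4, 3.0e-3])
    def test_gap_values_unclassified(self, hb):
        with pytest.warns(RuntimeWarning):
            lab = classify_subphenotype(ClinicalAnnotation("s", "PDR", hemoglobin=hb))
        assert lab.label == "unclassified"

    def test_control_stays_control(self):
        lab = classify_subphenotype(ClinicalAnnotation("s", "CTL"))
        assert lab.label == "CTL"

    def test_negative_hemoglobin_rejected(self):
        with pytest.raises(ValueError):
            ClinicalAnnotation("s", "PDR", hemoglobin=-1.0)


class TestAnnotateBlood:
    def test_default_panels_cover_30_symbols(self):
        assert len(set(DEFAULT_PLASMA_GENES) | set(DEFAULT_RBC_GENES)) == 30
        annot = annotate_blood(list(DEFAULT_PLASMA_GENES) + list(DEFAULT_RBC_GENES))
        counts = pd.Series(annot).value_counts()
        assert counts["plasma"] == 23 and counts["rbc"] == 7

    def test_membership_and_other(self):
        annot = annotate_blood(["ALB", "HBB", "NEO1"])
        assert annot == {"ALB": "plasma", "HBB": "rbc", "NEO1": "other"}

    def test_overlap_resolves_rbc_first(self):
        annot = annotate_blood(["X"], plasma_set=["X"], rbc_set=["X"])
        assert annot["X"] == "rbc"
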