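"""Feature tables, well summaries, correlations, group comparisons, embeddings."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score, silhouette_score

from prism.features import (
    cluster_profiles,
    compare_groups,
    correlation_difference_test,
    density_regions,
    embed_tsne,
    extract_features,
    normalize_for_embedding,
    pairwise_correlations,
    per_well_correlations,
    summarize_wells,
)
from prism.simulate import SubtypeDef, simulate_feature_tables


class TestExtractFeatures:
    @staticmethod
    def _inputs():
        from prism.segmentation import PunctaSet, SynapseSet

        syn_tab = pd.DataFrame(
            [{"id": 1, "area_px": 20, "area_um2": 0.7, "integrated_intensity": 100.0,
              "x": 5.0, "y": 5.0},
             {"id": 2, "area_px": 15, "area_um2": 0.52, "integrated_intensity": 80.0,
              "x": 20.0, "y": 20.0}]
        )
        synapses = SynapseSet(syn_tab, 187.0, 0.42)
        p_tab = pd.DataFrame(
            [{"id": 7, "area_px": 10, "area_um2": 0.35, "integrated_intensity": 50.0,
              "x": 5.5, "y": 5.0}]
        )
        puncta = {"PSD95": PunctaSet(np.zeros((32, 32), np.int32), p_tab, "PSD95", 187.0)}
        assignments = {
            "PSD95": pd.DataFrame(
                {"synapse_id": [1, 2], "punctum_id": [7, -1], "distance_um": [0.09, np.nan]}
            )
        }
        return synapses, assignments, puncta

    def test_zero_assigned_when_no_colocalized_punctum(self):
        synapses, assignments, puncta = self._inputs()
        tab = extract_features(synapses, assignments, puncta)
        row2 = tab[tab.synapse_id == 2].iloc[0]
        assert row2["PSD95_intensity"] == 0.0
        assert row2["PSD95_area_um2"] == 0.0
        assert row2["PSD95_mean_intensity"] == 0.0

    def test_mean_equals_integrated_over_area_rowwise(self):
        synapses, assignments, puncta = self._inputs()
        tab = extract_features(synapses, assignments, puncta)
        pos = tab["PSD95_area_um2"] > 0
        assert np.allclose(
            tab.loc[pos, "PSD95_mean_intensity"],
            tab.loc[pos, "PSD95_intensity"] / tab.loc[pos, "PSD95_area_um2"],
        )

    def test_missing_punctum_reference_raises(self):
        synapses, assignments, puncta = self._inputs()
        assignments["PSD95"].loc[0, "punctum_id"] = 999
        with pytest.raises(KeyError):
            extract_features(synapses, assignments, puncta)


class TestSummarizeWells:
    def test_single_image_single_synapse_passthrough(self):
        tab = pd.DataFrame(
            {"synapse_id": [0], "well": ["W1"], "image_id": ["a"], "f": [3.5]}
        )
        out = summarize_wells(tab, ["f"])
        assert out.loc[0, "f"] == 3.5

    def test_two_stage_mean_weights_images_equally(self):
        # image a: 3 synapses mean 2; image b: 1 synapse mean 4
        # two-stage mean = (2 + 4) / 2 = 3, not the pooled mean 2.5
        tab = pd.DataFrame(
            {
                "synapse_id": range(4),
                "well": ["W1"] * 4,
                "image_id": ["a", "a", "a", "b"],
                "f": [1.0, 2.0, 3.0, 4.0],
            }
        )
        out = summarize_wells(tab, ["f"])
        assert out.loc[0, "f"] == pytest.approx(3.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        tab = simulate_feature_tables(
            wells=[("W1", "u", "B1"), ("W2", "u", "B1")], synapses_per_image=20, seed=1
        )
        cols = [c for c in tab.columns if c.endswith("_intensity")]
        a = summarize_wells(tab, cols)
        shuffled = tab.sample(frac=1.0, random_state=2).reset_index(drop=True)
        b = summarize_wells(shuffled, cols)
        pd.testing.assert_frame_equal(
            a.sort_values("well").reset_index(drop=True)[["well"] + cols],
            b.sort_values("well").reset_index(drop=True)[["well"] + cols],
        )


class TestPairwiseCorrelations:
    def test_self_correlation_is_one_and_symmetry(self):
        tab = simulate_feature_tables(synapses_per_image=300, seed=3)
        chans = ["synapsin", "PSD95", "bassoon"]
        net = pairwise_correlations(tab, chans, by="batch")
        assert np.allclose(np.diag(net.matrix), 1.0)
        assert np.allclose(net.matrix, net.matrix.T)

    def test_twelve_channels_give_66_pairs(self):
        rng = np.random.default_rng(4)
        chans = [f"c{i}" for i in range(12)]
        data = {f"{c}_intensity": rng.random(50) for c in chans}
        data["batch"] = ["B1"] * 50
        net = pairwise_correlations(pd.DataFrame(data), chans, by="batch", threshold=-2)
        assert len(net.edges) == 66

    def test_planted_correlation_recovered_and_edges_thresholded(self):
        k = 4
        corr = np.eye(k)
        corr[0, 1] = corr[1, 0] = 0.70
        corr[2, 3] = corr[3, 2] = 0.20
        chans = ("a", "b", "c", "d")
        tab = simulate_feature_tables(
            channels=chans,
            correlation=corr,
            synapses_per_image=5000,
            images_per_well=1,
            well_effect_sigma=0.0,
            seed=5,
        )
        net = pairwise_correlations(tab, list(chans), by="batch")
        assert abs(net.matrix.loc["a", "b"] - 0.70) < 0.05
        edge_pairs = {frozenset((r.a, r.b)) for r in net.edges.itertuples()}
        # note: lognormal intensities attenuate the latent normal correlation
        # slightly, but 0.7 stays well above and 0.2 well below the threshold
        assert frozenset(("a", "b")) in edge_pairs
        assert frozenset(("c", "d")) not in edge_pairs

    def test_zero_variance_channel_warns_and_skips_group(self):
        tab = pd.DataFrame(
            {
                "a_intensity": [1.0, 2.0, 3.0, 4.0],
                "b_intensity": [5.0, 5.0, 5.0, 5.0],
                "batch": ["B1"] * 4,
            }
        )
        with pytest.warns(UserWarning):
            net = pairwise_correlations(tab, ["a", "b"], by="batch")
        assert np.isnan(net.matrix.loc["a", "b"])


class TestCompareGroups:
    @staticmethod
    def _well_table(u_vals, t_vals):
        rows = [
            {"well": f"U{i}", "treatment": "untreated", "f": v} for i, v in enumerate(u_vals)
        ] + [{"well": f"T{i}", "treatment": "TTX", "f": v} for i, v in enumerate(t_vals)]
        return pd.DataFrame(rows)

    def test_identical_groups_give_t_zero_p_one(self):
        tab = self._well_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = compare_groups(tab, "untreated", "TTX", ["f"]).table.iloc[0]
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)
        assert res["relative_treated"] == pytest.approx(1.0)

    def test_t_statistic_matches_hand_computation(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        res = compare_groups(self._well_table(a, b), "untreated", "TTX", ["f"]).table.iloc[0]
        # pooled-variance two-sample t on 3+3 values
        sp2 = (2 * np.var(a, ddof=1) + 2 * np.var(b, ddof=1)) / 4
        t_hand = (np.mean(b) - np.mean(a)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res["t"] == pytest.approx(t_hand)
        assert t_hand == pytest.approx(1.5491933)

    def test_planted_30_percent_effect_detected(self):
        wells = [(f"U{i}", "untreated", "B1") for i in range(6)] + [
            (f"T{i}", "TTX", "B1") for i in range(6)
        ]
        tab = simulate_feature_tables(
            wells=wells,
            effects={"TTX": {"PSD95": 1.3, "Homer": 1.3, "SHANK3": 1.3}},
            well_effect_sigma=0.05,
            synapses_per_image=100,
            seed=7,
        )
        cols = [c for c in tab.columns if c.endswith("_intensity")]
        welltab = summarize_wells(tab, cols)
        res = compare_groups(welltab, "untreated", "TTX", cols).table.set_index("feature")
        for ch in ("PSD95", "Homer", "SHANK3"):
            assert res.loc[f"{ch}_intensity", "p"] < 0.05
            assert res.loc[f"{ch}_intensity", "relative_treated"] == pytest.approx(1.3, abs=0.1)

    def test_too_few_wells_rejected(self):
        tab = self._well_table([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            compare_groups(tab, "untreated", "TTX", ["f"])


class TestCorrelationDifferenceTest:
    def test_centering_makes_untreated_differences_average_zero(self):
        rng = np.random.default_rng(8)
        rows = []
        for b in ("B1", "B2"):
            for i in range(3):
                rows.append({"well": f"{b}U{i}", "treatment": "u", "batch": b,
                             "a|b": rng.uniform(0.2, 0.5)})
                rows.append({"well": f"{b}T{i}", "treatment": "t", "batch": b,
                             "a|b": rng.uniform(0.2, 0.5)})
        wc = pd.DataFrame(rows)
        res = correlation_difference_test(wc, "u", "t")
        # reconstruct centered untreated means per replicate: must be 0
        for b in ("B1", "B2"):
            g = wc[wc.batch == b]
            base = g.loc[g.treatment == "u", "a|b"].mean()
            assert np.allclose((g.loc[g.treatment == "u", "a|b"] - base).mean(), 0.0)
        assert res.iloc[0]["p"] >= 0.0

    def test_raised_correlation_flagged_for_that_pair_only(self):
        corr_u = np.eye(3); corr_u[0, 1] = corr_u[1, 0] = 0.3
        corr_t = np.eye(3); corr_t[0, 1] = corr_t[1, 0] = 0.6
        chans = ("a", "b", "c")
        frames = []
        for b in ("B1", "B2"):
            for i in range(3):
                frames.append(simulate_feature_tables(
                    channels=chans, correlation=corr_u, wells=[(f"{b}U{i}", "u", b)],
                    synapses_per_image=400, seed=hash((b, i, "u")) % 2**31))
                frames.append(simulate_feature_tables(
                    channels=chans, correlation=corr_t, wells=[(f"{b}T{i}", "t", b)],
                    synapses_per_image=400, seed=hash((b, i, "t")) % 2**31))
        tab = pd.concat(frames, ignore_index=True)
        wc = per_well_correlations(tab, list(chans))
        res = correlation_difference_test(wc, "u", "t").set_index("pair")
        assert res.loc["a|b", "p"] < 0.05
        assert res.loc["a|c", "p"] > 0.05
        assert res.loc["b|c", "p"] > 0.05

    def test_replicate_without_untreated_rejected(self):
        wc = pd.DataFrame(
            [{"well": "W1", "treatment": "t", "batch": "B1", "a|b": 0.5}]
        )
        with pytest.raises(ValueError):
            correlation_difference_test(wc, "u", "t")


class TestNormalizeForEmbedding:
    def test_every_column_has_sd_one_and_min_zero(self):
        tab = simulate_feature_tables(synapses_per_image=200, seed=9)
        cols = [c for c in tab.columns if c.endswith(("_intensity", "_area_um2"))]
        out = normalize_for_embedding(tab, cols)
        assert np.allclose(out.std(axis=0, ddof=0), 1.0)
        assert np.allclose(out.min(axis=0), 0.0)

    def test_feature_count_contracts(self):
        rng = np.random.default_rng(10)
        n = 40
        # 13 intensity channels + 11 area channels -> 24 embedding features
        cols24 = [f"ch{i}_intensity" for i in range(13)] + [f"ch{i}_area" for i in range(11)]
        tab24 = pd.DataFrame({c: rng.random(n) for c in cols24})
        assert normalize_for_embedding(tab24, cols24).shape[1] == 24
        # 10 synaptic targets x (mean intensity + area) + MAP2 mean intensity -> 21
        cols21 = (
            [f"t{i}_mean_intensity" for i in range(10)]
            + [f"t{i}_area" for i in range(10)]
            + ["MAP2_mean_intensity"]
        )
        tab21 = pd.DataFrame({c: rng.random(n) for c in cols21})
        assert normalize_for_embedding(tab21, cols21).shape[1] == 21

    def test_zero_variance_feature_dropped_with_warning(self):
        tab = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            out = normalize_for_embedding(tab, ["a", "b"])
        assert list(out.columns) == ["a"]


@pytest.fixture(scope="module")
def subtype_profiles():
    """Two planted sub-types with disjoint suppressed-channel signatures."""
    tab = simulate_feature_tables(
        subtypes=(
            SubtypeDef("excitatory", (), 0.6),
            SubtypeDef("sparse", ("PSD95", "Homer"), 0.4),
        ),
        synapses_per_image=300,
        seed=11,
    )
    cols = [c for c in tab.columns if c.endswith(("_intensity", "_area_um2"))]
    X = normalize_for_embedding(tab, cols)
    return tab, X


class TestEmbedTsne:
    def test_subtypes_separate_and_embedding_reproducible(self, subtype_profiles):
        tab, X = subtype_profiles
        emb1 = embed_tsne(X, perplexity=20, n_iter=300, subsample=None, seed=0)
        emb2 = embed_tsne(X, perplexity=20, n_iter=300, subsample=None, seed=0)
        assert np.allclose(emb1, emb2)
        sil = silhouette_score(emb1, tab["subtype"])
        assert sil > 0.3

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            embed_tsne(np.random.rand(50, 4), perplexity=40)


class TestDensityRegions:
    def test_two_separated_blobs_give_two_modes(self):
        rng = np.random.default_rng(12)
        pts = np.vstack(
            [rng.normal([0, 0], 1.0, (300, 2)), rng.normal([12, 0], 1.0, (300, 2))]
        )
        dens, modes, info = density_regions(pts)
        assert len(modes) == 2
        assert info["integral"] == pytest.approx(1.0, abs=0.01)
        assert not info["low_confidence"]

    def test_uniform_points_flagged_low_confidence(self):
        rng = np.random.default_rng(13)
        pts = rng.uniform(0, 10, (500, 2))
        _, modes, info = density_regions(pts)
        assert info["low_confidence"]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            density_regions(np.random.rand(5, 2))


class TestClusterProfiles:
    def test_duplicated_channel_merges_at_lowest_feature_height(self, subtype_profiles):
        tab, X = subtype_profiles
        X = X.copy()
        rng = np.random.default_rng(14)
        # a second imaging round of the same channel: identical signal + noise
        X["synapsin_round2"] = X["synapsin_intensity"] + rng.normal(0, 0.05, len(X))
        _, feat_link = cluster_profiles(X)
        cols = list(X.columns)
        first = feat_link[0]
        merged = {cols[int(first[0])], cols[int(first[1])]}
        assert merged == {"synapsin_intensity", "synapsin_round2"}

    def test_two_subtypes_recovered_with_high_ari(self, subtype_profiles):
        tab, X = subtype_profiles
        row_link, _ = cluster_profiles(X)
        labels = fcluster(row_link, t=2, criterion="maxclust")
        assert adjusted_rand_score(tab["subtype"], labels) > 0.8

    def test_linkage_heights_nondecreasing(self, subtype_profiles):
        _, X = subtype_profiles
        row_link, feat_link = cluster_profiles(X)
        assert np.all(np.diff(row_link[:, 2]) >= -1e-9)
        assert np.all(np.diff(feat_link[:, 2]) >= -1e-9)

    def test_nan_features_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cluster_profiles(X)
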