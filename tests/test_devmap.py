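"""Developmental map: standardization, gene-space PCA, temporal clusters,
and projection of DE gene lists."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fxsmap import devmap as dm
from fxsmap import synthetic


class TestStandardizeSamples:
    def test_hand_computed(self):
        m = pd.DataFrame({"s": [1.0, 2.0, 3.0]})
        assert np.allclose(dm.standardize_samples(m)["s"], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(40, 3)))
        once = dm.standardize_samples(m)
        twice = dm.standardize_samples(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(30, 2)))
        a = dm.standardize_samples(m)
        b = dm.standardize_samples(m * 7.0 - 3.0)
        pd.testing.assert_frame_equal(a, b)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            dm.standardize_samples(pd.DataFrame({"s": [1.0, 1.0, 1.0]}))


@pytest.fixture(scope="module")
def noise_free():
    cfg = synthetic.HumanSimConfig(n_genes=90, sigma_noise=0.0,
                                   baseline_sd=0.0, seed=5)
    return synthetic.simulate_human_devseries(cfg)


class TestGeneSpacePCA:
    def test_archetypes_form_collinear_groups(self, noise_free):
        expr, meta, truth = noise_free
        cols = meta.index[meta["region"] == "NCX"]
        std = dm.standardize_samples(expr[list(cols)])
        scores = dm.gene_space_pca(std).scores
        for k in range(3):
            pts = scores[truth.genes["archetype_index"].to_numpy() == k].to_numpy()
            cov = np.cov(pts.T)
            eig = np.sort(np.linalg.eigvalsh(cov))
            # second principal direction carries ~no variance: a line
            assert eig[0] < 1e-3 * max(eig[1], 1e-30) + 1e-12

    def test_duplicated_gene_rows_share_scores(self, noise_free):
        expr, meta, _ = noise_free
        std = dm.standardize_samples(expr)
        dup = pd.concat([std, std.set_axis([f"{i}_dup" for i in std.index])])
        scores = dm.gene_space_pca(dup).scores
        for g in std.index[:5]:
            assert np.allclose(scores.loc[g], scores.loc[f"{g}_dup"])

    def test_variance_fractions_nonincreasing(self, noise_free):
        expr, _, _ = noise_free
        res = dm.gene_space_pca(dm.standardize_samples(expr), n_components=2)
        assert res.variance_fraction[0] >= res.variance_fraction[1]

    def test_fewer_samples_than_components_rejected(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 1)))
        with pytest.raises(ValueError):
            dm.gene_space_pca(m, n_components=2)


class TestKmeans:
    def test_separable_groups_exact_recovery(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        labels = np.repeat([0, 1, 2], 30)
        pts = centers[labels] + rng.normal(0, 0.1, (90, 2))
        scores = pd.DataFrame(pts, columns=["PC1", "PC2"])
        got = dm.kmeans3(scores, seed=0)
        assert adjusted_rand_score(labels, got) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(rng.normal(size=(50, 2)), columns=["PC1", "PC2"])
        a = dm.kmeans3(scores, seed=7)
        b = dm.kmeans3(scores, seed=7)
        assert (a == b).all()

    def test_restarts_do_not_worsen_objective(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(60, 2))
        scores = pd.DataFrame(pts, columns=["PC1", "PC2"])

        def inertia(assign):
            tot = 0.0
            for k in range(3):
                sub = pts[assign.to_numpy() == k]
                tot += ((sub - sub.mean(axis=0)) ** 2).sum()
            return tot

        single = inertia(dm.kmeans3(scores, seed=1, n_restarts=1))
        multi = inertia(dm.kmeans3(scores, seed=1, n_restarts=20))
        assert multi <= single + 1e-9

    def test_degenerate_points_rejected(self):
        scores = pd.DataFrame([[1.0, 1.0]] * 5, columns=["PC1", "PC2"])
        with pytest.raises(ValueError, match="distinct"):
            dm.kmeans3(scores)


class TestTemporalLabels:
    def test_noise_free_labels_equal_planted_archetypes(self, noise_free):
        expr, meta, truth = noise_free
        model = dm.build_dev_model(expr, meta, region="NCX", seed=0)
        assert (model.label_of() == truth.genes["archetype"]).all()

    def test_early_cluster_peaks_by_stage_six(self, noise_free):
        expr, meta, _ = noise_free
        model = dm.build_dev_model(expr, meta, region="NCX", seed=0)
        early = next(c for c, lab in model.labels.items() if lab == "early")
        assert int(model.median_profiles.loc[early].idxmax()) <= 6

    def test_cluster_index_permutation_invariance(self, noise_free):
        expr, meta, _ = noise_free
        model = dm.build_dev_model(expr, meta, region="NCX", seed=0)
        prof = model.median_profiles
        swapped = prof.rename(index={0: 2, 2: 0}).sort_index()
        lab_a = dm.assign_temporal_labels(prof)
        lab_b = dm.assign_temporal_labels(swapped)
        assert lab_b[2] == lab_a[0] and lab_b[0] == lab_a[2]

    def test_identical_profiles_degenerate(self):
        prof = pd.DataFrame([[0.0, 1.0, 0.0]] * 2, index=[0, 1],
                            columns=pd.RangeIndex(1, 4, name="stage"))
        with pytest.raises(ValueError, match="degenerate"):
            dm.assign_temporal_labels(prof)


@pytest.fixture(scope="module")
def model(human_sim):
    expr, meta, _ = human_sim
    return dm.build_dev_model(expr, meta, region="NCX", seed=0)


class TestProjection:

    def test_whole_universe_percentages_equal_proportions(self, model):
        lists = {"all": list(model.universe)}
        proj = dm.project_de_genes(lists, model, percent_digits=4)
        expect = 100.0 * model.proportions()
        assert np.allclose(proj.percent.loc["all"], expect, atol=1e-3)

    def test_partition_conservation(self, model):
        rng = np.random.default_rng(5)
        genes = rng.choice(model.universe, 300, replace=False)
        proj = dm.project_de_genes({"x": list(genes)}, model)
        assert proj.counts.loc["x"].sum() == 300

    def test_outside_universe_genes_dropped_and_counted(self, model):
        genes = list(model.universe[:10]) + [999999]
        proj = dm.project_de_genes({"x": genes}, model)
        assert proj.dropped["x"] == 1
        assert proj.counts.loc["x"].sum() == 10

    def test_homology_mapping_applied(self, model):
        hom = {int(g) - synthetic.HOMOLOGY_OFFSET: int(g)
               for g in model.universe[:50]}
        proj = dm.project_de_genes({"m": list(hom)}, model, homology=hom)
        assert proj.counts.loc["m"].sum() == 50

    @pytest.mark.parametrize("counts,expect", [
        ((821, 191, 298), (63, 15, 23)),
        ((239, 200, 260), (34, 29, 37)),
    ])
    def test_published_percentage_rows(self, counts, expect):
        assert tuple(dm.percentages(counts, 0).astype(int)) == expect

    def test_one_decimal_mode(self):
        assert tuple(dm.percentages((92, 126, 65), 1)) == (32.5, 44.5, 23.0)


class TestEarlyEnrichment:
    def test_published_cortical_culture_or(self):
        st = dm.early_or_from_counts((1160, 729, 576), (5572, 4217, 4041))
        assert round(st.odds_ratio, 2) == 1.40
        assert (round(st.ci_low, 2), round(st.ci_high, 2)) == (1.28, 1.53)

    def test_published_hippocampus_tissue_or(self):
        st = dm.early_or_from_counts((153, 197, 104), (5808, 4242, 3780))
        assert round(st.odds_ratio, 2) == 0.69

    def test_counts_exceeding_totals_rejected(self):
        with pytest.raises(ValueError):
            dm.early_or_from_counts((10, 0, 0), (5, 5, 5))


class TestRecoveryOnDefaults:
    def test_seed_change_preserves_composition(self, human_sim):
        expr, meta, _ = human_sim
        a = dm.build_dev_model(expr, meta, region="HIP", seed=0)
        b = dm.build_dev_model(expr, meta, region="HIP", seed=99)
        assert adjusted_rand_score(a.assignments, b.assignments) >= 0.95
        assert (a.label_of() == b.label_of()).mean() >= 0.97
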