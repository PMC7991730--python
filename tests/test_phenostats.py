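import numpy as np
import pandas as pd
import pytest

import methrevert as mr
from methrevert.core_io import PhenotypeTable
from methrevert.phenostats import (
    chi2_rank_promoters,
    cluster_promoters,
    correlate_panel,
    pca_common_sites,
    promoter_mean_table,
    _tier,
)
from methrevert.simulate import simulate_phenotypes


class TestTiers:
    @pytest.mark.parametrize(
        "r,p,expected",
        [
            (0.7, 5e-4, "strong"),
            (-0.7, 5e-4, "assoc"),  # strong demands positive r
            (0.45, 0.005, "assoc"),
            (0.45, 0.02, "none"),
            (0.2, 1e-5, "none"),
        ],
    )
    def test_conjunctive_thresholds(self, r, p, expected):
        assert _tier(r, p) == expected


class TestCorrelatePanel:
    def test_linear_phenotype_gives_perfect_strong_tier(self, planted_study):
        matrix = planted_study["matrix"]
        promoters = planted_study["promoters"]
        gene = promoters[0].gene_id
        levels = promoter_mean_table(matrix, promoters, [gene])
        pheno = pd.DataFrame(
            {
                "group": [planted_study["groups"][s] for s in matrix.samples],
                "BW": 10 + 50 * levels.loc[gene].to_numpy(),
            },
            index=pd.Index(matrix.samples, name="sample_id"),
        )
        (rec,) = correlate_panel(
            matrix, [gene], promoters, PhenotypeTable(pheno), phenos=("BW",)
        )
        assert rec.r == pytest.approx(1.0)
        assert rec.tier == "strong"

    def test_planted_linkage_is_recovered(self, planted_study):
        cfg = planted_study["config"]
        matrix = planted_study["matrix"]
        promoters = planted_study["promoters"]
        gene = "gene_0001"
        levels = promoter_mean_table(matrix, promoters, [gene])
        import dataclasses

        linked = dataclasses.replace(
            cfg, linked_genes={gene: ("BW", 20.0, 60.0, 1.0)}
        )
        pheno = simulate_phenotypes(linked, planted_study["groups"], levels)
        (rec,) = correlate_panel(
            matrix, [gene], promoters, pheno, phenos=("BW",)
        )
        assert rec.tier in ("assoc", "strong")

    def test_independent_phenotype_stays_none(self, planted_study):
        matrix = planted_study["matrix"]
        promoters = planted_study["promoters"]
        rng = np.random.default_rng(7)
        pheno = pd.DataFrame(
            {
                "group": [planted_study["groups"][s] for s in matrix.samples],
                "GLU": rng.normal(3.6, 0.3, len(matrix.samples)),
            },
            index=pd.Index(matrix.samples, name="sample_id"),
        )
        null_genes = list(
            planted_study["truth"].genes_with("null")
        )[:20]
        records = correlate_panel(
            matrix, null_genes, promoters, PhenotypeTable(pheno), phenos=("GLU",)
        )
        tiers = [r.tier for r in records]
        assert tiers.count("none") / len(tiers) >= 0.9

    def test_pearson_invariant_to_affine_transforms(self, planted_study):
        matrix = planted_study["matrix"]
        promoters = planted_study["promoters"]
        gene = promoters[1].gene_id
        levels = promoter_mean_table(matrix, promoters, [gene]).loc[gene]
        rng = np.random.default_rng(3)
        base = levels + rng.normal(0, 0.05, len(levels))
        for a, b in [(1.0, 0.0), (-2.0, 7.0), (0.01, -5.0)]:
            pheno = pd.DataFrame(
                {
                    "group": [planted_study["groups"][s] for s in matrix.samples],
                    "BW": a * base.to_numpy() + b,
                },
                index=pd.Index(matrix.samples, name="sample_id"),
            )
            (rec,) = correlate_panel(
                matrix, [gene], promoters, PhenotypeTable(pheno), phenos=("BW",)
            )
            if a > 0:
                r_pos = rec.r
            assert abs(rec.r) == pytest.approx(abs(r_pos), abs=1e-12)


class TestPca:
    def test_ffc_separates_from_other_groups(self, planted_study):
        from sklearn.metrics import silhouette_score

        scores, _ = pca_common_sites(planted_study["matrix"])
        labels = (scores["group"] == "FFC").astype(int)
        X = scores[["PC1", "PC2"]].to_numpy()
        assert silhouette_score(X, labels) > 0

    def test_duplicated_sample_gets_identical_scores(self, planted_study):
        matrix = planted_study["matrix"]
        import dataclasses

        twin = dataclasses.replace(
            matrix,
            samples=matrix.samples + [matrix.samples[0] + "_twin"],
            groups=pd.concat(
                [matrix.groups, pd.Series({matrix.samples[0] + "_twin": "SD"})]
            ),
            meth=np.column_stack([matrix.meth, matrix.meth[:, 0]]),
            depth=np.column_stack([matrix.depth, matrix.depth[:, 0]]),
        )
        scores, _ = pca_common_sites(twin)
        np.testing.assert_allclose(
            scores.loc[matrix.samples[0], ["PC1", "PC2"]].astype(float),
            scores.loc[matrix.samples[0] + "_twin", ["PC1", "PC2"]].astype(float),
            atol=1e-8,
        )

    def test_scores_preserve_centered_distances(self, planted_study):
        """Full-rank PCA is a rotation: pairwise sample distances survive."""
        common = planted_study["matrix"].common_view()
        X = common.ratio.T
        n = X.shape[0]
        scores, _ = pca_common_sites(planted_study["matrix"], n_components=n - 1)
        S = scores.drop(columns="group").to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(S), pdist(Xc), rtol=1e-8, atol=1e-10)


class TestChi2Ranking:
    def _matrix_from_pools(self, pools):
        """One promoter-covering site per group-sample with given pooled counts."""
        import pandas as pd
        from methrevert.quant import MethylationMatrix

        samples = [f"s{i}" for i in range(len(pools))]
        groups = {f"s{i}": f"G{i}" for i in range(len(pools))}
        meth = np.array([[m for m, _ in pools]])
        depth = np.array([[t for _, t in pools]])
        return MethylationMatrix(
            sites=pd.DataFrame({"chrom": ["chr1"], "pos": [1_000_000]}),
            samples=samples,
            groups=pd.Series(groups),
            meth=meth,
            depth=depth,
        )

    def test_hand_computed_statistic(self):
        matrix = self._matrix_from_pools([(90, 100), (10, 100), (50, 100)])
        promoters = mr.build_promoters([("g", "chr1", "+", 1_000_100)])
        ranked = chi2_rank_promoters(matrix, promoters)
        assert ranked.loc[0, "chi2"] == pytest.approx(128.0)

    def test_identical_proportions_rank_last(self):
        matrix = self._matrix_from_pools([(50, 100), (50, 100), (50, 100)])
        promoters = mr.build_promoters([("g", "chr1", "+", 1_000_100)])
        ranked = chi2_rank_promoters(matrix, promoters)
        assert ranked.loc[0, "chi2"] == 0.0 and ranked.loc[0, "p"] == 1.0

    def test_row_permutation_invariance_and_topk(self, planted_study):
        matrix = planted_study["matrix"]
        promoters = planted_study["promoters"]
        fwd = chi2_rank_promoters(matrix, promoters, ["SD", "FFC/SD", "FFC"], top_k=50)
        rev = chi2_rank_promoters(matrix, promoters, ["FFC", "SD", "FFC/SD"], top_k=50)
        pd.testing.assert_frame_equal(fwd, rev)
        full = chi2_rank_promoters(matrix, promoters, top_k=10_000)
        assert len(full) <= len(promoters)


def test_cluster_promoters_linkage_shape(planted_study):
    levels = promoter_mean_table(
        planted_study["matrix"], planted_study["promoters"][:20]
    )
    Z = cluster_promoters(levels)
    assert Z.shape == (len(levels) - 1, 4)
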