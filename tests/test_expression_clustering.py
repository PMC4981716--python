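"""Expression filtering, standardization, clustering and eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from photoacclim import expression_clustering as ec
from photoacclim import synthetic_data as sd


def _matrix(values, genes=None, conditions=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    conditions = conditions or [f"c{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=conditions)


class TestFilterLowExpression:
    def test_gene_lowest_everywhere_removed(self):
        m = _matrix([[50, 60], [40, 45], [30, 35], [20, 25], [1, 2]],
                    genes=list("ABCDE"))
        filtered, removed = ec.filter_low_expression(m, 0.20, policy="all")
        assert removed == ["E"]
        assert list(filtered.index) == list("ABCD")

    def test_policy_all_vs_any(self):
        # gene E lowest in condition 1 but highest in condition 2
        m = _matrix([[50, 60], [40, 45], [30, 35], [20, 25], [1, 99]],
                    genes=list("ABCDE"))
        _, removed_all = ec.filter_low_expression(m, 0.21, policy="all")
        _, removed_any = ec.filter_low_expression(m, 0.21, policy="any")
        assert "E" not in removed_all
        assert "E" in removed_any

    def test_identical_genes_tie_break_deterministic(self):
        n, q = 10, 0.20
        m = _matrix(np.ones((n, 3)))
        for policy in ("all", "any"):
            _, removed = ec.filter_low_expression(m, q, policy=policy)
            assert len(removed) == int(np.floor(q * n))
            assert removed == ["g0", "g1"]  # lowest gene ids break the tie

    def test_invalid_quantile(self):
        m = _matrix(np.ones((4, 2)))
        with pytest.raises(ValueError):
            ec.filter_low_expression(m, 1.5)


class TestTransformStandardize:
    def test_two_point_zscore(self):
        # logged values [1, 3] standardize to [-1, 1] with population sd
        m = _matrix([[1.0, 7.0], [3.0, 1.0]])  # log2(x+1) = [1,3],[2,1]
        z, excluded = ec.transform_standardize(m, pseudocount=1.0)
        np.testing.assert_allclose(z.loc["g0"].values, [-1.0, 1.0],
                                   atol=1e-12)

    def test_constant_gene_excluded_and_reported(self):
        m = _matrix([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        z, excluded = ec.transform_standardize(m)
        assert excluded == ["g0"]
        assert list(z.index) == ["g1"]

    def test_output_moments(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.uniform(0, 100, size=(20, 6)))
        z, _ = ec.transform_standardize(m)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ValueError):
            ec.transform_standardize(_matrix([[-1.0, 2.0], [1.0, 2.0]]))


def _brute_force_average_linkage(X, k):
    """Hand-coded agglomerative average linkage for tiny inputs."""
    clusters = [[i] for i in range(len(X))]

    def dist(c1, c2):
        return np.mean([np.linalg.norm(X[i] - X[j])
                        for i in c1 for j in c2])

    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = dist(clusters[a], clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(X), dtype=int)
    for cid, members in enumerate(clusters):
        labels[members] = cid
    return labels


class TestClusterGenes:
    def test_two_well_separated_archetypes(self):
        cfg = sd.ExpressionSimConfig(n_genes=(30, 30, 1, 1),
                                     gene_noise_sd=0.1, seed=3)
        sim = sd.simulate_expression(cfg)
        keep = sim.true_labels.isin([1, 2])
        z, _ = ec.transform_standardize(sim.rpkm[keep])
        res = ec.cluster_genes(z, k=2)
        ari = adjusted_rand_score(sim.true_labels[z.index], res.labels)
        assert ari == 1.0

    def test_four_archetype_recovery(self):
        cfg = sd.ExpressionSimConfig(n_genes=(200, 200, 200, 200),
                                     gene_noise_sd=0.3, seed=5)
        sim = sd.simulate_expression(cfg)
        res, _ = ec.cluster_pipeline(sim.rpkm, k=4, n_major=None)
        ari = adjusted_rand_score(sim.true_labels[res.labels.index],
                                  res.labels)
        assert ari >= 0.95

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 5))
        m = _matrix(X)
        for k in (2, 3, 4):
            res = ec.cluster_genes(m, k)
            oracle = _brute_force_average_linkage(X, k)
            assert adjusted_rand_score(oracle, res.labels.values) == 1.0

    def test_duplicating_rows_preserves_assignments(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (5, 4)), rng.normal(5, 1, (5, 4))])
        m = _matrix(X)
        dup = pd.concat([m, m.set_axis([f"{g}_dup" for g in m.index])])
        res1 = ec.cluster_genes(m, 2)
        res2 = ec.cluster_genes(dup, 2)
        ari = adjusted_rand_score(res1.labels.values,
                                  res2.labels.loc[m.index].values)
        assert ari == 1.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(size=(12, 5)))
        res1 = ec.cluster_genes(m, 3)
        shuffled = m.sample(frac=1.0, random_state=0)
        res2 = ec.cluster_genes(shuffled, 3)
        assert (res2.labels.loc[m.index] == res1.labels).all()

    def test_k_validation(self):
        m = _matrix(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValueError):
            ec.cluster_genes(m, 1)
        with pytest.raises(ValueError):
            ec.cluster_genes(m, 5)


class TestEigengenes:
    def test_rank_one_cluster(self):
        p = np.array([1.0, 2.0, 3.0, 4.0])
        m = _matrix(np.vstack([p, p, p]))
        labels = pd.Series([1, 1, 1], index=m.index)
        eig, var = ec.compute_eigengenes(m, labels)
        np.testing.assert_allclose(np.abs(eig[1]), p / np.linalg.norm(p),
                                   atol=1e-12)
        assert var[1] == pytest.approx(1.0)

    def test_sign_convention_positive_vs_mean(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(30, 6)))
        labels = pd.Series(np.repeat([1, 2], 15), index=m.index)
        eig, _ = ec.compute_eigengenes(m, labels)
        for cid, idx in labels.groupby(labels).groups.items():
            mean = m.loc[idx].values.mean(axis=0)
            assert np.dot(eig[cid], mean) >= 0

    def test_planted_archetype_correlation(self, small_expression):
        sim = small_expression
        z, _ = ec.transform_standardize(sim.rpkm)
        eig, _ = ec.compute_eigengenes(z, sim.true_labels[z.index])
        for arch in range(4):
            r = np.corrcoef(eig[arch + 1], sim.archetypes[arch])[0, 1]
            assert abs(r) >= 0.95

    def test_scale_invariance_through_standardization(self, small_expression):
        # with no pseudocount the per-gene z-score absorbs any positive
        # scale factor exactly
        sim = small_expression
        rng = np.random.default_rng(0)
        scaled = sim.rpkm.mul(rng.uniform(0.5, 5.0, len(sim.rpkm)), axis=0)
        z1, _ = ec.transform_standardize(sim.rpkm, pseudocount=0.0)
        z2, _ = ec.transform_standardize(scaled, pseudocount=0.0)
        eig1, _ = ec.compute_eigengenes(z1, sim.true_labels[z1.index])
        eig2, _ = ec.compute_eigengenes(z2, sim.true_labels[z2.index])
        for cid in eig1:
            np.testing.assert_allclose(eig1[cid], eig2[cid], atol=1e-9)


class TestCorrelateEigengene:
    def test_proportional_and_antiproportional(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert ec.correlate_eigengene(2 * v, v) == pytest.approx(1.0)
        assert ec.correlate_eigengene(-v, v) == pytest.approx(-1.0)

    def test_orthogonal_pair(self):
        # Gram-Schmidt: remove the projection, correlation vanishes
        rng = np.random.default_rng(3)
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        a0 = a - a.mean()
        b_orth = b - (b - b.mean()) @ a0 / (a0 @ a0) * a0
        assert ec.correlate_eigengene(a, b_orth) == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            ec.correlate_eigengene(np.ones(4), np.arange(4.0))


class TestPipelineDeterminism:
    def test_fixed_input_identical_result(self, small_expression):
        sim = small_expression
        r1, _ = ec.cluster_pipeline(sim.rpkm, k=6)
        r2, _ = ec.cluster_pipeline(sim.rpkm.copy(), k=6)
        assert (r1.labels == r2.labels).all()
        for cid in r1.eigengenes:
            np.testing.assert_array_equal(r1.eigengenes[cid],
                                          r2.eigengenes[cid])

    def test_six_to_four_merge(self):
        cfg = sd.ExpressionSimConfig(n_genes=(60, 60, 60, 60),
                                     gene_noise_sd=0.3, seed=9)
        sim = sd.simulate_expression(cfg)
        res, rep = ec.cluster_pipeline(sim.rpkm, k=6, n_major=4)
        assert rep["k_initial"] == 6
        assert res.k <= 6
        ari = adjusted_rand_score(sim.true_labels[res.labels.index],
                                  res.labels)
        assert ari >= 0.95
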