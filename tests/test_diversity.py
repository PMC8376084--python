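import itertools
import math

import numpy as np
import pandas as pd
import pytest

from igcoat import diversity as div


class TestShannon:
    def test_uniform_is_log_k(self):
        assert div.shannon([10, 10, 10, 10]) == pytest.approx(math.log(4))

    def test_single_taxon_is_zero(self):
        assert div.shannon([7]) == 0.0

    def test_direct_formula(self):
        assert div.shannon([5, 3, 2]) == pytest.approx(1.0297, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            div.shannon([0, 0])

    def test_matches_scipy_entropy(self, rng):
        from scipy.stats import entropy

        for _ in range(10):
            c = rng.integers(1, 50, size=6)
            assert div.shannon(c) == pytest.approx(entropy(c / c.sum()))

    def test_uniform_maximizes_at_fixed_richness(self, rng):
        k = 5
        h_uniform = div.shannon(np.ones(k))
        for _ in range(50):
            c = rng.dirichlet(np.ones(k))
            assert div.shannon(c) <= h_uniform + 1e-12

    def test_base_conversion(self):
        assert div.shannon([1, 1], base=2) == pytest.approx(1.0)


class TestClr:
    def test_equal_counts_give_zeros(self):
        out = div.clr_transform(np.array([[5.0, 5.0, 5.0]]), 1.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_two_part_example(self):
        out = div.clr_transform(np.array([1.0, 10.0]), 1.0)
        expected = math.log(2.0 / math.sqrt(22.0))
        assert out[0] == pytest.approx(expected, abs=1e-10)
        assert out[1] == pytest.approx(-expected, abs=1e-10)

    def test_rows_sum_to_zero(self, rng):
        x = rng.integers(0, 100, size=(20, 8)).astype(float)
        out = div.clr_transform(x, 1.0)
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-10)

    def test_matches_skbio(self, rng):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        x = rng.integers(0, 30, size=(5, 4)).astype(float) + 1.0
        ours = div.clr_transform(x, pseudocount=1e-12)
        theirs = skbio_comp.clr(x)
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_invalid_pseudocount(self):
        with pytest.raises(ValueError):
            div.clr_transform(np.ones((2, 2)), 0.0)


class TestAitchison:
    def test_identical_samples_zero(self):
        x = np.array([[3, 4, 5], [3, 4, 5]], dtype=float)
        d = div.aitchison_distance(x)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_at_tiny_pseudocount(self):
        x = np.array([[10.0, 20.0, 30.0], [100.0, 200.0, 300.0]])
        d = div.aitchison_distance(x, pseudocount=1e-8)
        assert d.values[0, 1] < 1e-5

    def test_equals_euclidean_of_clr(self, rng):
        x = rng.integers(0, 50, size=(5, 4)).astype(float)
        d = div.aitchison_distance(x, pseudocount=1.0)
        clr = div.clr_transform(x, 1.0)
        for i, j in itertools.combinations(range(5), 2):
            expected = np.linalg.norm(clr[i] - clr[j])
            assert d.values[i, j] == pytest.approx(expected, abs=1e-12)


class TestBrayCurtis:
    def test_identical_zero(self):
        d = div.bray_curtis(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = div.bray_curtis(np.array([[5.0, 0.0], [0.0, 7.0]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_worked_example(self):
        d = div.bray_curtis(np.array([[6.0, 2.0], [2.0, 6.0]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_matches_scipy(self, rng):
        from scipy.spatial.distance import braycurtis

        x = rng.integers(0, 40, size=(6, 5)).astype(float)
        d = div.bray_curtis(x)
        for i, j in itertools.combinations(range(6), 2):
            assert d.values[i, j] == pytest.approx(braycurtis(x[i], x[j]))

    def test_range(self, rng):
        x = rng.integers(0, 40, size=(6, 5)).astype(float)
        d = div.bray_curtis(x)
        assert (d.values >= 0).all() and (d.values <= 1).all()


def brute_force_upgma_cophenetic(labels, dmat):
    """Greedy average linkage recomputing cluster distances from the
    original matrix (proportional averaging) — independent oracle."""
    clusters = {lab: [i] for i, lab in enumerate(labels)}
    coph = np.zeros_like(dmat)
    names = sorted(clusters)
    while len(names) > 1:
        best = None
        for a, b in itertools.combinations(names, 2):
            avg = np.mean([dmat[i, j] for i in clusters[a] for j in clusters[b]])
            key = (avg, a, b)
            if best is None or key < best:
                best = key
        avg, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = avg
        clusters[f"({a}+{b})"] = clusters.pop(a) + clusters.pop(b)
        names = sorted(clusters)
    return coph


class TestUpgma:
    def three_leaf(self):
        labels = ["A", "B", "C"]
        vals = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        return div.DistanceMatrix(labels, vals)

    def test_hand_computed_heights(self):
        tree = div.upgma(self.three_leaf())
        assert tree.height == pytest.approx(3.0)
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert inner.height == pytest.approx(1.0)
        assert sorted(inner.leaves()) == ["A", "B"]

    def test_two_leaves(self):
        d = div.DistanceMatrix(["x", "y"], np.array([[0.0, 5.0], [5.0, 0.0]]))
        tree = div.upgma(d)
        assert tree.height == pytest.approx(2.5)

    def test_newick_branch_lengths(self):
        nwk = div.upgma(self.three_leaf()).to_newick()
        assert nwk.endswith(";")
        assert "A:1" in nwk and "C:3" in nwk

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            n = 5
            x = rng.uniform(1, 10, size=(n, n))
            vals = (x + x.T) / 2
            np.fill_diagonal(vals, 0.0)
            labels = [f"L{i}" for i in range(n)]
            dm = div.DistanceMatrix(labels, vals)
            tree = div.upgma(dm)
            coph = div.cophenetic_matrix(tree, labels)
            oracle = brute_force_upgma_cophenetic(labels, vals)
            np.testing.assert_allclose(coph, oracle, atol=1e-10)

    def test_matches_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        n = 6
        x = rng.uniform(1, 10, size=(n, n))
        vals = (x + x.T) / 2
        np.fill_diagonal(vals, 0.0)
        labels = [f"L{i}" for i in range(n)]
        tree = div.upgma(div.DistanceMatrix(labels, vals))
        coph = div.cophenetic_matrix(tree, labels)
        z = linkage(squareform(vals), method="average")
        np.testing.assert_allclose(squareform(coph), cophenet(z), atol=1e-10)

    def test_ultrametric_inequality(self, rng):
        n = 7
        x = rng.uniform(1, 10, size=(n, n))
        vals = (x + x.T) / 2
        np.fill_diagonal(vals, 0.0)
        labels = [f"L{i}" for i in range(n)]
        coph = div.cophenetic_matrix(
            div.upgma(div.DistanceMatrix(labels, vals)), labels
        )
        for i, j, k in itertools.permutations(range(n), 3):
            assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-10

    def test_merge_heights_non_decreasing(self, rng):
        n = 6
        x = rng.uniform(1, 10, size=(n, n))
        vals = (x + x.T) / 2
        np.fill_diagonal(vals, 0.0)
        tree = div.upgma(div.DistanceMatrix([f"L{i}" for i in range(n)], vals))

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(tree)


def brute_force_permanova_p(dist, groups):
    """Exhaustive enumeration over all distinct label assignments."""
    n = dist.n
    idx = list(range(n))
    labels = list(groups)

    def f_stat(lab):
        lab = np.asarray(lab)
        return div.permanova(dist, lab, n_perm=1, seed=0)["pseudo_F"]

    f_obs = f_stat(labels)
    count = 0
    total = 0
    for perm in itertools.permutations(idx):
        lab = [labels[i] for i in perm]
        total += 1
        if f_stat(lab) >= f_obs - 1e-12:
            count += 1
    return count / total


class TestPermanova:
    def separated(self, per_group=3):
        rng = np.random.default_rng(99)
        a = np.vstack(
            [rng.normal(0.0, 0.05, size=(per_group, 2)),
             rng.normal(5.0, 0.05, size=(per_group, 2))]
        )
        d = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
        return div.DistanceMatrix([f"s{i}" for i in range(2 * per_group)], d)

    def test_exhaustive_enumeration_matches(self, rng):
        x = rng.uniform(0, 1, size=(6, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        dist = div.DistanceMatrix([f"s{i}" for i in range(6)], d)
        groups = ["a", "a", "a", "b", "b", "b"]
        exact_p = brute_force_permanova_p(dist, groups)
        # all 720 permutations as the permutation set reproduces the
        # exhaustive tail probability up to the (1 + x)/(1 + n) estimator
        res = div.permanova(dist, groups, n_perm=7200, seed=1)
        assert res["p_value"] == pytest.approx(exact_p, abs=0.02)

    def test_two_separated_clusters_minimal_p(self):
        # with 2 x 10 samples the chance a permutation rebuilds the exact
        # partition is ~1e-5, so the minimal achievable p is attained
        res = div.permanova(self.separated(per_group=12),
                            ["a"] * 12 + ["b"] * 12, n_perm=999, seed=0)
        assert res["p_value"] == pytest.approx(1.0 / 1000.0)
        assert res["R2"] > 0.95

    def test_r2_in_unit_interval(self, rng):
        x = rng.uniform(0, 1, size=(10, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        dist = div.DistanceMatrix([f"s{i}" for i in range(10)], d)
        res = div.permanova(dist, ["a"] * 5 + ["b"] * 5, n_perm=99, seed=2)
        assert 0.0 <= res["R2"] <= 1.0

    def test_matches_skbio_statistic(self, rng):
        skbio_dist = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        x = rng.uniform(0, 1, size=(9, 4))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        labels = [f"s{i}" for i in range(9)]
        groups = ["a"] * 4 + ["b"] * 5
        ours = div.permanova(div.DistanceMatrix(labels, d), groups,
                             n_perm=9, seed=0)
        theirs = sk_permanova(skbio_dist.DistanceMatrix(d, labels),
                              grouping=groups, permutations=9)
        assert ours["pseudo_F"] == pytest.approx(
            float(theirs["test statistic"]), rel=1e-9
        )

    def test_full_set_group_rejected(self):
        with pytest.raises(ValueError, match="full sample"):
            div.permanova(self.separated(), ["a"] * 6)

    def test_strata_restricts_permutations(self):
        dist = self.separated()
        res = div.permanova(dist, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=3,
                            strata=["x"] * 3 + ["y"] * 3)
        # within-stratum shuffling cannot move samples across groups
        assert res["p_value"] == pytest.approx(1.0)

    def test_seed_determinism(self, rng):
        x = rng.uniform(0, 1, size=(8, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        dist = div.DistanceMatrix([f"s{i}" for i in range(8)], d)
        g = ["a"] * 4 + ["b"] * 4
        r1 = div.permanova(dist, g, n_perm=199, seed=5)
        r2 = div.permanova(dist, g, n_perm=199, seed=5)
        assert r1 == r2


def shannon_frame(rng, n_dogs=8, shift=0.0, sigma_dog=0.0, noise=0.1):
    rows = []
    for d in range(n_dogs):
        u = rng.normal(0, sigma_dog)
        for stage in ("before", "after"):
            for ig in ("IgA", "IgG"):
                mu = 1.0 + (shift if stage == "after" else 0.0)
                rows.append(
                    {
                        "dog_id": f"d{d}",
                        "cohort": "healthy",
                        "stage": stage,
                        "ig_class": ig,
                        "shannon": math.exp(mu + u + rng.normal(0, noise)),
                    }
                )
    return pd.DataFrame(rows)


class TestShannonLmm:
    def test_zero_variance_limit_matches_ols(self, rng):
        df = shannon_frame(rng, sigma_dog=0.0)
        fit = div.fit_shannon_lmm(df)
        y = np.log(df["shannon"].to_numpy())
        X = fit.design.fixed
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.sigma_dog2 < 0.02
        np.testing.assert_allclose(fit.fixed_estimates, ols, atol=5e-3)

    def test_recovers_stage_shift(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(5):
            df = shannon_frame(rng, n_dogs=12, shift=0.5, sigma_dog=0.2)
            fit = div.fit_shannon_lmm(df)
            j = fit.design.term_names.index("stage[after]")
            se = math.sqrt(fit.fixed_cov[j, j])
            if abs(fit.fixed_estimates[j] - 0.5) < 3 * se:
                hits += 1
        assert hits >= 4

    def test_constant_response(self, rng):
        df = shannon_frame(rng, noise=0.0)
        df["shannon"] = math.exp(1.5)
        fit = div.fit_shannon_lmm(df)
        assert fit.sigma_resid2 == 0.0
        assert fit.fixed_estimates[0] == pytest.approx(1.5)

    def test_nonpositive_shannon_excluded_with_warning(self, rng):
        df = shannon_frame(rng)
        df.loc[0, "shannon"] = 0.0
        with pytest.warns(UserWarning, match="Shannon"):
            fit = div.fit_shannon_lmm(df)
        assert fit.n_excluded == 1


class TestLmmR2:
    def _fit(self, var_fixed, sigma_dog2, sigma_resid2):
        import dataclasses

        md = pd.DataFrame(
            {
                "dog_id": ["d1", "d2"] * 8,
                "cohort": "healthy",
                "stage": ["before", "after"] * 8,
                "ig_class": "IgA",
            }
        )
        from igcoat.design import build_design

        dm = build_design(md, ["ig_class", "cohort", "stage"])
        beta = np.array([-math.sqrt(var_fixed), 2 * math.sqrt(var_fixed)])
        return div.LmmFit(dm, beta, np.zeros((2, 2)), sigma_dog2,
                          sigma_resid2, 0.0, dm.fixed @ beta)

    def test_direct_formula(self):
        marg, cond = div.lmm_r2(self._fit(1.0, 1.0, 2.0))
        assert marg == pytest.approx(0.25)
        assert cond == pytest.approx(0.50)

    def test_zero_dog_variance_equalizes(self):
        marg, cond = div.lmm_r2(self._fit(1.0, 0.0, 2.0))
        assert marg == cond

    def test_null_fixed_effects(self):
        fit = self._fit(0.0, 1.0, 1.0)
        marg, _ = div.lmm_r2(fit)
        assert marg == pytest.approx(0.0)

    def test_monotone_in_informative_fixed_effect(self):
        rng = np.random.default_rng(13)
        df = shannon_frame(rng, n_dogs=10, shift=0.8, sigma_dog=0.2)
        fit_full = div.fit_shannon_lmm(df, factors=["ig_class", "stage"])
        fit_null = div.fit_shannon_lmm(df, factors=["ig_class"])
        assert div.lmm_r2(fit_full)[0] >= div.lmm_r2(fit_null)[0]


class TestMarginalMeans:
    def test_constant_data(self, rng):
        df = shannon_frame(rng, noise=0.0)
        df["shannon"] = math.exp(0.7)
        fit = div.fit_shannon_lmm(df)
        mm = div.marginal_means(fit, ["stage"])
        assert np.allclose(mm["estimate"], 0.7, atol=1e-9)

    def test_balanced_design_equals_group_means(self, rng):
        df = shannon_frame(rng, n_dogs=10, shift=0.5, sigma_dog=0.0)
        fit = div.fit_shannon_lmm(df)
        mm = div.marginal_means(fit, ["stage"]).set_index("stage")
        y = np.log(df["shannon"])
        for stage in ("before", "after"):
            raw = y[df["stage"] == stage].mean()
            assert mm.loc[stage, "estimate"] == pytest.approx(raw, abs=1e-2)

    def test_exponentiated_display(self, rng):
        df = shannon_frame(rng, noise=0.0)
        df["shannon"] = math.exp(0.7)
        fit = div.fit_shannon_lmm(df)
        mm = div.marginal_means(fit, ["stage"], exponentiate=True)
        assert np.allclose(mm["estimate"], math.exp(0.7), atol=1e-6)

    def test_unknown_factor_rejected(self, rng):
        df = shannon_frame(rng)
        fit = div.fit_shannon_lmm(df)
        with pytest.raises(KeyError):
            div.marginal_means(fit, ["nope"])


class TestDistanceMatrixIO:
    def test_round_trip(self, tmp_path, rng):
        x = rng.uniform(0, 1, size=(4, 3))
        d = div.aitchison_distance(x, [f"s{i}" for i in range(4)])
        path = tmp_path / "d.tsv"
        d.write_tsv(path)
        back = div.DistanceMatrix.read_tsv(path)
        assert back.labels == d.labels
        np.testing.assert_allclose(back.values, d.values, atol=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            div.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
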