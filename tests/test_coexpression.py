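"""Weight cut, soft power, TOM modules, eigengenes, traits, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from transtage import coexpression as coex


class TestWeightCut:
    def test_lognormal_mixture_separated(self):
        rng = np.random.default_rng(8)
        low = 10 ** rng.normal(-5, 0.3, 4000)
        high = 10 ** rng.normal(-2, 0.3, 1000)
        w = pd.Series(np.concatenate([low, high]))
        cut = coex.detect_weight_cut(w)
        assert not cut.unimodal_fallback
        predicted_high = (w > cut.threshold).values
        truth_high = np.arange(5000) >= 4000
        err = (predicted_high != truth_high).mean()
        assert err <= 0.02

    def test_manual_threshold_verbatim(self):
        w = pd.Series(np.linspace(0, 1, 200))
        cut = coex.detect_weight_cut(w, method="manual",
                                     manual_threshold=1.6e-4)
        assert cut.threshold == 1.6e-4 and cut.method == "manual"

    def test_unimodal_falls_back_with_flag(self):
        rng = np.random.default_rng(0)
        w = pd.Series(10 ** rng.normal(-3, 0.2, 1000))
        with pytest.warns(UserWarning, match="unimodal"):
            cut = coex.detect_weight_cut(w, manual_threshold=1e-4)
        assert cut.unimodal_fallback and cut.threshold == 1e-4

    def test_zero_pile_counts_as_mode(self):
        """Rows shrunk to exactly zero form the low mode at the floor."""
        rng = np.random.default_rng(1)
        w = pd.Series(np.concatenate([np.zeros(1500),
                                      10 ** rng.normal(-1, 0.3, 500)]))
        cut = coex.detect_weight_cut(w)
        assert not cut.unimodal_fallback
        assert 0 < cut.threshold < 10 ** -2.5

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            coex.detect_weight_cut(pd.Series(np.ones(500)))
        with pytest.raises(ValueError):
            coex.detect_weight_cut(pd.Series(np.linspace(0, 1, 50)))


class TestSelectIndexGenes:
    def test_simple_selection_ordered(self):
        w = pd.Series({"a": 0.9, "b": 0.5, "c": 1e-6})
        cut = coex.WeightCut(1e-4, "manual")
        assert coex.select_index_genes(w, cut) == ["a", "b"]

    def test_all_above(self):
        w = pd.Series({"a": 0.9, "b": 0.5})
        assert len(coex.select_index_genes(w, coex.WeightCut(0.1, "manual"))) == 2

    def test_empty_selection_rejected(self):
        w = pd.Series({"a": 0.001})
        with pytest.raises(ValueError):
            coex.select_index_genes(w, coex.WeightCut(0.5, "manual"))


def _block_data(n_blocks=2, block_size=40, n_null=20, n_samples=100,
                factor_sd=1.0, noise_sd=0.3, seed=0):
    """Expression with perfectly modular correlation blocks + null genes."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for b in range(n_blocks):
        f = rng.normal(0, factor_sd, n_samples)
        for _ in range(block_size):
            rows.append(f + rng.normal(0, noise_sd, n_samples))
            truth.append(b + 1)
    for _ in range(n_null):
        rows.append(rng.normal(0, 1.0, n_samples))
        truth.append(0)
    return np.asarray(rows), np.asarray(truth)


class TestSoftPower:
    def test_default_candidates_include_four(self):
        assert 4 in coex.CoexprConfig().candidate_powers
        assert coex.CoexprConfig().soft_power == 4

    def test_uniform_connectivity_warning_path(self):
        """A single-factor design has no scale-free tail (all genes share
        the same connectivity), so no candidate reaches the target."""
        rng = np.random.default_rng(2)
        f = rng.normal(size=100)
        X = f[None, :] + rng.normal(0, 0.01, size=(200, 100))
        with pytest.warns(UserWarning, match="scale-free"):
            beta, table = coex.pick_soft_power(X, candidates=(2, 4, 6),
                                               target_r2=0.8)
        assert beta in (2, 4, 6)
        assert (table["sft_r2"] < 0.8).all()

    def test_matches_independent_recompute(self):
        X, _ = _block_data(n_blocks=3, block_size=30, n_null=60)
        beta, table = coex.pick_soft_power(X, candidates=(1, 2, 4, 6),
                                           target_r2=0.8)
        # independent recomputation of the fit table
        cor = np.abs(np.corrcoef(X))
        np.fill_diagonal(cor, 0.0)
        for _, row in table.iterrows():
            k = (cor ** int(row["power"])).sum(axis=1)
            r2, slope = coex.scale_free_fit(k)
            assert row["sft_r2"] == pytest.approx(r2, abs=1e-12)
        reached = table[table["sft_r2"] >= 0.8]
        expected = int(reached["power"].iloc[0]) if len(reached) else \
            int(table.loc[table["sft_r2"].idxmax(), "power"])
        assert beta == expected

    def test_constant_gene_excluded(self):
        X, _ = _block_data()
        X[0] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            coex.pick_soft_power(X, candidates=(4,), target_r2=0.0)


class TestAdjacencyTOM:
    def test_adjacency_bounds_symmetry(self):
        X, _ = _block_data()
        A = coex.adjacency_matrix(X, 4)
        assert np.allclose(A, A.T)
        assert (A >= 0).all() and (A <= 1).all()
        assert not np.diag(A).any()

    def test_tom_bounds(self):
        X, _ = _block_data()
        T = coex.tom_similarity(coex.adjacency_matrix(X, 4))
        assert np.allclose(T, T.T)
        assert (T >= 0).all() and (T <= 1 + 1e-12).all()
        np.testing.assert_allclose(np.diag(T), 1.0)


class TestDetectModules:
    def test_planted_blocks_recovered_nulls_unassigned(self):
        X, truth = _block_data(n_blocks=2, block_size=40, n_null=20,
                               noise_sd=0.05)
        gene_ids = [f"g{i}" for i in range(len(truth))]
        assignment, Z = coex.detect_modules(X, gene_ids,
                                            coex.CoexprConfig())
        assigned = assignment[assignment != 0]
        ari = adjusted_rand_score(truth[truth > 0],
                                  assignment.values[truth > 0])
        assert ari == 1.0
        assert (assignment.values[truth == 0] == 0).all()

    def test_fewer_genes_than_min_size(self):
        X, truth = _block_data(n_blocks=1, block_size=15, n_null=10)
        with pytest.warns(UserWarning, match="unassigned"):
            assignment, _ = coex.detect_modules(
                X, [f"g{i}" for i in range(25)],
                coex.CoexprConfig(min_module_size=30))
        assert (assignment == 0).all()

    def test_labels_partition_and_size_ranked(self):
        X, truth = _block_data(n_blocks=3, block_size=35, n_null=15,
                               noise_sd=0.1)
        assignment, _ = coex.detect_modules(
            X, [f"g{i}" for i in range(len(truth))], coex.CoexprConfig())
        sizes = assignment[assignment > 0].value_counts()
        assert list(sizes.index) == sorted(sizes.index)  # 1 = largest
        assert sizes.is_monotonic_decreasing


class TestMergeAndEigengenes:
    def _module_expr(self, cors, n=200, seed=0):
        """Three 10-gene modules whose latent factors have given pairwise
        correlations with the first factor."""
        rng = np.random.default_rng(seed)
        f0 = rng.normal(size=n)
        rows, assignment = [], []
        for m, c in enumerate(cors, start=1):
            f = c * f0 + np.sqrt(1 - c ** 2) * rng.normal(size=n)
            for _ in range(10):
                rows.append(f + rng.normal(0, 0.05, n))
                assignment.append(m)
        X = np.asarray(rows)
        genes = [f"g{i}" for i in range(len(rows))]
        samples = [f"s{i}" for i in range(n)]
        return X, genes, samples, pd.Series(assignment, index=genes)

    def test_highly_correlated_modules_merge(self):
        X, genes, samples, assignment = self._module_expr([1.0, 0.95, 0.0])
        merged = coex.merge_close_modules(assignment, X, genes, samples,
                                          merge_height=0.35)
        assert merged.nunique() == 2
        assert merged.iloc[0] == merged.iloc[10]   # modules 1+2 merged
        assert merged.iloc[0] != merged.iloc[20]

    def test_distant_modules_kept(self):
        X, genes, samples, assignment = self._module_expr([1.0, 0.3, 0.0])
        merged = coex.merge_close_modules(assignment, X, genes, samples,
                                          merge_height=0.35)
        assert merged.nunique() == 3

    def test_chain_merges_transitively(self):
        """A chain r(1,2)=0.9, r(2,3)~0.75 collapses step by step; the
        result matches the exhaustive agglomeration oracle."""
        X, genes, samples, assignment = self._module_expr([1.0, 0.9, 0.72])
        merged = coex.merge_close_modules(assignment, X, genes, samples,
                                          merge_height=0.35)
        # oracle: greedy agglomeration recomputing eigengene correlations
        work = assignment.copy()
        while True:
            mods = sorted(set(work))
            if len(mods) < 2:
                break
            eigs, _ = coex.compute_eigengenes(work, X, genes, samples)
            cor = eigs.corr().to_numpy()
            np.fill_diagonal(cor, -np.inf)
            i, j = np.unravel_index(np.argmax(cor), cor.shape)
            if cor[i, j] < 0.65:
                break
            work[work == int(eigs.columns[j][1:])] = int(eigs.columns[i][1:])
        assert adjusted_rand_score(merged.values, work.values) == 1.0

    def test_single_gene_module_is_standardized_gene(self, rng):
        X = rng.normal(2, 3, size=(1, 60))
        assignment = pd.Series([1], index=["g0"])
        eigs, ve = coex.compute_eigengenes(assignment, X, ["g0"],
                                           [f"s{i}" for i in range(60)])
        z = (X[0] - X[0].mean()) / X[0].std(ddof=1)
        np.testing.assert_allclose(eigs["M1"], z, atol=1e-10)
        assert ve["M1"] == pytest.approx(1.0)

    def test_two_gene_equal_variance_closed_form(self, rng):
        a = rng.normal(size=80)
        b = 0.8 * a + 0.6 * rng.normal(size=80)
        X = np.vstack([a, b])
        assignment = pd.Series([1, 1], index=["g0", "g1"])
        eigs, _ = coex.compute_eigengenes(assignment, X, ["g0", "g1"],
                                          [f"s{i}" for i in range(80)])
        za = (a - a.mean()) / a.std(ddof=1)
        zb = (b - b.mean()) / b.std(ddof=1)
        avg = za + zb
        avg = (avg - avg.mean()) / avg.std(ddof=1)
        assert abs(np.corrcoef(eigs["M1"], avg)[0, 1]) > 1 - 1e-10

    def test_sign_alignment(self):
        X, truth = _block_data(n_blocks=2, block_size=20, n_null=0)
        genes = [f"g{i}" for i in range(len(truth))]
        samples = [f"s{i}" for i in range(X.shape[1])]
        assignment = pd.Series(truth, index=genes)
        eigs, _ = coex.compute_eigengenes(assignment, X, genes, samples)
        for m in eigs.columns:
            rows = [genes.index(g) for g in
                    assignment.index[assignment == int(m[1:])]]
            M = X[rows]
            Mz = (M - M.mean(1, keepdims=True)) / M.std(1, ddof=1,
                                                        keepdims=True)
            assert np.corrcoef(eigs[m], Mz.mean(0))[0, 1] >= 0


class TestModuleTrait:
    def test_identical_series_r_one(self, rng):
        n = 50
        e = pd.DataFrame({"M1": rng.normal(size=n)},
                         index=[f"s{i}" for i in range(n)])
        ph = pd.DataFrame({"trait": e["M1"]}, index=e.index)
        out = coex.module_trait(e, ph, ["trait"])
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-30

    def test_matches_pearson_oracle(self, rng):
        n = 60
        e = pd.DataFrame({"M1": rng.normal(size=n),
                          "M2": rng.normal(size=n)},
                         index=[f"s{i}" for i in range(n)])
        ph = pd.DataFrame({"t1": rng.normal(size=n),
                           "t2": rng.normal(size=n)}, index=e.index)
        out = coex.module_trait(e, ph, ["t1", "t2"]).set_index(
            ["module", "trait"])
        for m in ("M1", "M2"):
            for t in ("t1", "t2"):
                r, p = stats.pearsonr(e[m], ph[t])
                assert out.loc[(m, t), "r"] == pytest.approx(r, abs=1e-12)
                assert out.loc[(m, t), "p"] == pytest.approx(p, abs=1e-12)

    def test_constant_trait_recorded_missing(self, rng):
        e = pd.DataFrame({"M1": rng.normal(size=20)},
                         index=[f"s{i}" for i in range(20)])
        ph = pd.DataFrame({"flat": np.ones(20)}, index=e.index)
        out = coex.module_trait(e, ph, ["flat"])
        assert np.isnan(out["r"].iloc[0])


class TestFisherEnrichment:
    def test_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(3)
        background = [f"g{i}" for i in range(1000)]
        for _ in range(50):
            mod = list(rng.choice(background, size=rng.integers(20, 80),
                                  replace=False))
            ref = list(rng.choice(background, size=rng.integers(50, 200),
                                  replace=False))
            out = coex.fisher_enrichment({"m": mod}, {"s": ref}, background)
            k = out["overlap"].iloc[0]
            oracle = stats.hypergeom.sf(k - 1, 1000, len(ref), len(mod))
            assert out["p"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_zero_overlap_p_one(self):
        background = [f"g{i}" for i in range(100)]
        out = coex.fisher_enrichment({"m": background[:10]},
                                     {"s": background[90:]}, background)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_capped_at_one(self):
        background = [f"g{i}" for i in range(100)]
        sets = {f"s{j}": background[50:] for j in range(10)}
        out = coex.fisher_enrichment({"m": background[:10]}, sets,
                                     background)
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_module_outside_background_rejected(self):
        with pytest.raises(ValueError):
            coex.fisher_enrichment({"m": ["x"]}, {"s": ["g1"]}, ["g1", "g2"])


class TestGMT:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg9\n")
        sets = coex.read_gmt(p)
        assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g9"]}
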