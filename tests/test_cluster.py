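"""Consensus clustering mechanics, k selection, chi-square enrichment,
and Ward heatmap clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from mirtyper.cluster import (
    chi2_enrichment,
    consensus_cluster,
    select_k,
    ward_cluster,
)
from mirtyper.datasets import cohort_table


class TestConsensus:
    def test_two_tight_pairs_give_block_consensus(self):
        """With p_item=1 the subsampling is deterministic, so the
        consensus matrix equals the co-clustering indicator of plain
        hierarchical clustering — hand-computable for two tight pairs."""
        base = np.random.default_rng(2).normal(size=12)
        X = pd.DataFrame({
            "a1": base + 0.01, "a2": base + 0.02,
            "b1": -base + 0.01, "b2": -base - 0.02,
        })
        res = consensus_cluster(X, max_k=3, reps=2, p_item=1.0, seed=0)
        M = res.consensus[2]
        assert M.loc["a1", "a2"] == 1.0 and M.loc["b1", "b2"] == 1.0
        assert M.loc["a1", "b1"] == 0.0 and M.loc["a2", "b2"] == 0.0
        assert np.allclose(M, M.T) and np.all(np.diag(M) == 1.0)

    def test_identical_samples_full_consensus_at_k2(self):
        col = np.random.default_rng(3).normal(size=15)
        X = pd.DataFrame({f"s{i}": col for i in range(8)})
        res = consensus_cluster(X, max_k=2, reps=10, p_item=0.8, seed=1)
        M = res.consensus[2].to_numpy()
        assert np.all(M[~np.isnan(M)] == 1.0)

    def test_entries_bounded_and_symmetric(self, planted_clusters):
        X, _ = planted_clusters
        res = consensus_cluster(X, max_k=4, reps=30, seed=5)
        for k, M in res.consensus.items():
            arr = M.to_numpy()
            finite = arr[~np.isnan(arr)]
            assert ((finite >= 0) & (finite <= 1)).all()
            assert np.allclose(arr, arr.T, equal_nan=True)

    def test_seed_reproducibility(self, planted_clusters):
        X, _ = planted_clusters
        a = consensus_cluster(X, max_k=4, reps=20, seed=42)
        b = consensus_cluster(X, max_k=4, reps=20, seed=42)
        for k in a.consensus:
            pd.testing.assert_frame_equal(a.consensus[k], b.consensus[k])
            pd.testing.assert_series_equal(a.labels[k], b.labels[k])
        assert a.areas == b.areas

    def test_permutation_equivariance_with_full_sampling(self):
        gen = np.random.default_rng(9)
        X = pd.DataFrame(gen.normal(size=(25, 10)),
                         columns=[f"s{i}" for i in range(10)])
        perm = list(gen.permutation(X.columns))
        a = consensus_cluster(X, max_k=3, reps=3, p_item=1.0, seed=1)
        b = consensus_cluster(X[perm], max_k=3, reps=3, p_item=1.0, seed=1)
        pd.testing.assert_frame_equal(
            a.consensus[3].loc[perm, perm], b.consensus[3]
        )

    def test_item_consensus_matches_direct_definition(self, planted_clusters):
        X, _ = planted_clusters
        res = consensus_cluster(X, max_k=3, reps=30, seed=7)
        k = 3
        M = res.consensus[k]
        lab = res.labels[k]
        for sid in X.columns:
            own = [s for s in X.columns if lab[s] == lab[sid] and s != sid]
            expected = M.loc[sid, own].mean() if own else 1.0
            assert res.item_consensus[k][sid] == pytest.approx(expected)

    def test_constant_sample_rejected_by_name(self):
        X = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0],
                          "ok2": [0.0, 5.0, 1.0], "ok3": [2.0, 1.0, 0.0],
                          "ok4": [1.0, 0.0, 2.0]})
        with pytest.raises(ValueError, match="flat"):
            consensus_cluster(X, max_k=3, reps=2)

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ValueError):
            consensus_cluster(X, max_k=6)


class TestSelectK:
    def test_threshold_arithmetic_on_artificial_deltas(self):
        # gains at k=3..6: large gain up to 3, negligible beyond
        assert select_k({3: 1.0, 4: 0.05, 5: 0.04, 6: 0.03}) == 3

    def test_planted_three_clusters_selected(self, planted_clusters):
        X, truth = planted_clusters
        res = consensus_cluster(X, max_k=6, reps=100, seed=13)
        k = select_k(res)
        assert k == 3
        assert adjusted_rand_score(truth, res.labels[k]) == 1.0

    def test_single_cluster_flagged_low_confidence(self, caplog):
        gen = np.random.default_rng(7)
        center = gen.normal(0, 6, 40)
        X = pd.DataFrame({f"s{i}": center + gen.normal(0, 1, 40)
                          for i in range(24)})
        res = consensus_cluster(X, max_k=6, reps=100, seed=9)
        with caplog.at_level("WARNING"):
            k = select_k(res)
        assert k == 2
        assert "low-confidence" in caplog.text


class TestChi2Enrichment:
    def test_perfect_2x2_association_closed_form(self):
        a = pd.Series([1] * 10 + [2] * 10)
        b = pd.Series(["x"] * 10 + ["y"] * 10)
        stat, dof, p, _ = chi2_enrichment(a, b)
        assert stat == pytest.approx(20.0)
        assert dof == 1
        assert p < 1e-4

    def test_independent_labels_give_uniformish_p(self):
        gen = np.random.default_rng(21)
        ps = []
        for _ in range(200):
            a = pd.Series(gen.integers(0, 2, 60))
            b = pd.Series(gen.integers(0, 3, 60))
            ps.append(chi2_enrichment(a, b)[2])
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= frac <= 0.12

    def test_cohort_table_subtype_by_er_is_finite(self):
        """The printed receptor-status table, expanded to per-patient
        rows and aggregated subtype x ER, yields a finite chi-square."""
        t = cohort_table()
        rows = t.loc[t.index.repeat(t["n"])]
        stat, dof, p, expected = chi2_enrichment(
            rows["subtype"], rows["ER"]
        )
        assert np.isfinite(stat) and np.isfinite(p)
        assert dof == 3
        assert expected.to_numpy().sum() == pytest.approx(t["n"].sum())

    def test_degenerate_factor_rejected(self):
        with pytest.raises(ValueError):
            chi2_enrichment(pd.Series([1, 1, 1]), pd.Series(["a", "b", "a"]))


def _lance_williams_ward(X):
    """Naive Ward agglomeration via the distance-update recurrence."""
    n = X.shape[0]
    d = squareform(pdist(X))
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    nxt = n
    dmat = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}

    def get(i, j):
        return dmat[(min(i, j), max(i, j))]

    while len(active) > 1:
        pair = min(
            ((i, j) for i in active for j in active if i < j),
            key=lambda ij: (get(*ij), ij),
        )
        i, j = pair
        h = get(i, j)
        merges.append(h)
        ni, nj = sizes[i], sizes[j]
        for k in active - {i, j}:
            nk = sizes[k]
            dik, djk, dij = get(i, k), get(j, k), h
            new = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            dmat[(min(nxt, k), max(nxt, k))] = new
        sizes[nxt] = ni + nj
        active -= {i, j}
        active.add(nxt)
        nxt += 1
    return np.array(merges)


class TestWardCluster:
    def test_duplicate_columns_merge_first_at_zero_height(self):
        gen = np.random.default_rng(4)
        X = pd.DataFrame(gen.normal(size=(10, 5)),
                         columns=list("abcde"))
        X["e"] = X["a"]
        res = ward_cluster(X, cut_cols=2)
        first = res.col_linkage[0]
        assert first[2] == pytest.approx(0.0)
        merged = {int(first[0]), int(first[1])}
        assert merged == {0, 4}  # columns a and e

    def test_planted_groups_recovered_at_cut(self):
        gen = np.random.default_rng(6)
        centers = gen.normal(0, 6, (20, 3))
        cols = {f"g{c}_{j}": centers[:, c] + gen.normal(0, 1, 20)
                for c in range(3) for j in range(6)}
        X = pd.DataFrame(cols)
        res = ward_cluster(X, cut_cols=3)
        truth = [name.split("_")[0] for name in X.columns]
        assert adjusted_rand_score(truth, res.col_labels) == 1.0

    def test_merge_heights_match_lance_williams_recurrence(self):
        gen = np.random.default_rng(8)
        X = pd.DataFrame(gen.normal(size=(7, 4)))
        res = ward_cluster(X, cut_rows=2)
        brute = _lance_williams_ward(X.to_numpy())
        assert np.allclose(np.sort(res.row_linkage[:, 2]), np.sort(brute),
                           atol=1e-8)

    def test_na_entries_rejected(self):
        X = pd.DataFrame([[1.0, np.nan], [0.0, 2.0]])
        with pytest.raises(ValueError):
            ward_cluster(X)
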