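"""Ward.D2 clustering, Newick export and PCA of frequency profiles."""
import io

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from sirscan.errors import ValidationError
from sirscan.multivariate import (Dendrogram, pca, profile_matrix, to_newick,
                                  ward_cluster, PROFILE_COLUMNS)
from sirscan.stats import LengthProfile

from oracles import ward_d2_merges


def _matrix(rows, labels=None):
    rows = np.asarray(rows, dtype=float)
    labels = labels or [f"r{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=labels)


def test_identical_rows_merge_at_zero():
    d = ward_cluster(_matrix([[1.0, 2.0], [1.0, 2.0]]))
    assert len(d.merges) == 1
    assert d.merges[0][2] == pytest.approx(0.0)


def test_separated_duplicates():
    d = ward_cluster(_matrix([[0, 0], [0, 0], [10, 10], [10, 10]]))
    heights = [h for _, _, h in d.merges]
    assert heights[0] == pytest.approx(0.0)
    assert heights[1] == pytest.approx(0.0)
    assert heights[2] > 0


def test_requires_two_rows():
    with pytest.raises(ValidationError):
        ward_cluster(_matrix([[1, 2]]))


def test_ward_heights_match_lance_williams_oracle():
    rng = np.random.default_rng(31)
    x = rng.normal(size=(6, 4))
    d = ward_cluster(_matrix(x))
    expected = ward_d2_merges(x)
    np.testing.assert_allclose(sorted(h for _, _, h in d.merges),
                               sorted(h for _, _, h in expected),
                               rtol=1e-10)
    # merge partitions agree, not only the heights
    def partitions(merges, resolve):
        return {frozenset(resolve(m)) for m in merges}
    n = 6
    members = {i: frozenset([i]) for i in range(n)}
    got = set()
    for k, (a, b, _) in enumerate(d.merges):
        members[n + k] = members[a] | members[b]
        got.add(members[n + k])
    exp = {a | b for a, b, _ in expected}
    assert got == exp


def test_leaf_permutation_invariance():
    rng = np.random.default_rng(77)
    x = rng.normal(size=(7, 5))
    d1 = ward_cluster(_matrix(x))
    perm = rng.permutation(7)
    d2 = ward_cluster(_matrix(x[perm]))
    h1 = sorted(round(h, 9) for _, _, h in d1.merges)
    h2 = sorted(round(h, 9) for _, _, h in d2.merges)
    assert h1 == h2


def test_two_separated_clusters_recovered_as_top_split():
    rng = np.random.default_rng(8)
    a = rng.normal(size=(5, 3)) * 0.1
    b = rng.normal(size=(5, 3)) * 0.1 + 100.0
    labels = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    d = ward_cluster(_matrix(np.vstack([a, b]), labels))
    n = 10
    members = {i: frozenset([i]) for i in range(n)}
    for k, (l, r, _) in enumerate(d.merges):
        members[n + k] = members[l] | members[r]
    left, right, _ = d.merges[-1]
    split = {frozenset(d.leaves[i] for i in members[left]),
             frozenset(d.leaves[i] for i in members[right])}
    assert split == {frozenset(labels[:5]), frozenset(labels[5:])}


def test_newick_two_leaves_and_single_leaf():
    d = Dendrogram(leaves=("A", "B"), merges=((0, 1, 3.0),))
    assert to_newick(d) == "(A:1.5,B:1.5);"
    assert to_newick(Dendrogram(leaves=("A",), merges=())) == "A;"


def test_newick_round_trip_topology():
    rng = np.random.default_rng(12)
    x = rng.normal(size=(6, 3))
    labels = list("abcdef")
    d = ward_cluster(_matrix(x, labels))
    tree = Phylo.read(io.StringIO(to_newick(d)), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == labels
    # clades mirror the merge structure
    n = 6
    members = {i: frozenset([labels[i]]) for i in range(n)}
    expected_clades = set()
    for k, (a, b, _) in enumerate(d.merges):
        members[n + k] = members[a] | members[b]
        expected_clades.add(members[n + k])
    got = {frozenset(t.name for t in c.get_terminals())
           for c in tree.get_nonterminals()}
    assert got == expected_clades


def test_profile_matrix_layout():
    p = LengthProfile("g1", {6: 2, 31: 1}, seq_bp=1000)
    m = profile_matrix([p])
    assert list(m.columns) == list(PROFILE_COLUMNS)
    assert m.loc["g1", "6"] == pytest.approx(2.0)
    assert m.loc["g1", ">30"] == pytest.approx(1.0)
    assert m.loc["g1", "8+"] == pytest.approx(1.0)  # only the 31-mer
    assert not m.isna().any().any()


def test_pca_collinear_rows_single_component():
    m = _matrix([[1, 2, 3], [2, 4, 6], [3, 6, 9], [5, 10, 15]])
    res = pca(m, scale=False)
    assert res.explained_ratio[0] == pytest.approx(1.0)


def test_pca_variance_conservation():
    rng = np.random.default_rng(33)
    m = _matrix(rng.normal(size=(20, 8)))
    res = pca(m)
    # unit-scaled columns each carry variance 1 → total 8
    assert res.explained_variance.sum() == pytest.approx(8.0)
    assert np.all(np.diff(res.explained_variance) <= 1e-12)


def test_pca_scores_match_eigendecomposition():
    rng = np.random.default_rng(33)
    m = _matrix(rng.normal(size=(20, 8)))
    res = pca(m, scale=False)
    x = m.to_numpy() - m.to_numpy().mean(axis=0)
    evals, evecs = np.linalg.eigh(np.cov(x, rowvar=False))
    order = np.argsort(evals)[::-1]
    np.testing.assert_allclose(res.explained_variance, evals[order][:8],
                               rtol=1e-9)
    got = np.abs(res.scores.to_numpy())
    exp = np.abs(x @ evecs[:, order])
    np.testing.assert_allclose(got, exp[:, :got.shape[1]], atol=1e-9)


def test_pca_loadings_orthonormal_and_sign_fixed():
    rng = np.random.default_rng(4)
    m = _matrix(rng.normal(size=(10, 5)))
    res = pca(m)
    L = res.loadings.to_numpy()
    np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
    for j in range(L.shape[1]):
        assert L[np.argmax(np.abs(L[:, j])), j] > 0


def test_pca_degenerate_matrix_errors():
    with pytest.raises(ValidationError):
        pca(_matrix([[1, 1], [1, 1], [1, 1]]))
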