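"""Pearson correlation, significance, and Ward clustering against oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from frailmark import (
    SyntheticConfig,
    cluster_markers,
    correlation_matrix,
    generate_cohort,
    pearson_p,
    pearson_r,
    ward_cluster,
)
from frailmark.simulate import block_correlation


# ---------------------------------------------------------------- pearson


def test_pearson_exact_linearity():
    assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)


def test_pearson_matches_covariance_formula():
    x = np.array([1, 2, 3, 4, 5.0])
    y = np.array([2, 1, 4, 3, 5.0])
    num = np.sum((x - x.mean()) * (y - y.mean()))
    den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    assert pearson_r(x, y) == pytest.approx(num / den, rel=1e-12)


def test_pearson_affine_invariance(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    r = pearson_r(x, y)
    assert pearson_r(3 * x + 7, y) == pytest.approx(r, rel=1e-10)
    assert pearson_r(-2 * x + 1, y) == pytest.approx(-r, rel=1e-10)


def test_pearson_errors():
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson_p(0.5, 2)


def test_pearson_p_limits_and_oracle():
    assert pearson_p(0.0, 30) == pytest.approx(1.0)
    assert pearson_p(1.0, 10) == 0.0
    t = 0.5 * np.sqrt(18) / np.sqrt(1 - 0.25)
    assert t == pytest.approx(2.449, abs=1e-3)
    assert pearson_p(0.5, 20) == pytest.approx(2 * stats.t.sf(t, 18), rel=1e-12)


def test_pearson_p_matches_scipy(rng):
    x, y = rng.normal(size=27), rng.normal(size=27)
    r = pearson_r(x, y)
    assert pearson_p(r, 27) == pytest.approx(stats.pearsonr(x, y).pvalue, rel=1e-9)


# ---------------------------------------------------------------- correlation_matrix


def test_correlation_matrix_null_structure():
    cfg = SyntheticConfig(
        n_pfs=500,
        n_control=500,
        corr_pfs=np.eye(10),
        corr_control=np.eye(10),
        effect={m: 0.0 for m in SyntheticConfig().marker_names},
    )
    t = generate_cohort(cfg, seed=8)
    res = correlation_matrix(t, "PFS")
    off = res.r[~np.eye(10, dtype=bool)]
    assert np.max(np.abs(off)) < 0.2
    assert np.allclose(res.r, res.r.T)
    assert np.allclose(np.diag(res.r), 1.0)


def test_correlation_matrix_duplicate_column(default_cohort):
    t = default_cohort
    t2 = t.subset_markers([0, 1, 2])
    t2.markers[:, 2] = t2.markers[:, 0]
    res = correlation_matrix(t2, "PFS")
    assert res.r[0, 2] == pytest.approx(1.0)
    assert res.sig_mask[0, 2]


def test_correlation_matrix_planted_block_detected():
    blocks = block_correlation(10, [[0, 1, 2, 3]], 0.8)
    cfg = SyntheticConfig(n_pfs=22, n_control=27, corr_pfs=blocks, corr_control=blocks)
    t = generate_cohort(cfg, seed=4)
    res = correlation_matrix(t, "CONTROL")  # n=27 as in the study's control group
    for i, j in itertools.combinations(range(4), 2):
        assert res.sig_mask[i, j]


def test_correlation_matrix_subject_order_invariance(default_cohort):
    res1 = correlation_matrix(default_cohort, "PFS")
    rng = np.random.default_rng(0)
    perm = rng.permutation(default_cohort.n_subjects)
    import dataclasses

    shuffled = dataclasses.replace(
        default_cohort,
        **{
            f: getattr(default_cohort, f)[perm]
            for f in ("subject_id", "group", "age", "sex", "bmi", "sppb", "alm",
                      "alm_bmi", "n_diseases", "n_medications", "markers")
        },
    )
    res2 = correlation_matrix(shuffled, "PFS")
    assert np.allclose(res1.r, res2.r, atol=1e-12)


def test_correlation_matrix_unknown_group(default_cohort):
    with pytest.raises(ValueError, match="unknown group"):
        correlation_matrix(default_cohort, "OTHER")


# ---------------------------------------------------------------- Ward


def brute_force_ward(points):
    """Greedy Ward by direct evaluation of every candidate merge's increase
    in total within-cluster sum of squares."""
    clusters = [[i] for i in range(len(points))]
    ids = list(range(len(points)))
    nxt = len(points)
    merges = []

    def sse(idx):
        P = points[idx]
        return float(((P - P.mean(axis=0)) ** 2).sum())

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            inc = sse(clusters[a] + clusters[b]) - sse(clusters[a]) - sse(clusters[b])
            key = (inc, ids[a], ids[b])
            if best is None or key < best[0]:
                best = (key, a, b)
        (inc, ia, ib), a, b = best
        merges.append((ia, ib, inc))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [
            clusters[a] + clusters[b]
        ]
        ids = [x for i, x in enumerate(ids) if i not in (a, b)] + [nxt]
        nxt += 1
    return merges


@pytest.mark.parametrize("seed", range(25))
def test_ward_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((5, 3))
    D = squareform(pdist(pts))
    mine = ward_cluster(D).merges
    oracle = brute_force_ward(pts)
    for (a1, b1, h1), (a2, b2, h2) in zip(mine, oracle):
        assert {a1, b1} == {a2, b2}
        # recorded height is the Ward criterion = 2x the SSE increase
        assert h1 == pytest.approx(2 * h2, rel=1e-9)


def test_ward_matches_scipy_heights(rng):
    pts = rng.standard_normal((8, 4))
    Z = linkage(pdist(pts), method="ward")
    mine = ward_cluster(squareform(pdist(pts)))
    assert np.allclose(np.sort(mine.heights), np.sort(Z[:, 2] ** 2), rtol=1e-9)


def test_ward_identical_items_merge_first():
    D = np.array([[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 1], [5, 5, 1, 0.0]])
    dend = ward_cluster(D)
    a, b, h = dend.merges[0]
    assert {a, b} == {0, 1} and h == 0.0


def test_ward_two_far_pairs_recovered():
    pts = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
    dend = ward_cluster(squareform(pdist(pts)))
    labels = dend.cut(2)
    assert labels[0] == labels[1] and labels[2] == labels[3]
    assert labels[0] != labels[2]


def test_ward_heights_monotone_on_correlation_input(default_cohort):
    corr = correlation_matrix(default_cohort, "CONTROL")
    dend, order, reordered, labels = cluster_markers(corr)
    h = dend.heights
    assert np.all(np.diff(h) >= -1e-10)
    assert sorted(order) == list(range(10))
    assert reordered.shape == (10, 10)


def test_ward_input_validation():
    with pytest.raises(ValueError):
        ward_cluster(np.array([[0, 1], [2, 0.0]]))  # asymmetric
    with pytest.raises(ValueError):
        ward_cluster(np.array([[0, -1], [-1, 0.0]]))  # negative


# ---------------------------------------------------------------- cluster_markers


def test_planted_two_block_structure_recovered():
    blocks = block_correlation(10, [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]], 0.7)
    cfg = SyntheticConfig(n_pfs=200, n_control=200, corr_pfs=blocks, corr_control=blocks)
    t = generate_cohort(cfg, seed=6)
    corr = correlation_matrix(t, "PFS")
    _, _, _, labels = cluster_markers(corr)
    assert len(set(labels[:5])) == 1
    assert len(set(labels[5:])) == 1
    assert labels[0] != labels[5]


def test_identity_correlation_heights_near_one():
    r = np.eye(6)
    diss = 1.0 - r
    np.fill_diagonal(diss, 0.0)
    dend = ward_cluster(diss)
    assert np.allclose(dend.heights, 1.0)


def test_perfect_pair_merges_first():
    r = np.eye(5)
    r[1, 3] = r[3, 1] = 1.0
    diss = 1 - r
    np.fill_diagonal(diss, 0)
    dend = ward_cluster(diss)
    a, b, h = dend.merges[0]
    assert {a, b} == {1, 3} and h == 0.0


def test_newick_export_well_formed(default_cohort):
    corr = correlation_matrix(default_cohort, "PFS")
    dend, *_ = cluster_markers(corr)
    nwk = dend.to_newick(list(corr.marker_names))
    assert nwk.endswith(";") and nwk.count("(") == 9
    for name in corr.marker_names:
        assert name in nwk
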