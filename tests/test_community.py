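"""Unit tests for dissimilarity, ordination, and PERMANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from symcomm import community
from symcomm.community import (
    bray_curtis,
    group_mean_dissimilarity,
    nmds,
    permanova,
    sqrt_relative,
    stress1,
    taxa_scores,
)


def frame(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids)


# ---------------------------------------------------------------------------
# transform


def test_sqrt_relative_hand_values():
    out = sqrt_relative(frame([[25, 75]]))
    assert out.iloc[0, 0] == pytest.approx(0.5, abs=1e-4)
    assert out.iloc[0, 1] == pytest.approx(0.8660, abs=1e-4)


def test_sqrt_relative_unit_row_and_normalization():
    out = sqrt_relative(frame([[1, 0, 0], [3, 5, 9]]))
    assert list(out.iloc[0]) == [1, 0, 0]
    assert np.allclose((out ** 2).sum(axis=1), 1.0)


def test_sqrt_relative_drops_zero_sum_rows():
    out = sqrt_relative(frame([[1, 1], [0, 0]]))
    assert len(out) == 1


# ---------------------------------------------------------------------------
# Bray-Curtis


def test_bray_curtis_identical_and_disjoint():
    dm = bray_curtis(frame([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
    assert dm[0, 1] == 0.0
    assert dm[0, 2] == 1.0


def test_bray_curtis_hand_value():
    dm = bray_curtis(frame([[0.5, 0.8660], [0.8660, 0.5]]))
    assert dm[0, 1] == pytest.approx(0.2679, abs=1e-4)


def test_bray_curtis_two_zero_rows_error():
    with pytest.raises(ValueError):
        bray_curtis(frame([[0.0, 0.0], [0.0, 0.0]]))


def test_bray_curtis_matches_definition_oracle():
    rng = np.random.default_rng(0)
    x = rng.random((6, 5))
    dm = bray_curtis(frame(x))
    for i in range(6):
        for j in range(6):
            want = (np.abs(x[i] - x[j]).sum() / (x[i] + x[j]).sum())
            assert dm[i, j] == pytest.approx(want, abs=1e-12)
    assert (dm.data <= 1.0 + 1e-12).all() and (dm.data >= 0).all()


# ---------------------------------------------------------------------------
# group means


def ids_of(n):
    return [f"s{i}" for i in range(n)]


def test_group_means_constant_matrix():
    n = 6
    d = 0.4 * (np.ones((n, n)) - np.eye(n))
    g = group_mean_dissimilarity(
        DistanceMatrix(d, ids=ids_of(n)),
        pd.Series(["a", "a", "a", "b", "b", "b"], index=ids_of(n)))
    assert (g.overall, g.within, g.between) == (
        pytest.approx(0.4), pytest.approx(0.4), pytest.approx(0.4))


def test_group_means_two_plus_two_enumeration():
    # within pairs at 0, the four cross pairs at 1: overall = 4/6
    d = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]],
                 float)
    g = group_mean_dissimilarity(
        DistanceMatrix(d, ids=ids_of(4)),
        pd.Series(["a", "a", "b", "b"], index=ids_of(4)))
    assert g.overall == pytest.approx(4 / 6)
    assert g.within == pytest.approx(0.0)
    assert g.between == pytest.approx(1.0)


def test_group_means_single_group_has_no_between():
    d = np.array([[0, 0.5], [0.5, 0]])
    g = group_mean_dissimilarity(DistanceMatrix(d, ids=ids_of(2)),
                                 pd.Series(["a", "a"], index=ids_of(2)))
    assert g.between is None


def test_overall_is_not_mean_of_within_and_between():
    # unbalanced groups: overall is a pair-count weighted quantity,
    # generally not the average of the within and between means
    n = 5
    groups = pd.Series(["a", "a", "b", "b", "b"], index=ids_of(n))
    d = np.full((n, n), 0.9)
    d[0, 1] = d[1, 0] = 0.1
    for i, j in [(2, 3), (2, 4), (3, 4)]:
        d[i, j] = d[j, i] = 0.3
    np.fill_diagonal(d, 0.0)
    g = group_mean_dissimilarity(DistanceMatrix(d, ids=ids_of(n)), groups)
    assert g.overall == pytest.approx((0.1 + 3 * 0.3 + 6 * 0.9) / 10)
    assert g.within == pytest.approx(0.25)
    assert g.between == pytest.approx(0.9)
    assert abs(g.overall - (g.within + g.between) / 2) > 0.05


# ---------------------------------------------------------------------------
# PERMANOVA


def oracle_oneway_F(d2, groups):
    """Pseudo-F from the distance-based definition: total and within
    sums of squared dissimilarities (McArdle & Anderson identity)."""
    n = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    levels = sorted(set(groups))
    for lev in levels:
        idx = [i for i, g in enumerate(groups) if g == lev]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df1, df2 = len(levels) - 1, n - len(levels)
    return (ss_among / df1) / (ss_within / df2)


def test_permanova_constant_matrix_R2():
    n, g = 9, 3
    d = np.ones((n, n)) - np.eye(n)
    md = pd.DataFrame({"g": ["a", "b", "c"] * 3}, index=ids_of(n))
    res = permanova(DistanceMatrix(d, ids=ids_of(n)), md, "g",
                    permutations=99, seed=0)
    assert res["g"]["R2"] == pytest.approx((g - 1) / (n - 1))
    assert res["g"]["F"] == pytest.approx(1.0)


def test_permanova_exact_matches_enumeration_oracle():
    rng = np.random.default_rng(2)
    x = np.vstack([rng.random((2, 4)), rng.random((2, 4)) + 2.0])
    dm = bray_curtis(frame(np.abs(x)))
    md = pd.DataFrame({"g": ["a", "a", "b", "b"]}, index=dm.ids)
    res = permanova(dm, md, "g", permutations="exact")
    d2 = dm.data ** 2
    f_want = oracle_oneway_F(d2, ["a", "a", "b", "b"])
    assert res["g"]["F"] == pytest.approx(f_want, rel=1e-10)
    count = 0
    perms = list(itertools.permutations(range(4)))
    for p in perms:
        f_p = oracle_oneway_F(d2[np.ix_(p, p)], ["a", "a", "b", "b"])
        if f_p >= f_want - 1e-12:
            count += 1
    assert res["g"]["p"] == pytest.approx(count / len(perms))


def test_permanova_matches_skbio_oneway():
    pytest.importorskip("skbio.stats.distance")
    from skbio.stats.distance import permanova as skbio_permanova

    rng = np.random.default_rng(3)
    x = rng.random((12, 6))
    dm = bray_curtis(frame(x))
    grouping = ["a"] * 6 + ["b"] * 6
    ours = permanova(dm, pd.DataFrame({"g": grouping}, index=dm.ids), "g",
                     permutations=99, seed=0)
    theirs = skbio_permanova(dm, grouping, permutations=99)
    assert ours["g"]["F"] == pytest.approx(theirs["test statistic"], rel=1e-9)


def test_permanova_R2_invariant_under_duplication():
    rng = np.random.default_rng(4)
    x = rng.random((8, 5))
    md = ["a"] * 4 + ["b"] * 4
    dm1 = bray_curtis(frame(x))
    r1 = permanova(dm1, pd.DataFrame({"g": md}, index=dm1.ids), "g",
                   permutations=49, seed=0)
    x2 = np.vstack([x, x])
    dm2 = bray_curtis(frame(x2, ids=[f"s{i}" for i in range(16)]))
    r2 = permanova(dm2, pd.DataFrame({"g": md + md}, index=dm2.ids), "g",
                   permutations=49, seed=0)
    assert r1["g"]["R2"] == pytest.approx(r2["g"]["R2"], rel=1e-9)


# frozen toy dataset; expected sequential SS/F/R2 computed once with
# vegan::adonis2(d ~ A * B, by="terms") as the independent oracle
ADONIS_COUNTS = np.array([
    [12, 5, 3, 9, 1, 7], [14, 6, 2, 8, 2, 6], [11, 4, 4, 10, 1, 8],
    [13, 7, 3, 7, 3, 5], [2, 15, 8, 1, 9, 4], [3, 14, 9, 2, 8, 3],
    [1, 16, 7, 1, 10, 5], [2, 13, 10, 3, 7, 4], [6, 6, 12, 4, 5, 11],
    [7, 5, 13, 5, 4, 12], [5, 7, 11, 3, 6, 10], [6, 6, 14, 4, 5, 13]],
    dtype=float)


def test_permanova_two_way_matches_adonis_oracle():
    dm = bray_curtis(sqrt_relative(frame(ADONIS_COUNTS)))
    md = pd.DataFrame({"A": ["w"] * 4 + ["s"] * 4 + ["c"] * 4,
                       "B": ["p3", "p4"] * 6}, index=dm.ids)
    res = permanova(dm, md, ["A", "B"], permutations=199, seed=0)
    assert res["A"]["SS"] == pytest.approx(0.20540302217, rel=1e-8)
    assert res["B"]["SS"] == pytest.approx(0.00288570371, rel=1e-8)
    assert res["A:B"]["SS"] == pytest.approx(0.00941066015, rel=1e-8)
    assert res["A"]["F"] == pytest.approx(133.61611, rel=1e-6)
    assert res["B"]["F"] == pytest.approx(3.75434, rel=1e-5)
    assert res["A:B"]["F"] == pytest.approx(6.12170, rel=1e-5)
    assert res["A"]["R2"] == pytest.approx(0.9239437635, rel=1e-8)
    # R2 over terms plus residual partitions the total exactly
    assert res.table["R2"].sum() == pytest.approx(1.0)


def test_permanova_single_level_factor_raises():
    d = np.ones((4, 4)) - np.eye(4)
    md = pd.DataFrame({"g": ["a"] * 4}, index=ids_of(4))
    with pytest.raises(ValueError):
        permanova(DistanceMatrix(d, ids=ids_of(4)), md, "g", permutations=9)


# ---------------------------------------------------------------------------
# NMDS


def test_nmds_three_equidistant_points_zero_stress():
    d = np.ones((3, 3)) - np.eye(3)
    res = nmds(DistanceMatrix(d, ids=ids_of(3)), k=2, n_starts=5, seed=0)
    assert res.stress < 0.01


def test_nmds_points_on_line_embed_exactly():
    x = np.linspace(0, 1, 12)[:, None]
    from scipy.spatial.distance import pdist, squareform
    dm = DistanceMatrix(squareform(pdist(x)), ids=ids_of(12))
    res = nmds(dm, k=2, n_starts=10, seed=1)
    assert res.stress < 0.01
    assert res.coordinates.shape == (12, 2)


def test_stress_invariant_under_rotation_and_translation():
    rng = np.random.default_rng(5)
    x = rng.random((8, 4))
    dm = bray_curtis(frame(x))
    res = nmds(dm, k=2, n_starts=5, seed=2)
    coords = res.coordinates.to_numpy()
    theta = 1.1
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    moved = coords @ rot + np.array([3.0, -1.5])
    assert stress1(moved, dm) == pytest.approx(stress1(coords, dm), abs=1e-9)


def test_taxa_scores_weighted_average():
    coords = pd.DataFrame([[0.0, 0.0], [2.0, 2.0]], index=["s1", "s2"],
                          columns=["NMDS1", "NMDS2"])
    rel = pd.DataFrame({"t1": [1.0, 0.0], "t2": [0.5, 0.5]},
                       index=["s1", "s2"])
    scores = taxa_scores(coords, rel)
    assert list(scores.loc["t1"]) == [0.0, 0.0]
    assert list(scores.loc["t2"]) == [1.0, 1.0]
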