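"""Community dissimilarity, ordination, and PERMANOVA.

Counts are converted to square-root-transformed relative abundances,
from which Bray-Curtis dissimilarities are computed. Differences between
groups (pools, compartments) are tested by one- or two-way PERMANOVA on
the Gower-centered squared-dissimilarity matrix with permutation
p-values, and visualized by non-metric multidimensional scaling.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .table import CountTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# transforms and dissimilarity


def sqrt_relative(counts: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Square-root-transformed relative abundances.

    Each entry is sqrt(count / sample total), so squared entries sum to
    one per sample; zero-total samples are excluded with a warning.
    """
    mat = counts.counts if isinstance(counts, CountTable) else counts
    totals = mat.sum(axis=1)
    empty = totals.index[totals == 0]
    if len(empty):
        logger.warning("excluding %d zero-total samples: %s",
                       len(empty), list(empty))
        mat = mat.loc[totals > 0]
        totals = totals[totals > 0]
    return np.sqrt(mat.div(totals, axis=0))


def bray_curtis(x: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between rows:
    d(u, v) = sum|u_i - v_i| / sum(u_i + v_i)."""
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative abundances")
    if (arr.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between all-zero rows")
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(d, ids=list(x.index))


@dataclass(frozen=True)
class GroupDissimilarity:
    overall: float
    within: float
    between: float | None


def group_mean_dissimilarity(dm: DistanceMatrix,
                             groups: pd.Series) -> GroupDissimilarity:
    """Mean pairwise dissimilarity overall, within groups (weighted by
    each group's pair count), and across groups.

    With a single group the between-group mean is None; groups of size
    one contribute no within pairs.
    """
    groups = groups.loc[list(dm.ids)]
    d = dm.data
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    overall = float(d[iu].mean())
    g = np.asarray(groups)
    same = (g[iu[0]] == g[iu[1]])
    within = float(d[iu][same].mean()) if same.any() else math.nan
    between = float(d[iu][~same].mean()) if (~same).any() else None
    return GroupDissimilarity(overall, within, between)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """Sequential (Type I) sum-of-squares partition of a dissimilarity
    matrix with permutation p-values per term."""

    table: pd.DataFrame  # indexed by term: df, SS, F, R2, p
    n_permutations: int
    seed: int | None

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    return c @ a @ c


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _design_matrices(metadata: pd.DataFrame, factors: list[str]):
    """Cumulative design matrices (intercept, +A, +B, +A:B) and the
    term names, for one factor or two crossed factors with interaction."""
    n = len(metadata)
    blocks = [np.ones((n, 1))]
    terms = []
    for f in factors:
        dummies = pd.get_dummies(metadata[f].astype(str), drop_first=True)
        blocks.append(dummies.to_numpy(dtype=float))
        terms.append(f)
    if len(factors) == 2:
        a = metadata[factors[0]].astype(str)
        b = metadata[factors[1]].astype(str)
        inter = pd.get_dummies(a + ":" + b, drop_first=False).to_numpy(float)
        blocks.append(inter)
        terms.append(f"{factors[0]}:{factors[1]}")
    cumulative = []
    for i in range(1, len(blocks) + 1):
        cumulative.append(np.hstack(blocks[:i]))
    return cumulative, terms


def permanova(dm: DistanceMatrix, metadata: pd.DataFrame | pd.Series,
              factors: list[str] | str, permutations: int | str = 9999,
              seed: int | None = None) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    One factor, or two crossed factors plus their interaction with
    sequential (Type I) sums of squares in the order given. Significance
    comes from free permutation of sample labels:
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1). Passing
    ``permutations="exact"`` enumerates all n! label permutations
    (feasible only for small n) and reports p = #{F >= F_obs} / n!.
    """
    if isinstance(factors, str):
        factors = [factors]
    if len(factors) not in (1, 2):
        raise ValueError("permanova supports one or two factors")
    if isinstance(metadata, pd.Series):
        metadata = metadata.to_frame()
    metadata = metadata.loc[list(dm.ids)]
    for f in factors:
        if metadata[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    n = len(dm.ids)
    g = _gower_center(dm.data)
    designs, terms = _design_matrices(metadata, factors)
    hats = [_hat(x) for x in designs]
    ranks = [np.linalg.matrix_rank(x) for x in designs]
    df_terms = [ranks[i + 1] - ranks[i] for i in range(len(terms))]
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_total = float(np.trace(g))

    def partition(gm: np.ndarray) -> tuple[np.ndarray, float]:
        traces = [float(np.sum(h * gm)) for h in hats]
        ss = np.diff(traces)
        ss_res = float(np.trace(gm)) - traces[-1]
        return ss, ss_res

    ss_obs, ss_res_obs = partition(g)
    f_obs = (ss_obs / df_terms) / (ss_res_obs / df_res)

    if permutations == "exact":
        if n > 9:
            raise ValueError("exact enumeration is limited to n <= 9")
        perms = list(itertools.permutations(range(n)))
        count = np.zeros(len(terms))
        for p in perms:
            idx = np.asarray(p)
            ss_p, ss_res_p = partition(g[np.ix_(idx, idx)])
            f_p = (ss_p / df_terms) / (ss_res_p / df_res)
            count += f_p >= f_obs - 1e-12
        pvals = count / len(perms)
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(int(permutations)):
            idx = rng.permutation(n)
            ss_p, ss_res_p = partition(g[np.ix_(idx, idx)])
            f_p = (ss_p / df_terms) / (ss_res_p / df_res)
            count += f_p >= f_obs - 1e-12
        pvals = (count + 1) / (int(permutations) + 1)
        n_perm = int(permutations)

    rows = []
    for i, term in enumerate(terms):
        rows.append({"df": df_terms[i], "SS": ss_obs[i], "F": f_obs[i],
                     "R2": ss_obs[i] / ss_total, "p": pvals[i]})
    rows.append({"df": df_res, "SS": ss_res_obs, "F": math.nan,
                 "R2": ss_res_obs / ss_total, "p": math.nan})
    table = pd.DataFrame(rows, index=terms + ["Residual"])
    return PermanovaResult(table, n_perm, seed if permutations != "exact" else None)


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float  # Kruskal stress-1
    n_starts: int
    converged: bool


def nmds(dm: DistanceMatrix, k: int = 2, n_starts: int = 20,
         max_iter: int = 300, seed: int | None = None) -> NmdsResult:
    """Non-metric multidimensional scaling (best of ``n_starts`` SMACOF
    runs with monotone regression), reporting Kruskal stress-1."""
    from sklearn.manifold import MDS

    n = len(dm.ids)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                n_init=n_starts, max_iter=max_iter, init="random",
                eps=1e-6, random_state=seed, normalized_stress=True)
    coords = model.fit_transform(dm.data)
    converged = bool(model.n_iter_ < max_iter)
    if not converged:
        logger.warning("NMDS did not converge in %d iterations; returning "
                       "best configuration (stress %.4f)", max_iter,
                       model.stress_)
    return NmdsResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids),
                                 columns=[f"NMDS{i + 1}" for i in range(k)]),
        stress=float(model.stress_),
        n_starts=n_starts,
        converged=converged,
    )


def taxa_scores(coordinates: pd.DataFrame,
                rel_abundance: pd.DataFrame) -> pd.DataFrame:
    """Weighted-average taxon scores for biplots: each taxon is placed
    at the abundance-weighted mean of the sample coordinates."""
    w = rel_abundance.loc[coordinates.index]
    w = w / w.sum(axis=0).replace(0, np.nan)
    return w.T @ coordinates


def stress1(coordinates: np.ndarray, dm: DistanceMatrix) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity
    matrix, using isotonic regression for the monotone fit."""
    from sklearn.isotonic import IsotonicRegression

    d_hat = pdist(coordinates)
    iu = np.triu_indices(len(dm.ids), k=1)
    d_obs = dm.data[iu]
    order = np.argsort(d_obs, kind="stable")
    disp = IsotonicRegression().fit_transform(np.arange(len(d_obs)),
                                              d_hat[order])
    resid = np.sum((d_hat[order] - disp) ** 2)
    return math.sqrt(resid / np.sum(d_hat ** 2))
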