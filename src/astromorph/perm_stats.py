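"""Distance-matrix construction and permutation inference.

Implements distance-based multivariate analysis of variance (PERMANOVA) with
one- or two-factor fixed designs (type-III sums of squares by full-vs-reduced
model comparison on the Gower-centred inner-product matrix, permutation of
residuals under the reduced model), the homogeneity-of-dispersions test
(PERMDISP: ANOVA on distances to group centroids in principal-coordinate
space), pairwise pseudo-t comparisons, and the univariate GLM / Sidak /
Cohen-d post-hoc battery.

All permutation p-values use the ``(count >= observed + 1) / (n_perm + 1)``
convention, so they are never exactly zero, and every result records the seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "PermutationResult",
    "assemble_distance_matrix",
    "permanova",
    "permdisp",
    "pairwise_pseudo_t",
    "univariate_glm_posthoc",
]


@dataclass
class DistanceMatrix:
    ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class PermutationResult:
    statistic_name: str
    observed: float
    n_perm: int
    p: float
    seed: int | None
    term: str


def assemble_distance_matrix(features: pd.DataFrame,
                             transform: bool = True) -> DistanceMatrix:
    """Euclidean distances between cells, optionally after log10(x+1) and
    unit-variance normalization of each feature."""
    if features.isna().any().any():
        bad = features.index[features.isna().any(axis=1)].tolist()
        raise ValueError(f"missing feature values for cells: {bad}")
    X = features.to_numpy(float)
    if transform:
        X = np.log10(X + 1.0)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        X = X[:, keep] / sd[keep]
    d = squareform(pdist(X))
    return DistanceMatrix(ids=list(features.index), d=d)


def _gower(d: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = -1/2 J D^2 J."""
    n = len(d)
    A = -0.5 * d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _effect_columns(levels: pd.Series) -> np.ndarray:
    """Sum-to-zero (effect) coding: one column per non-reference level."""
    cats = sorted(pd.unique(levels))
    n = len(levels)
    cols = np.zeros((n, len(cats) - 1))
    for j, c in enumerate(cats[:-1]):
        cols[np.asarray(levels) == c, j] = 1.0
    cols[np.asarray(levels) == cats[-1], :] = -1.0
    return cols


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _one_factor_permanova(d: np.ndarray, labels: np.ndarray, n_perm: int,
                          seed, term: str) -> PermutationResult:
    """Vectorised one-way PERMANOVA with free permutation of labels."""
    n = len(labels)
    levels, inv = np.unique(labels, return_inverse=True)
    a = len(levels)
    D2 = d ** 2
    sst = D2.sum() / (2.0 * n)
    if sst <= 0:
        raise ValueError("total sum of squares is zero; all observations identical")
    if n - a <= 0:
        raise ValueError(f"term {term!r} has zero residual degrees of freedom")

    def ssw_for(inv_mat: np.ndarray) -> np.ndarray:
        # inv_mat: (P, n) integer group codes; returns SSW per permutation
        P = inv_mat.shape[0]
        ssw = np.zeros(P)
        for gi in range(a):
            M = (inv_mat == gi).T.astype(float)        # (n, P)
            ng = M.sum(axis=0)
            ssw += ((D2 @ M) * M).sum(axis=0) / (2.0 * ng)
        return ssw

    ssw_obs = float(ssw_for(inv[None, :])[0])
    ssa = sst - ssw_obs
    f_obs = (ssa / (a - 1)) / (ssw_obs / (n - a))

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(inv, (n_perm, 1)), axis=1)
    ssw_p = ssw_for(perm)
    f_p = ((sst - ssw_p) / (a - 1)) / (ssw_p / (n - a))
    p = (np.count_nonzero(f_p >= f_obs) + 1) / (n_perm + 1)
    return PermutationResult("pseudo-F", float(f_obs), n_perm, float(p),
                             seed, term)


def permanova(dm: DistanceMatrix, design: pd.DataFrame,
              factors: list[str] | None = None, interaction: bool = True,
              n_perm: int = 9999, seed: int | None = None,
              scheme: str = "residuals") -> list[PermutationResult]:
    """Distance-based MANOVA by permutation.

    One factor: classical pseudo-F with free permutation of group labels.
    Two factors: type-III sums of squares for each main effect and the
    interaction via full-minus-reduced model fits with sum-to-zero contrasts;
    p-values by permutation of residuals under each term's reduced model
    (``scheme='residuals'``, the default) or free permutation
    (``scheme='free'``).
    """
    if factors is None:
        factors = list(design.columns)
    if not 1 <= len(factors) <= 2:
        raise ValueError("permanova supports one or two factors")
    for f in factors:
        if design[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    d = dm.d
    n = dm.n
    if len(design) != n:
        raise ValueError("design length does not match distance matrix")

    if len(factors) == 1:
        return [_one_factor_permanova(d, design[factors[0]].to_numpy(),
                                      n_perm, seed, factors[0])]

    G = _gower(d)
    sst = float(np.trace(G))
    if sst <= 0:
        raise ValueError("total sum of squares is zero; all observations identical")

    fa, fb = factors
    A = _effect_columns(design[fa])
    B = _effect_columns(design[fb])
    terms: dict[str, np.ndarray] = {fa: A, fb: B}
    if interaction:
        AB = np.einsum("ni,nj->nij", A, B).reshape(n, -1)
        terms[f"{fa}:{fb}"] = AB

    ones = np.ones((n, 1))
    X_full = np.hstack([ones] + [terms[t] for t in terms])
    H_full = _hat(X_full)
    df_res = n - int(round(np.trace(H_full)))
    if df_res <= 0:
        raise ValueError("model is saturated: zero residual degrees of freedom")
    ss_res = float(np.sum((np.eye(n) - H_full) * G))

    rng = np.random.default_rng(seed)
    results = []
    for t, cols in terms.items():
        others = [c for u, c in terms.items() if u != t]
        X_red = np.hstack([ones] + others) if others else ones
        H_red = _hat(X_red)
        df_t = cols.shape[1]
        ss_t = float(np.sum((H_full - H_red) * G))
        if ss_t < 0:
            ss_t = 0.0
        f_obs = (ss_t / df_t) / (ss_res / df_res)

        I = np.eye(n)
        if scheme == "residuals":
            R = (I - H_red) @ G @ (I - H_red)
        elif scheme == "free":
            R = G
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        Hdiff = H_full - H_red
        Hres = I - H_full
        count = 0
        for _ in range(n_perm):
            pi = rng.permutation(n)
            Rp = R[np.ix_(pi, pi)]
            ss_t_p = float(np.sum(Hdiff * Rp))
            ss_res_p = float(np.sum(Hres * Rp))
            if ss_res_p <= 0:
                continue
            f_p = (ss_t_p / df_t) / (ss_res_p / df_res)
            if f_p >= f_obs:
                count += 1
        p = (count + 1) / (n_perm + 1)
        results.append(PermutationResult("pseudo-F", float(f_obs), n_perm,
                                         float(p), seed, t))
    return results


def _pco_centroid_distances(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Distance of each point to its group centroid in principal-coordinate
    space, with Anderson's correction for negative eigenvalues."""
    G = _gower(d)
    vals, vecs = np.linalg.eigh(G)
    keep = np.abs(vals) > 1e-10 * max(1.0, np.abs(vals).max())
    vals, vecs = vals[keep], vecs[:, keep]
    coords = vecs * np.sqrt(np.abs(vals))
    pos = vals > 0
    z2 = np.zeros(len(d))
    for g in np.unique(labels):
        sel = labels == g
        c = coords[sel].mean(axis=0)
        diff2 = (coords[sel] - c) ** 2
        z2[sel] = diff2[:, pos].sum(axis=1) - diff2[:, ~pos].sum(axis=1)
    return np.sqrt(np.clip(z2, 0.0, None))


def _anova_f(values: np.ndarray, codes: np.ndarray, a: int) -> float:
    n = len(values)
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(a):
        v = values[codes == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (a - 1)) / (ssw / (n - a))


def permdisp(dm: DistanceMatrix, groups, n_perm: int = 9999,
             seed: int | None = None
             ) -> tuple[PermutationResult, pd.DataFrame]:
    """Homogeneity of multivariate dispersions.

    Distances of members to their group centroid are computed in
    principal-coordinate space; the observed statistic is the one-way ANOVA F
    on those distances, with p obtained by permuting group labels of the
    centroid distances.  Also returns a pairwise pseudo-t table.
    """
    labels = np.asarray(groups)
    levels, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    if (counts < 2).any():
        bad = levels[counts < 2].tolist()
        raise ValueError(f"singleton group(s) {bad}: dispersion undefined")
    a = len(levels)
    z = _pco_centroid_distances(dm.d, labels)
    f_obs = _anova_f(z, inv, a)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_p = _anova_f(z, rng.permutation(inv), a)
        if f_p >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    overall = PermutationResult("F", float(f_obs), n_perm, float(p), seed,
                                "dispersion")

    rows = []
    for g1, g2 in itertools.combinations(range(a), 2):
        sel = (inv == g1) | (inv == g2)
        zi, ci = z[sel], (inv[sel] == g2).astype(int)
        f12 = _anova_f(zi, ci, 2)
        cnt = 0
        for _ in range(n_perm):
            if _anova_f(zi, rng.permutation(ci), 2) >= f12:
                cnt += 1
        rows.append({"group1": levels[g1], "group2": levels[g2],
                     "pseudo_t": float(np.sqrt(f12)),
                     "p": (cnt + 1) / (n_perm + 1)})
    return overall, pd.DataFrame(rows)


def pairwise_pseudo_t(dm: DistanceMatrix, groups, n_perm: int = 9999,
                      seed: int | None = None) -> pd.DataFrame:
    """Pairwise two-group PERMANOVA comparisons; pseudo-t = sqrt(pseudo-F).

    Permutations are restricted to the members of each pair.  Raw and
    Sidak-adjusted p-values are both reported; singleton groups are skipped
    with a warning.
    """
    labels = np.asarray(groups)
    levels, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in itertools.combinations(range(len(levels)), 2):
        if counts[g1] < 2 or counts[g2] < 2:
            warnings.warn(f"pair ({levels[g1]}, {levels[g2]}) skipped: "
                          "group with a single member", stacklevel=2)
            continue
        sel = np.flatnonzero((inv == g1) | (inv == g2))
        sub = dm.d[np.ix_(sel, sel)]
        res = _one_factor_permanova(sub, inv[sel], n_perm,
                                    rng.integers(2 ** 31), "pair")
        rows.append({"group1": levels[g1], "group2": levels[g2],
                     "pseudo_t": float(np.sqrt(max(res.observed, 0.0))),
                     "p": res.p})
    out = pd.DataFrame(rows)
    if not out.empty:
        m = len(out)
        out["p_sidak"] = 1.0 - (1.0 - out["p"]) ** m
    return out


@dataclass
class GLMPosthoc:
    F: float
    p: float
    pairwise: pd.DataFrame


def univariate_glm_posthoc(values, groups) -> GLMPosthoc:
    """One-way fixed-effect GLM with Sidak-adjusted pairwise tests and Cohen d.

    Pairwise p-values come from pooled-variance t-tests, adjusted as
    ``1 - (1 - p)^m`` over the m pairwise comparisons; Cohen's d is the mean
    difference over the pooled standard deviation of the pair (a missing-value
    marker when the pooled variance is zero).
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [x[labels == g] for g in levels]
    for g, s in zip(levels, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    F, p = stats.f_oneway(*samples)

    pairs = list(itertools.combinations(range(len(levels)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        a, b = samples[i], samples[j]
        sp2 = (((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
               / (len(a) + len(b) - 2))
        diff = a.mean() - b.mean()
        d = diff / np.sqrt(sp2) if sp2 > 0 else np.nan
        if sp2 > 0:
            _, praw = stats.ttest_ind(a, b, equal_var=True)
        else:
            praw = 1.0 if diff == 0 else 0.0
        rows.append({"group1": levels[i], "group2": levels[j],
                     "mean_diff": float(diff), "p": float(praw),
                     "p_sidak": float(1.0 - (1.0 - praw) ** m),
                     "cohen_d": float(d) if np.isfinite(d) else np.nan})
    return GLMPosthoc(F=float(F), p=float(p), pairwise=pd.DataFrame(rows))
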