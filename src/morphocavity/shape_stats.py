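"""Shape-space statistics: PCA, PC retention, resampling stability, Ward
clustering with automatic cluster count, and cluster characterization tests
(per-landmark MANOVA, per-axis ANOVA, pairwise Tukey HSD, Lin's CCC,
chi-square, Kruskal-Wallis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .geometry_io import LandmarkConfiguration
from .procrustes import AlignedSample

__all__ = [
    "ShapePCA",
    "WardTree",
    "ClusterModel",
    "shape_pca",
    "select_components_elbow",
    "pca_stability_resampling",
    "ward_tree",
    "within_inertia_profile",
    "select_cluster_count",
    "cluster_count_vote",
    "manova_per_landmark",
    "anova_per_axis",
    "tukey_pairwise",
    "lins_ccc",
    "repeatability_report",
    "chi_square_test",
    "kruskal_wallis_test",
    "benjamini_hochberg",
]

#: an inertia-gain ratio below this flags the selected k as low-confidence
LOW_CONFIDENCE_RATIO = 1.5


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class ShapePCA:
    scores: np.ndarray  # (n, m)
    loadings: np.ndarray  # (m, 3k) rows are unit eigenvectors
    explained_ratio: np.ndarray  # (m,) non-increasing, sums to 1
    eigenvalues: np.ndarray  # (m,)
    center: np.ndarray  # (3k,)

    @property
    def n_components(self) -> int:
        return len(self.explained_ratio)

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        m = n_components or self.n_components
        return self.scores[:, :m] @ self.loadings[:m] + self.center


def shape_pca(sample: AlignedSample | np.ndarray) -> ShapePCA:
    """PCA of the flattened aligned coordinates.

    Eigendecomposition of the covariance of the n x 3k matrix; components
    beyond the data rank are dropped so the explained spectrum sums to one.
    Sign convention: the largest-magnitude entry of every loading is positive.
    """
    X = sample.flattened() if isinstance(sample, AlignedSample) else np.asarray(sample, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"PCA requires at least 3 specimens, got {n}")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > eig[0] * 1e-12 if eig[0] > 0 else slice(0, 1)
    eig = eig[keep]
    Vt = Vt[keep]
    s = s[keep]
    # deterministic sign: flip each loading so its peak entry is positive
    flips = np.sign(Vt[np.arange(len(Vt)), np.argmax(np.abs(Vt), axis=1)])
    flips[flips == 0] = 1.0
    Vt = Vt * flips[:, None]
    scores = Xc @ Vt.T
    ratio = eig / eig.sum()
    return ShapePCA(scores, Vt, ratio, eig, center)


def select_components_elbow(spectrum: Sequence[float]) -> int:
    """Elbow pick: the scree index with maximum perpendicular distance to the
    chord joining the first and last scree points (1-based; ties and flat
    spectra resolve to the smallest index)."""
    y = np.asarray(spectrum, float)
    m = len(y)
    if m == 0:
        raise ValueError("empty spectrum")
    if m == 1:
        return 1
    x = np.arange(1, m + 1, dtype=float)
    chord = np.array([x[-1] - x[0], y[-1] - y[0]])
    norm = np.linalg.norm(chord)
    if norm == 0:
        return 1
    rel = np.stack([x - x[0], y - y[0]], axis=1)
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    return int(np.argmax(dist)) + 1  # argmax takes the first maximum


def pca_stability_resampling(
    sample: AlignedSample,
    sizes: Sequence[int],
    reps: int = 100,
    m: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cumulative explained variance of the first ``m`` PCs on random subsets.

    Subsets are drawn without replacement, ``reps`` times per size; returns a
    tidy table (size, mean, sd).
    """
    n = sample.n_specimens
    rng = np.random.default_rng(seed)
    rows = []
    flat = sample.flattened()
    for size in sizes:
        if size > n:
            raise ValueError(f"subset size {size} exceeds sample size {n}")
        vals = np.empty(reps)
        for r in range(reps):
            idx = rng.choice(n, size=size, replace=False)
            pca = shape_pca(flat[idx])
            vals[r] = pca.explained_ratio[: min(m, pca.n_components)].sum()
        rows.append({"size": size, "mean": vals.mean(), "sd": vals.std(ddof=0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ward clustering / HCPC
# ---------------------------------------------------------------------------


@dataclass
class WardTree:
    """Ward linkage (Ward.D2 convention) plus the scores it was built from."""

    linkage: np.ndarray  # scipy linkage matrix
    scores: np.ndarray  # (n, m)

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels in 1..k, renumbered in order of first appearance."""
        raw = sch.fcluster(self.linkage, k, criterion="maxclust")
        _, first = np.unique(raw, return_index=True)
        order = raw[np.sort(first)]
        remap = {int(old): i + 1 for i, old in enumerate(order)}
        return np.array([remap[int(r)] for r in raw], np.int64)


@dataclass
class ClusterModel:
    tree: WardTree
    k: int
    labels: np.ndarray
    within_inertia: dict[int, float] = field(default_factory=dict)
    low_confidence: bool = False


def ward_tree(scores: np.ndarray) -> WardTree:
    """Agglomerative Ward tree on Euclidean distances between score rows."""
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if len(scores) < 2:
        raise ValueError("need at least two observations to cluster")
    Z = sch.linkage(scores, method="ward")
    return WardTree(Z, scores)


def _within_inertia(scores: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for g in np.unique(labels):
        sub = scores[labels == g]
        total += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    return total


def within_inertia_profile(tree: WardTree, kmin: int, kmax: int) -> dict[int, float]:
    """W(k) for each k in [kmin, kmax], computed from tree cuts."""
    return {
        k: _within_inertia(tree.scores, tree.cut(k))
        for k in range(kmin, kmax + 1)
    }


def select_cluster_count(
    tree: WardTree,
    kmin: int = 2,
    kmax: int = 10,
    return_details: bool = False,
):
    """Automatic cluster count from inertia gains.

    With dW(k) = W(k-1) - W(k), picks the k in [kmin, kmax] maximizing
    dW(k) / dW(k+1) (ties to the smaller k).  A maximum ratio below
    ``LOW_CONFIDENCE_RATIO`` flags the choice as low-confidence.
    """
    n = len(tree.scores)
    kmax = min(kmax, n - 1)
    if kmax < kmin:
        raise ValueError(f"cluster scan range empty: kmin={kmin}, kmax={kmax}")
    W = within_inertia_profile(tree, kmin - 1, kmax + 1)
    ratios: dict[int, float] = {}
    for k in range(kmin, kmax + 1):
        dw = W[k - 1] - W[k]
        dw_next = W[k] - W[k + 1]
        ratios[k] = dw / dw_next if dw_next > 0 else np.inf
    best = max(ratios, key=lambda k: (ratios[k], -k))
    low_conf = ratios[best] < LOW_CONFIDENCE_RATIO  # inf ratios are confident
    if return_details:
        return best, ratios, low_conf
    return best


def cluster_count_vote(
    scores: np.ndarray, kmin: int = 2, kmax: int = 10
) -> tuple[dict[str, int], int]:
    """Reduced index battery: Calinski-Harabasz, mean silhouette, inertia-gain.

    Majority vote over the three indices; ties resolve to the inertia-gain
    choice.
    """
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if np.allclose(scores, scores[0]):
        raise ValueError("constant data: cluster indices undefined")
    tree = ward_tree(scores)
    kmax = min(kmax, len(scores) - 1)
    ch: dict[int, float] = {}
    sil: dict[int, float] = {}
    for k in range(kmin, kmax + 1):
        labels = tree.cut(k)
        ch[k] = calinski_harabasz_score(scores, labels)
        sil[k] = silhouette_score(scores, labels)
    choices = {
        "calinski_harabasz": max(ch, key=lambda k: (ch[k], -k)),
        "silhouette": max(sil, key=lambda k: (sil[k], -k)),
        "inertia_gain": select_cluster_count(tree, kmin, kmax),
    }
    votes = pd.Series(list(choices.values())).value_counts()
    if votes.iloc[0] > 1:
        majority = int(votes.index[0])
    else:
        majority = choices["inertia_gain"]
    return choices, majority


# ---------------------------------------------------------------------------
# cluster characterization tests
# ---------------------------------------------------------------------------


def _aligned_array(sample: AlignedSample | np.ndarray) -> np.ndarray:
    if isinstance(sample, AlignedSample):
        return sample.aligned
    arr = np.asarray(sample, float)
    if arr.ndim != 3:
        raise ValueError("expected an (n, k, 3) coordinate stack")
    return arr


def _pillai_oneway(Y: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-way MANOVA Pillai trace and F-approximation p-value for (n, p) data."""
    groups = np.unique(labels)
    g = len(groups)
    n, p = Y.shape
    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for grp in groups:
        sub = Y[labels == grp]
        gm = sub.mean(axis=0)
        d = (gm - grand)[:, None]
        H += len(sub) * (d @ d.T)
        E += (sub - gm).T @ (sub - gm)
    try:
        V = float(np.trace(np.linalg.solve(E + H, H)))
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    s = min(p, g - 1)
    m_ = (abs(p - g + 1) - 1) / 2
    n_ = (n - g - p - 1) / 2
    df1 = s * (2 * m_ + s + 1)
    df2 = s * (2 * n_ + s + 1)
    if df2 <= 0 or s - V <= 0:
        pval = 0.0 if V > 0 else 1.0
        return V, pval
    F = (df2 / df1) * V / (s - V)
    return V, float(scipy.stats.f.sf(F, df1, df2))


def manova_per_landmark(
    sample: AlignedSample | np.ndarray, labels: np.ndarray | list
) -> pd.DataFrame:
    """One-way MANOVA (Pillai's trace) of each landmark's (x, y, z) triplet
    across cluster labels.  Singular within-group structure yields NaN p."""
    arr = _aligned_array(sample)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("MANOVA needs at least two clusters")
    if counts.min() < 4:
        raise ValueError("every cluster needs at least 4 members for MANOVA")
    rows = []
    for lm in range(arr.shape[1]):
        pillai, p = _pillai_oneway(arr[:, lm, :], labels)
        rows.append({"landmark": lm, "pillai": pillai, "p": p})
    return pd.DataFrame(rows)


def anova_per_axis(
    sample: AlignedSample | np.ndarray, labels: np.ndarray | list
) -> pd.DataFrame:
    """One-way ANOVA F and p per landmark per axis (X, Y, Z)."""
    arr = _aligned_array(sample)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two clusters")
    masks = [labels == g for g in groups]
    rows = []
    for lm in range(arr.shape[1]):
        for ax, name in enumerate("XYZ"):
            samples = [arr[m, lm, ax] for m in masks]
            if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
                F, p = 0.0, 1.0
            else:
                F, p = scipy.stats.f_oneway(*samples)
                F = max(float(F), 0.0)  # guard rounding when SSB ~ 0
                if np.isnan(p):
                    n_tot = sum(len(s) for s in samples)
                    p = scipy.stats.f.sf(F, len(samples) - 1, n_tot - len(samples))
            rows.append({"landmark": lm, "axis": name, "F": float(F), "p": float(p)})
    return pd.DataFrame(rows)


def tukey_pairwise(
    sample: AlignedSample | np.ndarray, labels: np.ndarray | list
) -> pd.DataFrame:
    """Tukey HSD per landmark, axis and cluster pair.

    ``diff`` is mean(cluster_a) - mean(cluster_b); its sign states which
    cluster's landmarks sit further along the axis (i.e. further from the
    origin for positive coordinates).
    """
    arr = _aligned_array(sample)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("Tukey test needs at least two clusters")
    masks = [labels == g for g in groups]
    rows = []
    for lm in range(arr.shape[1]):
        for ax, name in enumerate("XYZ"):
            data = [arr[m, lm, ax] for m in masks]
            if all(np.ptp(d) == 0 for d in data):
                res = None
            else:
                res = scipy.stats.tukey_hsd(*data)
            for i, j in combinations(range(len(groups)), 2):
                diff = float(np.mean(data[i]) - np.mean(data[j]))
                p = 1.0 if res is None else float(res.pvalue[i, j])
                rows.append(
                    {
                        "landmark": lm,
                        "axis": name,
                        "cluster_a": groups[i],
                        "cluster_b": groups[j],
                        "diff": diff,
                        "p_adj": p,
                        "sign": int(np.sign(diff)),
                    }
                )
    return pd.DataFrame(rows)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# agreement / demographics tests
# ---------------------------------------------------------------------------


def lins_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient with 1/n (biased) moments:
    2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired vectors of equal length >= 2 required")
    mx, my = x.mean(), y.mean()
    sxy = np.mean((x - mx) * (y - my))
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        return 1.0  # identical constant sessions agree perfectly
    return float(2 * sxy / denom)


def repeatability_report(
    sessions: Mapping[str, Sequence[LandmarkConfiguration]],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Lin's CCC between digitization sessions, split by landmark class.

    Coordinates are pooled across specimens, landmarks and axes into one
    paired vector per session pair, separately for fixed landmarks and
    semi-landmarks (a per-landmark table is derivable from the raw configs).
    """
    names = list(sessions)
    if len(names) < 2:
        raise ValueError("at least two sessions required")
    if pairs is None:
        pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        ca, cb = sessions[a], sessions[b]
        if len(ca) != len(cb):
            raise ValueError(f"sessions {a!r} and {b!r} cover different specimens")
        fixed_a, fixed_b, semi_a, semi_b = [], [], [], []
        for conf_a, conf_b in zip(ca, cb):
            fixed_a.append(conf_a.fixed.ravel())
            fixed_b.append(conf_b.fixed.ravel())
            semi_a.append(conf_a.semilandmarks.ravel())
            semi_b.append(conf_b.semilandmarks.ravel())
        rows.append(
            {
                "pair": f"{a}|{b}",
                "landmark_class": "fixed",
                "ccc": lins_ccc(np.concatenate(fixed_a), np.concatenate(fixed_b)),
            }
        )
        if semi_a and semi_a[0].size:
            rows.append(
                {
                    "pair": f"{a}|{b}",
                    "landmark_class": "sliding",
                    "ccc": lins_ccc(np.concatenate(semi_a), np.concatenate(semi_b)),
                }
            )
    return pd.DataFrame(rows)


def chi_square_test(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    table = np.asarray(table, float)
    res = scipy.stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def kruskal_wallis_test(groups: Sequence[np.ndarray]) -> tuple[float, int, float]:
    """Rank-based Kruskal-Wallis H with tie correction (chi-square approx)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    H, p = scipy.stats.kruskal(*groups)
    return float(H), df, float(p)
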