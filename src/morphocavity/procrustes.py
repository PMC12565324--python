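"""Procrustes superimposition, shape distances, and permutation Procrustes ANOVA.

GPA removes translation (centering), scale (unit centroid size) and rotation
(iterative alignment to the evolving mean shape).  Reflections are disallowed
by default because specimens are pre-mirrored to a single-side convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlignedSample",
    "ProcrustesAnovaResult",
    "centroid_size",
    "align_pair",
    "gpa",
    "procrustes_distance",
    "procrustes_anova",
]


@dataclass
class AlignedSample:
    """GPA output: configurations centered at the origin with unit centroid size."""

    aligned: np.ndarray  # (n, k, 3)
    mean_shape: np.ndarray  # (k, 3), unit centroid size
    centroid_sizes: np.ndarray  # (n,) original sizes in mm
    iterations: int

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        return self.aligned.reshape(self.n_specimens, -1)


@dataclass
class ProcrustesAnovaResult:
    ss_between: float
    ss_within: float
    F: float
    p: float
    n_perm: int
    seed: int


def centroid_size(config: np.ndarray) -> float:
    """Root summed squared distance of the landmarks to their centroid."""
    config = np.asarray(config, float).reshape(-1, 3)
    centered = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _normalize(config: np.ndarray, label: str = "configuration") -> np.ndarray:
    config = np.asarray(config, float).reshape(-1, 3)
    centered = config - config.mean(axis=0)
    size = np.sqrt(np.sum(centered**2))
    if size <= 0:
        raise ValueError(f"degenerate {label}: zero centroid size")
    return centered / size


def align_pair(
    mobile: np.ndarray, reference: np.ndarray, allow_reflection: bool = False
) -> tuple[np.ndarray, float]:
    """Rotate ``mobile`` onto ``reference``; both should be centered, unit-size.

    Returns the rotated copy and the residual root-summed-square difference.
    With ``allow_reflection=False`` the returned transform has determinant +1
    (smallest singular direction sign-corrected).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    A = mobile.T @ reference
    U, s, Vt = np.linalg.svd(A)
    if s[-1] / max(s[0], 1e-300) < 1e-12:
        warnings.warn(
            "rank-deficient cross-covariance in pair alignment", RuntimeWarning,
            stacklevel=2,
        )
    d = np.sign(np.linalg.det(U @ Vt))
    if not allow_reflection and d < 0:
        U = U.copy()
        U[:, -1] *= -1
    R = U @ Vt
    rotated = mobile @ R
    return rotated, float(np.linalg.norm(rotated - reference))


def gpa(
    configs: np.ndarray | list[np.ndarray],
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool = False,
) -> AlignedSample:
    """Generalized Procrustes Analysis.

    Iterates: align every unit-size configuration to the current mean,
    recompute the mean, renormalize it to unit centroid size; stops when the
    root-summed-square change of the mean drops below ``tol``.
    """
    arr = np.asarray(configs, float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("configs must be an (n, k, 3) stack")
    n = arr.shape[0]
    sizes = np.empty(n)
    normed = np.empty_like(arr)
    for i in range(n):
        sizes[i] = centroid_size(arr[i])
        try:
            normed[i] = _normalize(arr[i])
        except ValueError as exc:
            raise ValueError(f"specimen {i}: {exc}") from exc

    mean = normed[0].copy()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            normed[i], _ = align_pair(normed[i], mean, allow_reflection)
        new_mean = normed.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        norm = np.sqrt(np.sum(new_mean**2))
        if norm <= 0:
            raise ValueError("degenerate mean shape during GPA")
        new_mean /= norm
        change = np.sqrt(np.sum((new_mean - mean) ** 2))
        mean = new_mean
        if change < tol:
            break
    return AlignedSample(normed, mean, sizes, iterations)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Residual distance between two shapes after normalization and alignment."""
    na = _normalize(a, "first configuration")
    nb = _normalize(b, "second configuration")
    _, resid = align_pair(na, nb)
    return resid


def _goodall_f(flat: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    grand = flat.mean(axis=0)
    ss_total = float(np.sum((flat - grand) ** 2))
    ss_between = 0.0
    for g in groups:
        sub = flat[labels == g]
        gm = sub.mean(axis=0)
        ss_between += len(sub) * float(np.sum((gm - grand) ** 2))
    ss_within = ss_total - ss_between
    n, g = len(flat), len(groups)
    if ss_within <= 0:
        return ss_between, ss_within, np.inf
    F = (ss_between / (g - 1)) / (ss_within / (n - g))
    return ss_between, ss_within, F


def procrustes_anova(
    sample: AlignedSample,
    labels: np.ndarray | list,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesAnovaResult:
    """Goodall-F Procrustes ANOVA with a label-permutation p-value.

    The statistic compares squared distances of aligned shapes to their
    group means against distances to the overall mean; significance is
    assessed by permuting group labels (p = (#{F_perm >= F_obs} + 1) /
    (n_perm + 1)).
    """
    labels = np.asarray(labels)
    if len(labels) != sample.n_specimens:
        raise ValueError("one label per specimen required")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("procrustes_anova needs at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")

    flat = sample.flattened()
    ss_b, ss_w, f_obs = _goodall_f(flat, labels, groups)
    rng = np.random.default_rng(seed)
    count = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        _, _, f_p = _goodall_f(flat, perm, groups)
        if f_p >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return ProcrustesAnovaResult(ss_b, ss_w, f_obs, p, n_perm, seed)
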