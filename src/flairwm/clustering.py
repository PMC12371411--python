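"""White-matter intensity clustering.

The core of the method: a robust fuzzy C-means (RFCM) over the extracted WM
intensities, Dice-based selection of the lesion-salient cluster against a
fixed reference, and membership thresholding. RFCM minimizes

    J = sum_j sum_k u_jk^q (y_j - v_k)^2
        + (beta/2) sum_j sum_k u_jk^q sum_{l in N_j} sum_{m != k} u_lm^q

over memberships u (simplex-constrained per voxel) and centroids v, where
N_j is the 6-face neighborhood. The spatial cross-class penalty (weight
beta) discourages a voxel from committing to a cluster its neighbors do not
belong to, yielding smoother membership maps and some noise insensitivity.

Updates alternate exact coordinate minimizations: memberships are updated in
a red-black (checkerboard) sweep — with a 6-face neighborhood the penalty
couples only opposite-parity voxels, so each half-sweep is an exact block
minimization — followed by the closed-form centroid update. J is therefore
non-increasing at every iteration, beta = 0 reduces exactly to standard FCM,
and the fuzzy partition is scale-equivariant at beta = 0.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .io import Volume

_FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclasses.dataclass
class RFCMParams:
    """Hyperparameters of the robust fuzzy C-means.

    beta weighs the spatial penalty; the default is chosen so the penalty
    term is on the order of 10% of the data term on the default phantom
    (see the package docs). tol is the convergence tolerance on the maximum
    centroid change between iterations.
    """

    K: int = 3
    q: float = 2.0
    beta: float = 0.005
    tol: float = 1e-5
    max_iter: int = 200
    neighborhood: str = "6-face"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.q <= 1:
            raise ValueError("q must be > 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.neighborhood != "6-face":
            raise ValueError("only the 6-face neighborhood is supported")


@dataclasses.dataclass
class MembershipStack:
    """K fuzzy membership maps with their (ascending) centroids and support mask."""

    memberships: np.ndarray          # (K, *shape), zeros outside mask
    mask: np.ndarray                 # boolean (*shape)
    centroids: np.ndarray            # (K,) strictly increasing
    objective_history: list[float] = dataclasses.field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    @property
    def K(self) -> int:
        return self.memberships.shape[0]


@dataclasses.dataclass
class ClusterSelection:
    selected_index: int              # 0-based into the sorted stack
    dice_scores: np.ndarray          # (K,)
    thresholded: Volume              # values 0 or in [tau, 1]


def _neighbor_table(mask: np.ndarray) -> np.ndarray:
    """(M, 6) indices into the masked-voxel array; -1 where no masked neighbor."""
    idx_grid = np.full(mask.shape, -1, dtype=np.int64)
    coords = np.argwhere(mask)
    idx_grid[mask] = np.arange(len(coords))
    table = np.full((len(coords), 6), -1, dtype=np.int64)
    for a, off in enumerate(_FACE_OFFSETS):
        nb = coords + np.array(off)
        ok = np.all((nb >= 0) & (nb < np.array(mask.shape)), axis=1)
        table[ok, a] = idx_grid[tuple(nb[ok].T)]
    return table


def _fcm_memberships(y: np.ndarray, centroids: np.ndarray, q: float) -> np.ndarray:
    """Closed-form simplex minimizer of sum_k u_k^q d_k for d_k = (y - v_k)^2."""
    d = (y[:, None] - centroids[None, :]) ** 2
    return _memberships_from_distances(d, q)


def _memberships_from_distances(d: np.ndarray, q: float) -> np.ndarray:
    u = np.empty_like(d)
    zero = d <= 0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d[~any_zero] ** (-1.0 / (q - 1.0))
    u[~any_zero] = w / w.sum(axis=1, keepdims=True)
    if any_zero.any():
        z = zero[any_zero].astype(float)
        u[any_zero] = z / z.sum(axis=1, keepdims=True)
    return u


def rfcm(wm_image: Volume, params: RFCMParams | None = None,
         init: str = "percentile", seed: int = 0) -> MembershipStack:
    """Cluster the extracted-WM intensities into K fuzzy intensity classes.

    The support mask is {voxels with intensity > 0} (WM extraction is
    multiplicative, so zero means no WM). Centroids are initialized at
    deterministic percentiles of the in-mask intensities ((k+1)/(K+1)
    quantiles); ``init="random"`` draws them from the in-mask intensity range
    using ``seed``. Returns memberships permuted so centroids are ascending.
    """
    params = params or RFCMParams()
    mask = wm_image.data > 0
    if not mask.any():
        raise ValueError("empty clustering mask (no positive WM intensities)")
    y = wm_image.data[mask].astype(np.float64)
    if len(np.unique(y)) < params.K:
        raise ValueError(f"fewer than K={params.K} distinct intensities in mask")

    K, q, beta = params.K, params.q, params.beta
    if init == "percentile":
        v = np.percentile(y, [100.0 * (k + 1) / (K + 1) for k in range(K)])
    elif init == "random":
        rng = np.random.default_rng(seed)
        v = np.sort(rng.uniform(y.min(), y.max(), size=K))
    else:
        raise ValueError(f"unknown init rule: {init}")
    v = v.astype(np.float64)

    u = _fcm_memberships(y, v, q)
    nbr = _neighbor_table(mask) if beta > 0 else None
    parity = (np.argwhere(mask).sum(axis=1) % 2) if beta > 0 else None

    def penalty_matrix(u_q: np.ndarray, rows: np.ndarray) -> np.ndarray:
        # P[j,k] = sum_{l in N_j} (S_l - u_lk^q) over masked neighbors
        S = u_q.sum(axis=1)
        t = nbr[rows]
        valid = t >= 0
        tt = np.where(valid, t, 0)
        P = (np.where(valid, S[tt], 0.0).sum(axis=1))[:, None] \
            - np.einsum("jak->jk", np.where(valid[:, :, None], u_q[tt], 0.0))
        return P

    def objective(u: np.ndarray, v: np.ndarray) -> float:
        u_q = u ** q
        J = float(np.sum(u_q * (y[:, None] - v[None, :]) ** 2))
        if beta > 0:
            P = penalty_matrix(u_q, np.arange(len(y)))
            J += 0.5 * beta * float(np.sum(u_q * P))
        return J

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        if beta == 0:
            u = _fcm_memberships(y, v, q)
        else:
            for p in (0, 1):
                rows = np.flatnonzero(parity == p)
                u_q = u ** q
                d = (y[rows, None] - v[None, :]) ** 2 + beta * penalty_matrix(u_q, rows)
                u[rows] = _memberships_from_distances(d, q)
        u_q = u ** q
        denom = u_q.sum(axis=0)
        v_new = np.where(denom > 0, (u_q * y[:, None]).sum(axis=0) / np.maximum(denom, 1e-300), v)
        delta = float(np.max(np.abs(v_new - v)))
        v = v_new
        history.append(objective(u, v))
        if delta < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"RFCM did not converge in {params.max_iter} iterations",
                      stacklevel=2)
    # final membership refresh so memberships correspond to the final centroids
    if beta == 0:
        u = _fcm_memberships(y, v, q)
    else:
        for p in (0, 1):
            rows = np.flatnonzero(parity == p)
            u_q = u ** q
            d = (y[rows, None] - v[None, :]) ** 2 + beta * penalty_matrix(u_q, rows)
            u[rows] = _memberships_from_distances(d, q)
    history.append(objective(u, v))

    order = np.argsort(v)
    v = v[order]
    u = u[:, order]
    full = np.zeros((K,) + wm_image.shape, dtype=np.float64)
    for k in range(K):
        full[k][mask] = u[:, k]
    return MembershipStack(memberships=full, mask=mask, centroids=v,
                           objective_history=history, converged=converged,
                           n_iter=it)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|) of two binary masks.

    Two empty masks agree vacuously (Dice 1).
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / total


def select_cluster(stack: MembershipStack, reference: Volume,
                   tau: float = 0.5) -> ClusterSelection:
    """Pick the cluster most similar to the fixed reference map.

    Candidate memberships and the reference are binarized at 0.5 and compared
    by Dice; the highest-Dice cluster wins, ties broken toward the highest
    centroid (lesions are the brightest WM compartment on FLAIR). An all-zero
    Dice vector signals an incompatible reference (mis-registration or empty
    clusters) and raises.
    """
    if reference.shape != stack.mask.shape:
        raise ValueError(f"reference shape {reference.shape} != {stack.mask.shape}")
    if reference.data.min() < 0 or reference.data.max() > 1:
        raise ValueError("reference values must lie in [0,1]")
    ref_bin = reference.data >= 0.5
    scores = np.array([dice(stack.memberships[k] >= 0.5, ref_bin)
                       for k in range(stack.K)])
    if np.all(scores == 0):
        raise ValueError("reference incompatible: all cluster Dice scores are 0")
    best = np.flatnonzero(scores == scores.max()).max()  # tie -> highest centroid
    thresholded = threshold_cluster(stack.memberships[best], tau)
    return ClusterSelection(selected_index=int(best), dice_scores=scores,
                            thresholded=thresholded)


def threshold_cluster(membership: np.ndarray | Volume, tau: float = 0.5) -> Volume:
    """Zero out low-confidence membership values (below tau); values at or
    above tau are kept as-is (float, not binarized)."""
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0,1), got {tau}")
    m = membership.data if isinstance(membership, Volume) else np.asarray(membership, float)
    if m.min() < 0 or m.max() > 1:
        raise ValueError("membership values must lie in [0,1]")
    return Volume(np.where(m < tau, 0.0, m))


def cluster_histogram_summary(membership: np.ndarray | Volume,
                              mask: np.ndarray) -> tuple[float, float]:
    """Fractions of in-mask membership values strictly below 0.2 and strictly
    above 0.8 — the shape QC used to sanity-check a selected cluster."""
    m = membership.data if isinstance(membership, Volume) else np.asarray(membership, float)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = m[mask]
    return float(np.mean(vals < 0.2)), float(np.mean(vals > 0.8))
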