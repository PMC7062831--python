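"""Two-group splitting of a mutually exclusive marker pair.

For one (reference, target) pair within one sample, the 2-D profile of a
cell is ``y = [b_ref + s_ref, b_tgt + s_tgt]`` with baseline
(autofluorescence) ``b`` and true signal ``s``. Mutual exclusivity means
at most one of the two signals is nonzero, so the point cloud decomposes
into a reference-positive arm, a target-positive arm, and a
double-negative blob near the origin. Because ``s >> b > 0``, a
reference-positive profile cannot be written as a positive combination of
profiles from the other two groups — the arms live in (approximately)
distinct rays, which is exactly the regime where self-expressive
(sparse subspace) and low-rank (NNMF) models separate the groups.

The default backend is sparse subspace clustering (SSC): each cell's
profile is reconstructed as a sparse non-trivial combination of the other
cells' profiles; cells sharing a ray reconstruct each other, so the
sparse coefficient matrix is (nearly) block diagonal and spectral
bipartition of its symmetrized magnitude recovers the groups. NNMF and a
Gaussian mixture are provided as cross-check backends.

Downstream code never depends on arbitrary cluster indices: the group
with the LOWER mean reference intensity is always relabeled 0
(reference-negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import SpectralClustering
from sklearn.linear_model import Lasso
from sklearn.mixture import GaussianMixture

from .errors import DegenerateInputError, InputError, NoPositiveCellsError, TooFewCellsError
from .io_config import FeatureTable

logger = logging.getLogger(__name__)

BACKENDS = ("ssc", "nnmf", "gmm")

#: Default relative L1 penalty for the self-expression lasso.
DEFAULT_SPARSITY = 0.05
#: Above this many cells, SSC clusters a seeded subsample and assigns the
#: rest to the nearest group centroid.
DEFAULT_MAX_CELLS = 2000
#: Minimum fold change between group means of the reference marker below
#: which the split is declared unreliable (no credible positive population).
DEFAULT_MIN_FOLD = 1.2


@dataclass
class PairSlice:
    """The n x 2 intensity slice of one (reference, target) pair.

    Column 0 is the reference marker, column 1 the target.
    """

    sample_id: str
    reference: str
    target: str
    Y: np.ndarray
    cell_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] != 2:
            raise InputError("PairSlice.Y must be an n x 2 matrix")
        if self.Y.shape[0] < 2:
            raise TooFewCellsError("PairSlice needs >= 2 cells")
        if not np.isfinite(self.Y).all() or (self.Y < 0).any():
            raise InputError("PairSlice intensities must be finite and >= 0")
        if self.cell_index is not None:
            self.cell_index = np.asarray(self.cell_index, dtype=object)
            if len(self.cell_index) != self.Y.shape[0]:
                raise InputError("cell_index length does not match Y")

    @classmethod
    def from_table(
        cls, table: FeatureTable, sample: str, reference: str, target: str
    ) -> "PairSlice":
        mask = table.sample_mask(sample)
        Y = np.column_stack([table.column(reference)[mask], table.column(target)[mask]])
        return cls(
            sample_id=sample,
            reference=reference,
            target=target,
            Y=Y,
            cell_index=table.cell_id[mask],
        )

    @property
    def n_cells(self) -> int:
        return self.Y.shape[0]


@dataclass
class GroupLabels:
    """Binary split of a PairSlice: 1 = reference-positive, 0 = reference-negative."""

    labels: np.ndarray
    backend: str
    n_subsampled: int = 0
    group_means: tuple[float, float] = (0.0, 0.0)  # (negative, positive) ref means

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise InputError("labels must be binary")
        if 0 not in self.labels or 1 not in self.labels:
            raise NoPositiveCellsError("both groups must be non-empty")

    @property
    def negative_mask(self) -> np.ndarray:
        return self.labels == 0

    @property
    def positive_mask(self) -> np.ndarray:
        return self.labels == 1


def ssc_coefficients(
    Y: np.ndarray,
    sparsity: float = DEFAULT_SPARSITY,
    max_iter: int = 2000,
    tol: float = 1e-3,
) -> np.ndarray:
    """Sparse self-expression coefficients: each cell's 2-D profile is
    regressed (lasso, zero self-coefficient) on all other cells' profiles.

    The exact self-expression constraint ``Y' = Y'C, diag(C) = 0`` is
    infeasible under noise; per standard SSC practice it is relaxed to a
    per-cell penalized least squares

        min_c  1/2 ||y_m - Y'_{-m} c||^2 + lambda_m ||c||_1

    with ``lambda_m = sparsity * max_{k != m} |y_m . y_k|``. Profiles are
    first scaled to unit L2 norm, per standard SSC practice: the clusters
    of interest are rays from the origin (an expression *direction*, not
    a magnitude), and without the normalization the lasso prefers
    high-magnitude cells as regressors for everyone, which strips the
    low-intensity double-negative cells of within-group connections.
    Normalization also makes C — and hence the downstream labels —
    exactly invariant to rescaling the slice. Coefficients are not
    sign-constrained: with non-negative profiles the L1 penalty does not
    select negative coefficients in practice.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if n < 3:
        raise TooFewCellsError(f"SSC needs >= 3 cells, got {n}")
    if sparsity <= 0:
        raise InputError("sparsity must be positive")
    norms = np.linalg.norm(Y, axis=1)
    Yn = np.divide(Y, norms[:, None], out=np.zeros_like(Y), where=norms[:, None] > 0)
    G = np.abs(Yn @ Yn.T)
    np.fill_diagonal(G, 0.0)
    C = np.zeros((n, n))
    # design matrix: columns are unit cell profiles (2 x n)
    X = Yn.T
    idx = np.arange(n)
    for m in range(n):
        lam = sparsity * G[m].max()
        if lam == 0.0:
            continue  # cell at the origin, or all others at the origin
        others = idx != m
        # sklearn's objective is 1/(2*n_samples) ||y-Xw||^2 + alpha ||w||_1
        # with n_samples = 2 here, so alpha = lambda / 2.
        # tol is loose: cells on a shared ray are near-collinear regressors,
        # where coordinate descent closes the last of the duality gap very
        # slowly without changing which cells carry the coefficient mass.
        model = Lasso(alpha=lam / 2.0, fit_intercept=False, max_iter=max_iter, tol=tol)
        model.fit(X[:, others], Yn[m])
        C[others, m] = model.coef_
    return C


def ssc_affinity(C: np.ndarray) -> np.ndarray:
    """Symmetrized coefficient magnitudes ``|C| + |C|^T`` with a tiny
    uniform floor so isolated cells (all-zero rows) stay connected."""
    A = np.abs(C) + np.abs(C).T
    A += 1e-10
    np.fill_diagonal(A, 0.0)
    return A


def nnmf_factorize(
    Y: np.ndarray,
    rank: int = 2,
    seed: int = 0,
    n_iter: int = 300,
    n_restarts: int = 3,
    return_trace: bool = False,
):
    """Rank-2 non-negative factorization ``Y ~ W H`` by multiplicative
    updates with seeded random restarts.

    On an n x 2 profile matrix the unconstrained problem has the trivial
    solution ``W = Y, H = I``; random (hence off-identity) initialization
    of H plus restarts steers the updates toward factors aligned with the
    two expression arms instead. The best restart by Frobenius
    reconstruction error wins. With ``return_trace=True`` also returns
    the per-iteration error trace of the winning restart (the
    multiplicative updates are monotonically non-increasing in it).
    """
    Y = np.asarray(Y, dtype=float)
    if (Y < 0).any():
        raise InputError("NNMF requires non-negative input")
    if not Y.any():
        raise DegenerateInputError("all-zero matrix")
    n, d = Y.shape
    eps = 1e-12
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        scale = np.sqrt(Y.mean() / rank)
        W = rng.uniform(0.1, 1.0, size=(n, rank)) * scale
        H = rng.uniform(0.1, 1.0, size=(rank, d)) * scale
        trace = []
        for _ in range(n_iter):
            H *= (W.T @ Y) / (W.T @ W @ H + eps)
            W *= (Y @ H.T) / (W @ H @ H.T + eps)
            trace.append(float(np.linalg.norm(Y - W @ H)))
        err = trace[-1]
        if best is None or err < best[0]:
            best = (err, W, H, trace)
    _, W, H, trace = best
    if return_trace:
        return W, H, np.asarray(trace)
    return W, H


def split_two_groups(
    pair: PairSlice,
    backend: str = "ssc",
    seed: int = 0,
    sparsity: float = DEFAULT_SPARSITY,
    max_cells: int = DEFAULT_MAX_CELLS,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> GroupLabels:
    """Split the cells of a pair slice into reference-positive and
    reference-negative groups.

    The raw backend clustering is label-agnostic; the group with the
    lower mean reference intensity is relabeled 0 (reference-negative).
    If the two group means differ by less than ``min_fold`` the split
    carries no evidence of a positive population and
    :class:`NoPositiveCellsError` is raised — a marker without positive
    cells in a sample is skipped rather than normalized against noise.

    For ``backend='ssc'`` with more than ``max_cells`` cells, a seeded
    uniform subsample is clustered and the remaining cells are assigned
    to the nearest group centroid in the 2-D profile (SSC cost is
    quadratic in n; sections routinely carry 10^4-10^5 cells).
    """
    if backend not in BACKENDS:
        raise InputError(f"unknown backend {backend!r}; choose from {BACKENDS}")
    Y = pair.Y
    n = Y.shape[0]
    if n < 3:
        raise TooFewCellsError(f"need >= 3 cells to split, got {n}")
    if np.allclose(Y, Y[0]):
        raise NoPositiveCellsError("all cells identical: nothing to split")

    n_subsampled = 0
    if backend == "ssc" and n > max_cells:
        rng = np.random.default_rng(seed)
        sub = np.sort(rng.choice(n, size=max_cells, replace=False))
        raw_sub = _cluster_binary(Y[sub], backend, seed, sparsity)
        centroids = np.stack([Y[sub][raw_sub == g].mean(axis=0) for g in (0, 1)])
        d = np.linalg.norm(Y[:, None, :] - centroids[None, :, :], axis=2)
        raw = np.argmin(d, axis=1)
        raw[sub] = raw_sub  # clustered cells keep their direct labels
        n_subsampled = max_cells
    else:
        raw = _cluster_binary(Y, backend, seed, sparsity)

    return _orient_labels(Y, raw, backend, n_subsampled, min_fold)


def _cluster_binary(Y: np.ndarray, backend: str, seed: int, sparsity: float) -> np.ndarray:
    if backend == "ssc":
        C = ssc_coefficients(Y, sparsity=sparsity)
        A = ssc_affinity(C)
        # The pair slice holds up to three natural groups (two expression
        # arms plus double-negatives), and a forced bipartition of a
        # three-block affinity can shear the weakly connected block in
        # half. Cluster into three and merge down to two at the widest
        # gap in mean reference intensity: clusters sharing a background
        # level reunite, and an arm over-split by k=3 reunites likewise.
        k = 3 if Y.shape[0] >= 6 else 2
        model = SpectralClustering(
            n_clusters=k, affinity="precomputed", random_state=seed, n_init=10
        )
        lab = model.fit_predict(A)
        return _merge_to_two(Y, lab)
    if backend == "nnmf":
        W, H = nnmf_factorize(Y, rank=2, seed=seed)
        # make factor loadings comparable: fold each basis row's scale into W
        loads = W * np.linalg.norm(H, axis=1)
        # Double-negative cells load near-equally on both factors, so a raw
        # per-cell argmax scatters them across the two groups; instead the
        # 1-D factor-dominance share is split at its widest gap, which keeps
        # each blob of similar cells together on one side.
        share = loads[:, 0] / np.maximum(loads.sum(axis=1), 1e-12)
        order = np.argsort(share)
        gaps = np.diff(share[order])
        cut = int(np.argmax(gaps))
        labels = np.zeros(len(share), dtype=int)
        labels[order[cut + 1 :]] = 1
        return labels
    # gmm
    model = GaussianMixture(
        n_components=2, covariance_type="full", random_state=seed, n_init=3
    )
    return model.fit_predict(Y)


def _merge_to_two(Y: np.ndarray, lab: np.ndarray) -> np.ndarray:
    """Merge a k-way clustering into two groups, splitting the sorted
    cluster means of the reference marker at their widest gap."""
    clusters = np.unique(lab)
    if len(clusters) <= 2:
        return (lab == clusters[-1]).astype(int)
    means = np.array([Y[lab == c, 0].mean() for c in clusters])
    order = np.argsort(means)
    cut = int(np.argmax(np.diff(means[order])))
    hi = clusters[order[cut + 1 :]]
    return np.isin(lab, hi).astype(int)


def _orient_labels(
    Y: np.ndarray, raw: np.ndarray, backend: str, n_subsampled: int, min_fold: float
) -> GroupLabels:
    if len(np.unique(raw)) < 2:
        raise NoPositiveCellsError("clustering produced a single group")
    means = np.array([Y[raw == g, 0].mean() for g in (0, 1)])
    lo, hi = np.argsort(means)
    if means[lo] <= 0:
        fold = np.inf if means[hi] > 0 else 1.0
    else:
        fold = means[hi] / means[lo]
    if fold < min_fold:
        raise NoPositiveCellsError(
            f"group reference means {means[lo]:.4g} vs {means[hi]:.4g} differ by "
            f"less than {min_fold}x: no credible positive population"
        )
    labels = (raw == hi).astype(int)
    return GroupLabels(
        labels=labels,
        backend=backend,
        n_subsampled=n_subsampled,
        group_means=(float(means[lo]), float(means[hi])),
    )
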