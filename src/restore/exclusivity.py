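"""Data-driven scoring of mutually exclusive marker pairs.

Two markers are mutually exclusive when no cell expresses both: the joint
scatter of their per-cell mean intensities hugs the two axes (an
"L shape"). Stacking the two raw, uncentered intensity columns into
``D in R^{n x 2}`` and taking its singular values ``sigma1 >= sigma2``,
the ratio ``r = sigma2 / sigma1`` measures how far D is from rank one:
correlated markers give an elongated ellipse through the origin
(``r -> 0``), mutually exclusive markers spread mass onto both principal
axes (``r -> 1``). Columns are deliberately NOT centered or standardized —
the geometry is an ellipse anchored at the origin of intensity space, and
centering would destroy that interpretation.

The ratio alone does not distinguish a true L shape from isotropic
uncorrelated noise; it is a ranking and QC statistic, meant to be
cross-checked against biologically curated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InputError
from .io_config import FeatureTable

#: Relative sigma2/sigma1 below which a pair is reported as exactly rank-1.
_RANK1_RTOL = 1e-12


@dataclass(frozen=True)
class ExclusivityScore:
    """Mutual-exclusivity score of one marker pair.

    ``ratio`` is the singular-value ratio sigma2/sigma1 in [0, 1];
    ``n_cells`` is the number of cells it was computed on.
    """

    marker_i: str
    marker_j: str
    ratio: float
    n_cells: int


def exclusivity_ratio(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Singular-value ratio sigma2/sigma1 of the uncentered n x 2 matrix
    ``D = [x_i, x_j]``.

    Returns a float in [0, 1]; exactly-rank-1 pairs (e.g. identical or
    proportional columns) return 0. Optionally apply ``np.log1p`` to the
    columns *before* calling if log-scale geometry is wanted; nothing is
    transformed here.

    Raises
    ------
    InputError
        On length mismatch, length < 2, or negative/non-finite entries.
    DegenerateInputError
        If both columns are entirely zero.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.ndim != 1 or x_j.ndim != 1:
        raise InputError("inputs must be 1-D intensity vectors")
    if x_i.shape != x_j.shape:
        raise InputError(f"length mismatch: {x_i.size} vs {x_j.size}")
    if x_i.size < 2:
        raise InputError("need at least 2 cells")
    for v in (x_i, x_j):
        if not np.isfinite(v).all() or (v < 0).any():
            raise InputError("intensities must be finite and non-negative")
    if not (x_i.any() or x_j.any()):
        raise DegenerateInputError("both columns are all zero")
    D = np.column_stack([x_i, x_j])
    s = np.linalg.svd(D, compute_uv=False)
    if s[1] <= s[0] * _RANK1_RTOL:
        return 0.0
    # sigma2 <= sigma1 by construction; clip guards rounding at the top end
    return float(min(s[1] / s[0], 1.0))


def rank_exclusive_pairs(
    table: FeatureTable,
    reference: str,
    top_k: int = 5,
    log1p: bool = False,
    per_sample: bool = False,
) -> list[ExclusivityScore]:
    """Rank candidate mutually exclusive partners for one reference marker.

    Scores every other marker against ``reference`` on the pooled cells
    (default) and returns the ``top_k`` pairs by descending ratio, ties
    broken by marker name. With ``per_sample=True`` the ratio is computed
    within each sample and the median across samples is ranked instead,
    which is robust to batch effects leaking into the pooled geometry.
    """
    if top_k < 1:
        raise InputError("top_k must be >= 1")
    ref_idx = table.marker_index(reference)
    transform = np.log1p if log1p else (lambda v: v)
    x_ref = transform(table.intensities[:, ref_idx])
    scores = []
    for j, marker in enumerate(table.markers):
        if j == ref_idx:
            continue
        x_j = transform(table.intensities[:, j])
        if per_sample:
            ratios = []
            for sample in table.samples:
                mask = table.sample_id == sample
                if mask.sum() < 2:
                    continue
                ratios.append(_safe_ratio(x_ref[mask], x_j[mask]))
            ratio = float(np.median(ratios)) if ratios else 0.0
        else:
            ratio = _safe_ratio(x_ref, x_j)
        scores.append(
            ExclusivityScore(
                marker_i=reference, marker_j=marker, ratio=ratio, n_cells=table.n_cells
            )
        )
    scores.sort(key=lambda s: (-s.ratio, s.marker_j))
    return scores[:top_k]


def exclusivity_matrix(table: FeatureTable, log1p: bool = False) -> np.ndarray:
    """Full symmetric m x m matrix of pairwise exclusivity ratios.

    The diagonal is 0 by convention: a marker paired with itself is
    exactly rank-1, i.e. maximally non-exclusive.
    """
    m = table.n_markers
    transform = np.log1p if log1p else (lambda v: v)
    cols = [transform(table.intensities[:, j]) for j in range(m)]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = _safe_ratio(cols[i], cols[j])
    return out


def _safe_ratio(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """exclusivity_ratio, mapping the all-zero degenerate case to 0."""
    try:
        return exclusivity_ratio(x_i, x_j)
    except DegenerateInputError:
        return 0.0
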