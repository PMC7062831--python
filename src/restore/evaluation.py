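"""Replicate-concordance metrics and the quantile-normalization baseline.

Adjacent tissue sections are near-technical replicates: whatever
threshold or clustering is applied, the resulting cell-type composition
should agree across them. Batch effects break that agreement, so
composition concordance across replicate sections is the evaluation
currency here:

* Pearson correlation of per-section composition vectors (fractions of
  marker-positive cells, or of k-means cluster membership);
* coefficient of variation ``c_v = sigma / mu`` of positive-cell counts
  across the sections of a group (relative standard deviation — the
  standard repeatability measure in analytical chemistry);
* side-by-side "local" (per-section background) vs "global" (pooled
  background) gating — when there is no intensity variation the two
  agree, and their divergence exposes the batch effect;
* k-means composition concordance on raw vs normalized intensities.

A percentile-window quantile normalization is included purely as a
baseline comparator: it aligns each sample's [P1, P99] intensity window
onto the pooled window, which misbehaves when samples genuinely differ
in their positive populations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .background import infer_all_backgrounds, normalize, positive_fractions
from .errors import InputError, UndefinedStatisticError
from .io_config import FeatureTable, PairConfig

logger = logging.getLogger(__name__)


@dataclass
class CompositionVector:
    """Per-sample composition over a fixed category set (marker-positive
    classes or cluster IDs)."""

    sample_id: str
    categories: list[str]
    counts: np.ndarray
    total_cells: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise InputError("counts must be non-negative")
        if len(self.counts) != len(self.categories):
            raise InputError("counts and categories must align")

    @property
    def fractions(self) -> np.ndarray:
        if self.total_cells == 0:
            raise UndefinedStatisticError("composition of an empty sample")
        return self.counts / self.total_cells


@dataclass
class ReplicateGroup:
    """Samples treated as near-technical replicates (e.g. adjacent
    sections of one TMA core)."""

    group_id: str
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) < 2:
            raise InputError(f"group {self.group_id!r} needs >= 2 samples")


def composition_correlation(
    a: CompositionVector, b: CompositionVector, method: str = "pearson"
) -> float:
    """Correlation of two composition-fraction vectors.

    Fractions, not raw counts, are compared so that section-area
    differences do not masquerade as discordance. Pearson by default
    (``method='spearman'`` for ranks); undefined for fewer than two
    categories or zero-variance vectors.
    """
    if a.categories != b.categories:
        raise InputError("composition vectors have different category sets")
    if len(a.categories) < 2:
        raise UndefinedStatisticError("correlation needs >= 2 categories")
    x, y = a.fractions, b.fractions
    if method == "spearman":
        x = pd.Series(x).rank().to_numpy()
        y = pd.Series(y).rank().to_numpy()
    elif method != "pearson":
        raise InputError(f"unknown correlation method {method!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero-variance composition vector")
    return float(np.corrcoef(x, y)[0, 1])


def coefficient_of_variation(counts) -> float:
    """Relative standard deviation sigma/mu of per-replicate counts,
    with the sample standard deviation (ddof=1): a handful of sections
    is a sample, not a population."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise InputError("need >= 2 replicates")
    mu = counts.mean()
    if mu == 0:
        raise UndefinedStatisticError("zero-mean counts: c_v undefined")
    return float(counts.std(ddof=1) / mu)


def _marker_compositions(
    table: FeatureTable, normalized: FeatureTable, threshold: float = 1.0
) -> dict[str, CompositionVector]:
    fracs = positive_fractions(normalized, threshold)
    out = {}
    for sample, f in fracs.items():
        n = int((table.sample_id == sample).sum())
        out[sample] = CompositionVector(
            sample_id=sample,
            categories=list(table.markers),
            counts=np.round(f * n),
            total_cells=n,
        )
    return out


def local_vs_global_report(
    table: FeatureTable,
    groups: list[ReplicateGroup],
    pairs: PairConfig,
    backend: str = "ssc",
    method: str = "percentile",
    threshold: float = 1.0,
    seed: int = 0,
    **infer_kwargs,
) -> pd.DataFrame:
    """Composition concordance under per-section vs pooled backgrounds.

    The default background statistic here is the 99th percentile (a
    robust max), not the mean used for rescaling: gating counts a cell
    positive above the background level, so the threshold must sit at
    the top of the negative distribution, not at its center.

    For each mode, backgrounds are inferred, cells gated at
    ``threshold``, and per-sample marker-positive composition vectors
    built; the report contains every pairwise correlation within each
    replicate group and the per-marker coefficient of variation of
    positive counts. Long format: columns group_id, mode, statistic
    (``pairwise_r`` | ``cv``), item (sample pair or marker), value.
    Undefined statistics are emitted as NaN.
    """
    records = []
    for mode in ("local", "global"):
        estimates = infer_all_backgrounds(
            table, pairs, mode=mode, backend=backend, method=method, seed=seed,
            **infer_kwargs,
        )
        normalized = normalize(table, estimates)
        comps = _marker_compositions(table, normalized, threshold)
        for grp in groups:
            for s1, s2 in itertools.combinations(grp.sample_ids, 2):
                try:
                    r = composition_correlation(comps[s1], comps[s2])
                except UndefinedStatisticError:
                    r = np.nan
                records.append(
                    {
                        "group_id": grp.group_id,
                        "mode": mode,
                        "statistic": "pairwise_r",
                        "item": f"{s1}|{s2}",
                        "value": r,
                    }
                )
            for j, marker in enumerate(table.markers):
                counts = [comps[s].counts[j] for s in grp.sample_ids]
                try:
                    cv = coefficient_of_variation(counts)
                except UndefinedStatisticError:
                    cv = np.nan
                records.append(
                    {
                        "group_id": grp.group_id,
                        "mode": mode,
                        "statistic": "cv",
                        "item": marker,
                        "value": cv,
                    }
                )
    return pd.DataFrame.from_records(records)


def kmeans_concordance(
    table: FeatureTable,
    groups: list[ReplicateGroup],
    k_values: tuple[int, ...] = (5, 10, 15, 20),
    seed: int = 0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Cluster-composition concordance across replicate sections.

    Cells of each group's samples are pooled, k-means (k-means++ with 10
    restarts, seeded) is run on the all-marker profiles, and per-sample
    cluster-membership composition vectors are correlated pairwise. Run
    once on the raw table and once on a normalized table to quantify how
    much of the clustering reflects batch rather than biology. Markers
    are standardized (z-score on the pooled cells) before clustering by
    default so no single high-intensity channel dominates the Euclidean
    metric.

    Long format: group_id, k, pair, r.
    """
    records = []
    for grp in groups:
        mask = np.isin(table.sample_id, grp.sample_ids)
        X = table.intensities[mask]
        samples = table.sample_id[mask]
        if standardize:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - X.mean(axis=0)) / sd
        for k in k_values:
            if k >= X.shape[0]:
                raise InputError(f"k={k} >= number of pooled cells ({X.shape[0]})")
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            labels = km.fit_predict(X)
            comps = {}
            for s in grp.sample_ids:
                counts = np.bincount(labels[samples == s], minlength=k)
                comps[s] = CompositionVector(
                    sample_id=s,
                    categories=[f"cluster_{i}" for i in range(k)],
                    counts=counts,
                    total_cells=int(counts.sum()),
                )
            for s1, s2 in itertools.combinations(grp.sample_ids, 2):
                try:
                    r = composition_correlation(comps[s1], comps[s2])
                except UndefinedStatisticError:
                    r = np.nan
                records.append(
                    {"group_id": grp.group_id, "k": k, "pair": f"{s1}|{s2}", "r": r}
                )
    return pd.DataFrame.from_records(records)


def quantile_normalize(
    table: FeatureTable, lower_pct: float = 1.0, upper_pct: float = 99.0
) -> FeatureTable:
    """Percentile-window alignment baseline.

    Per marker, each sample's [P_lower, P_upper] intensity window is
    mapped affinely onto the pooled window (values outside the window
    follow the same affine map; results are clipped at 0 to keep the
    table valid). A degenerate per-sample window (P_lower = P_upper) is
    skipped with a warning. This comparator inherits quantile
    normalization's known failure mode: a sample lacking positives for a
    marker has its negatives stretched up to the pooled positive range.
    """
    if len(table.samples) < 2:
        return table.with_intensities(table.intensities.copy())
    values = table.intensities.copy()
    for j in range(table.n_markers):
        pooled = table.intensities[:, j]
        lo_ref, hi_ref = np.percentile(pooled, [lower_pct, upper_pct])
        if hi_ref == lo_ref:
            logger.warning(
                "marker %s: degenerate pooled window; skipped", table.markers[j]
            )
            continue
        for sample in table.samples:
            mask = table.sample_id == sample
            lo, hi = np.percentile(table.intensities[mask, j], [lower_pct, upper_pct])
            if hi == lo:
                logger.warning(
                    "marker %s sample %s: degenerate window; skipped",
                    table.markers[j], sample,
                )
                continue
            scaled = lo_ref + (table.intensities[mask, j] - lo) * (hi_ref - lo_ref) / (
                hi - lo
            )
            values[mask, j] = np.clip(scaled, 0.0, None)
    return table.with_intensities(values)
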