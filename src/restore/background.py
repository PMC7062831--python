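"""Background inference and intensity normalization — the heart of the method.

A measured single-cell intensity is modeled as ``y = G (b + s)``: a
per-(sample, marker) multiplicative gain G (fixation, exposure, antibody
lot, batch — every technical nuisance lumped into one factor) applied to
the sum of a baseline/autofluorescence level b and the true signal s
(zero for negative cells). Cells positive for a mutually exclusive
partner marker are guaranteed negative for the reference marker, so
their reference-channel intensities measure ``B = G * b`` directly.

The per-sample background estimate ``B_bar`` is read off the
reference-negative group found by :func:`restore.grouping.split_two_groups`
and every intensity is divided by it:

    y_norm = y / B_bar = (b + s) / b_bar

The gain cancels exactly, so normalized intensities are comparable
across samples and batches. With the ``max`` statistic every truly
negative cell lands at <= 1 and positive cells above 1, making 1.0 a
natural gating threshold. The normalization preserves true signal ratios
in the high signal-to-baseline (SBR) regime and is knowingly distorted
when signals sit close to the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import CannotInferError, InputError, NoPositiveCellsError
from .grouping import (
    DEFAULT_MAX_CELLS,
    DEFAULT_MIN_FOLD,
    DEFAULT_SPARSITY,
    PairSlice,
    split_two_groups,
)
from .io_config import FeatureTable, PairConfig

logger = logging.getLogger(__name__)

METHODS = ("mean", "max", "percentile")

#: Pseudo sample id used for estimates computed on pooled cells.
GLOBAL_SAMPLE = "__global__"


@dataclass
class BackgroundEstimate:
    """Inferred background level for one (sample, reference marker).

    ``B_bar`` is in the same (arbitrary fluorescence) units as the input
    intensities and absorbs the sample gain: B_bar = G * b_bar.
    ``signal_estimate`` is the diagnostic mean positive-minus-negative
    reference intensity (an estimate of G * mean signal), combined across
    targets like ``B_bar``.
    """

    sample_id: str
    reference: str
    targets_used: list[str]
    B_bar: float
    method: str
    n_negative: int
    percentile: float | None = None
    signal_estimate: float | None = None
    per_target: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InputError(f"unknown method {self.method!r}; choose from {METHODS}")
        if not self.B_bar > 0:
            raise InputError("B_bar must be positive")
        if self.n_negative < 1:
            raise InputError("n_negative must be >= 1")


def background_statistic(
    values: np.ndarray, method: str = "mean", percentile: float = 99.0
) -> float:
    """Summary of the reference intensities of the negative group.

    ``mean`` matches the expectation-based identities of the model;
    ``max`` yields the clean <= 1 bound on negative cells after
    normalization but is outlier-sensitive; ``percentile`` (default 99)
    is a robust max.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InputError("empty negative group")
    if method == "mean":
        return float(values.mean())
    if method == "max":
        return float(values.max())
    if method == "percentile":
        return float(np.percentile(values, percentile))
    raise InputError(f"unknown method {method!r}; choose from {METHODS}")


def infer_background(
    table: FeatureTable,
    sample: str,
    reference: str,
    targets: list[str] | str,
    backend: str = "ssc",
    method: str = "mean",
    percentile: float = 99.0,
    seed: int = 0,
    sparsity: float = DEFAULT_SPARSITY,
    max_cells: int = DEFAULT_MAX_CELLS,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> BackgroundEstimate:
    """Infer the background level of one reference marker in one sample.

    For each mutually exclusive target, the (reference, target) slice is
    split into two groups and the chosen statistic of the reference
    intensities in the reference-negative group gives a per-target
    background. The final ``B_bar`` is the median across targets: a
    single corrupted target (non-specific staining makes a pair
    positively correlated) cannot drag the estimate, which is why more
    than one exclusive partner makes the inference robust.

    Targets whose split raises :class:`NoPositiveCellsError` are skipped
    with a warning; if every target fails, :class:`CannotInferError` is
    raised. A background of exactly zero (all negatives at zero) is
    floored at half the smallest positive intensity of the column so
    that division is always defined.
    """
    if isinstance(targets, str):
        targets = [targets]
    if not targets:
        raise InputError("need at least one target marker")
    per_target: dict[str, float] = {}
    per_target_n: dict[str, int] = {}
    per_target_signal: dict[str, float] = {}
    for target in targets:
        try:
            pair = PairSlice.from_table(table, sample, reference, target)
            labels = split_two_groups(
                pair,
                backend=backend,
                seed=seed,
                sparsity=sparsity,
                max_cells=max_cells,
                min_fold=min_fold,
            )
        except NoPositiveCellsError as exc:
            logger.warning(
                "sample %s reference %s target %s: split unreliable (%s); skipping",
                sample, reference, target, exc,
            )
            continue
        neg = pair.Y[labels.negative_mask, 0]
        per_target[target] = background_statistic(neg, method, percentile)
        per_target_n[target] = int(neg.size)
        pos = pair.Y[labels.positive_mask, 0]
        per_target_signal[target] = float(pos.mean() - neg.mean())
    if not per_target:
        raise CannotInferError(
            f"no target of reference {reference!r} in sample {sample!r} yielded a "
            "usable negative-control group"
        )
    values = np.array(list(per_target.values()))
    B_bar = float(np.median(values))
    # n_negative reported for the target whose estimate sits at the median
    median_target = min(per_target, key=lambda t: (abs(per_target[t] - B_bar), t))
    n_negative = per_target_n[median_target]
    if B_bar <= 0:
        col = table.column(reference)[table.sample_mask(sample)]
        positive = col[col > 0]
        if positive.size == 0:
            raise CannotInferError(
                f"reference {reference!r} is identically zero in sample {sample!r}"
            )
        B_bar = 0.5 * float(positive.min())
        logger.warning(
            "sample %s reference %s: background computed to 0; floored at %.4g",
            sample, reference, B_bar,
        )
    return BackgroundEstimate(
        sample_id=sample,
        reference=reference,
        targets_used=sorted(per_target),
        B_bar=B_bar,
        method=method,
        percentile=percentile if method == "percentile" else None,
        n_negative=n_negative,
        signal_estimate=float(np.median(list(per_target_signal.values()))),
        per_target=per_target,
    )


def infer_all_backgrounds(
    table: FeatureTable,
    pairs: PairConfig,
    mode: str = "local",
    backend: str = "ssc",
    method: str = "mean",
    percentile: float = 99.0,
    seed: int = 0,
    sparsity: float = DEFAULT_SPARSITY,
    max_cells: int = DEFAULT_MAX_CELLS,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> list[BackgroundEstimate]:
    """Backgrounds for every (sample, reference) combination in the config.

    ``mode='local'`` infers within each sample separately — the proper
    per-batch correction. ``mode='global'`` pools all samples' cells,
    infers one background per reference, and applies it to every sample;
    it exists as the comparison arm that exposes batch effects (a global
    threshold is exactly what per-sample gains break).

    References that cannot be inferred for a sample are skipped with a
    warning and simply yield no estimate.
    """
    if mode not in ("local", "global"):
        raise InputError("mode must be 'local' or 'global'")
    pairs.validate_against(table)
    kwargs = dict(
        backend=backend, method=method, percentile=percentile, seed=seed,
        sparsity=sparsity, max_cells=max_cells, min_fold=min_fold,
    )
    estimates: list[BackgroundEstimate] = []
    if mode == "local":
        for sample in table.samples:
            for reference in pairs.references:
                try:
                    estimates.append(
                        infer_background(
                            table, sample, reference, pairs.targets(reference), **kwargs
                        )
                    )
                except CannotInferError as exc:
                    logger.warning("skipping: %s", exc)
    else:
        pooled = FeatureTable(
            cell_id=np.array(
                [f"{s}:{c}" for s, c in zip(table.sample_id, table.cell_id)],
                dtype=object,
            ),
            sample_id=np.full(table.n_cells, GLOBAL_SAMPLE, dtype=object),
            markers=table.markers,
            intensities=table.intensities,
        )
        for reference in pairs.references:
            try:
                est = infer_background(
                    pooled, GLOBAL_SAMPLE, reference, pairs.targets(reference), **kwargs
                )
            except CannotInferError as exc:
                logger.warning("skipping: %s", exc)
                continue
            for sample in table.samples:
                estimates.append(
                    BackgroundEstimate(
                        sample_id=sample,
                        reference=reference,
                        targets_used=est.targets_used,
                        B_bar=est.B_bar,
                        method=est.method,
                        percentile=est.percentile,
                        n_negative=est.n_negative,
                        signal_estimate=est.signal_estimate,
                        per_target=est.per_target,
                    )
                )
    return estimates


def normalize(
    table: FeatureTable,
    backgrounds: list[BackgroundEstimate],
    strict: bool = False,
) -> FeatureTable:
    """Divide each (sample, marker) column by its inferred background.

    Output values are unitless multiples of the background level; the
    per-sample gain cancels, and within a (sample, marker) the ranking
    of cells is preserved exactly. Markers without an estimate for a
    sample are passed through unchanged and logged (error in strict
    mode).
    """
    lookup: dict[tuple[str, str], BackgroundEstimate] = {}
    for est in backgrounds:
        key = (est.sample_id, est.reference)
        if key in lookup:
            raise InputError(f"duplicate background estimate for {key}")
        lookup[key] = est
    values = table.intensities.copy()
    for sample in table.samples:
        mask = table.sample_id == sample
        for j, marker in enumerate(table.markers):
            est = lookup.get((sample, marker))
            if est is None:
                msg = f"no background estimate for sample {sample!r} marker {marker!r}"
                if strict:
                    raise InputError(msg)
                logger.info("%s; passing through unnormalized", msg)
                continue
            values[mask, j] /= est.B_bar
    return table.with_intensities(values)


def call_positive(normalized: FeatureTable, threshold: float = 1.0) -> np.ndarray:
    """Binary cells x markers positivity matrix: positive iff the
    normalized intensity strictly exceeds ``threshold``.

    After normalization the background level sits at 1, so 1.0 is the
    natural gate. The inequality is strict: a cell exactly at background
    is not evidence of signal.
    """
    if not threshold > 0:
        raise InputError("threshold must be positive")
    return normalized.intensities > threshold


def positive_fractions(normalized: FeatureTable, threshold: float = 1.0):
    """Per-sample fraction of positive cells for each marker.

    Returns a dict sample_id -> vector of fractions (marker order of the
    table).
    """
    calls = call_positive(normalized, threshold)
    out = {}
    for sample in normalized.samples:
        mask = normalized.sample_id == sample
        out[sample] = calls[mask].mean(axis=0)
    return out
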