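"""Feature tables and pair configurations: containers, validation, I/O.

The universal currency of the pipeline is the :class:`FeatureTable` — one
row per segmented cell, one column per marker, values are non-negative
mean fluorescence intensities on a linear scale (no log transform is ever
applied implicitly). Tables are stored as CSV with a ``cell_id`` and a
``sample_id`` column located by name; lines starting with ``#`` are
treated as comments so pipeline outputs can embed their run configuration.

A :class:`PairConfig` maps each *reference* marker to the *target* markers
known (biologically or data-driven) to be mutually exclusive with it; the
target-positive cells serve as negative controls when inferring the
reference marker's background level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, IntegrityError

logger = logging.getLogger(__name__)

#: Required identifier columns, located by name (not position).
ID_COLUMNS = ("cell_id", "sample_id")


@dataclass
class FeatureTable:
    """Cells x markers matrix of non-negative mean intensities.

    Parameters
    ----------
    cell_id
        Per-row cell identifier, unique within a sample.
    sample_id
        Per-row sample/section/batch identifier.
    markers
        Ordered marker names, one per intensity column.
    intensities
        ``(n_cells, n_markers)`` float array, finite and >= 0.
    """

    cell_id: np.ndarray
    sample_id: np.ndarray
    markers: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id, dtype=object)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.markers = list(self.markers)
        self.intensities = np.asarray(self.intensities, dtype=float)
        validate_feature_table(self)

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_markers(self) -> int:
        return self.intensities.shape[1]

    @property
    def samples(self) -> list[str]:
        """Sample identifiers in order of first appearance."""
        return list(pd.unique(self.sample_id))

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise IntegrityError(f"marker {marker!r} not in table") from None

    def column(self, marker: str) -> np.ndarray:
        return self.intensities[:, self.marker_index(marker)]

    def sample_mask(self, sample: str) -> np.ndarray:
        mask = self.sample_id == sample
        if not mask.any():
            raise IntegrityError(f"sample {sample!r} not in table")
        return mask

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        """Row subset (boolean mask or integer index)."""
        return FeatureTable(
            cell_id=self.cell_id[mask],
            sample_id=self.sample_id[mask],
            markers=self.markers,
            intensities=self.intensities[mask],
        )

    def with_intensities(self, intensities: np.ndarray) -> "FeatureTable":
        """Same cells/markers, new intensity matrix."""
        return FeatureTable(
            cell_id=self.cell_id.copy(),
            sample_id=self.sample_id.copy(),
            markers=list(self.markers),
            intensities=intensities,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.markers)
        df.insert(0, "sample_id", self.sample_id)
        df.insert(0, "cell_id", self.cell_id)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, drop_bad_rows: bool = False) -> "FeatureTable":
        missing = [c for c in ID_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        markers = [c for c in df.columns if c not in ID_COLUMNS]
        if len(markers) < 2:
            raise FormatError(
                f"need >= 2 marker columns, found {len(markers)}: {markers}"
            )
        if len(df) == 0:
            raise IntegrityError("empty table: no cells")
        try:
            values = df[markers].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric marker values: {exc}") from exc
        bad = ~np.isfinite(values) | (values < 0)
        bad_rows = bad.any(axis=1)
        if bad_rows.any():
            if not drop_bad_rows:
                raise IntegrityError(
                    f"{int(bad_rows.sum())} row(s) with negative or non-finite "
                    "intensities (pass drop_bad_rows=True to drop them)"
                )
            logger.warning("dropping %d row(s) with invalid intensities", int(bad_rows.sum()))
            df = df.loc[~bad_rows]
            values = values[~bad_rows]
            if len(df) == 0:
                raise IntegrityError("empty table after dropping invalid rows")
        return cls(
            cell_id=df["cell_id"].astype(str).to_numpy(dtype=object),
            sample_id=df["sample_id"].astype(str).to_numpy(dtype=object),
            markers=markers,
            intensities=values,
        )


def validate_feature_table(table: FeatureTable) -> None:
    """Enforce the table invariants; raise :class:`IntegrityError` on violation."""
    n = table.intensities.shape[0]
    if table.intensities.ndim != 2:
        raise IntegrityError("intensities must be a 2-D matrix")
    if n == 0:
        raise IntegrityError("empty table: no cells")
    if len(table.markers) < 2:
        raise IntegrityError(f"need >= 2 markers, got {len(table.markers)}")
    if len(set(table.markers)) != len(table.markers):
        raise IntegrityError("duplicate marker names")
    if table.intensities.shape[1] != len(table.markers):
        raise IntegrityError("marker count does not match intensity columns")
    if len(table.cell_id) != n or len(table.sample_id) != n:
        raise IntegrityError("identifier arrays do not match intensity rows")
    if not np.isfinite(table.intensities).all():
        raise IntegrityError("non-finite intensity values")
    if (table.intensities < 0).any():
        raise IntegrityError("negative intensity values")
    key = pd.MultiIndex.from_arrays([table.sample_id, table.cell_id])
    if key.has_duplicates:
        dup = key[key.duplicated()][0]
        raise IntegrityError(f"duplicate (sample_id, cell_id): {tuple(dup)}")


def read_feature_table(path: str | Path, drop_bad_rows: bool = False) -> FeatureTable:
    """Read a CSV feature table.

    The header must contain ``cell_id``, ``sample_id`` and at least two
    marker columns. Rows with negative or non-finite marker values raise
    :class:`IntegrityError` unless ``drop_bad_rows`` is set, in which case
    they are dropped and counted in the log.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", dtype={"cell_id": str, "sample_id": str})
    except pd.errors.EmptyDataError:
        raise IntegrityError(f"empty file: {path}") from None
    return FeatureTable.from_dataframe(df, drop_bad_rows=drop_bad_rows)


def write_feature_table(
    table: FeatureTable, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a CSV feature table (floats at 17 significant digits, so a
    round-trip reproduces the matrix to full double precision)."""
    path = Path(path)
    df = table.to_dataframe()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


@dataclass
class PairConfig:
    """Reference marker -> ordered mutually exclusive target markers.

    ``provenance`` optionally tags each reference as ``curated`` (from
    biological knowledge) or ``data_driven`` (from exclusivity ranking).
    """

    pairs: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ConfigError("pair configuration is empty")
        for ref, targets in self.pairs.items():
            if not targets:
                raise ConfigError(f"reference {ref!r} has an empty target list")
            if ref in targets:
                raise ConfigError(f"reference {ref!r} lists itself as a target")
            if len(set(targets)) != len(targets):
                raise ConfigError(f"reference {ref!r} has duplicate targets")
        bad = {v for v in self.provenance.values()} - {"curated", "data_driven"}
        if bad:
            raise ConfigError(f"unknown provenance flag(s): {sorted(bad)}")

    @property
    def references(self) -> list[str]:
        return list(self.pairs)

    def targets(self, reference: str) -> list[str]:
        try:
            return list(self.pairs[reference])
        except KeyError:
            raise ConfigError(f"no pair entry for reference {reference!r}") from None

    def validate_against(self, table: FeatureTable) -> None:
        """Every marker named in the config must exist in the table."""
        known = set(table.markers)
        for ref, targets in self.pairs.items():
            for m in (ref, *targets):
                if m not in known:
                    raise ConfigError(
                        f"pair config names marker {m!r} absent from the table"
                    )


def read_pair_config(path: str | Path) -> PairConfig:
    """Read a YAML or JSON mapping of reference marker -> target markers.

    Entries may be plain lists, or mappings ``{targets: [...], provenance:
    curated|data_driven}``.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            raw = json.load(fh)
        else:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError("pair config must be a mapping of reference -> targets")
    pairs: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    for ref, entry in raw.items():
        if isinstance(entry, Mapping):
            targets = entry.get("targets")
            if targets is None:
                raise ConfigError(f"entry for {ref!r} lacks a 'targets' list")
            if "provenance" in entry:
                provenance[str(ref)] = str(entry["provenance"])
        else:
            targets = entry
        if isinstance(targets, str) or not isinstance(targets, Sequence):
            raise ConfigError(f"targets for {ref!r} must be a list of marker names")
        pairs[str(ref)] = [str(t) for t in targets]
    return PairConfig(pairs=pairs, provenance=provenance)


def write_pair_config(config: PairConfig, path: str | Path) -> None:
    path = Path(path)
    payload: dict[str, object] = {}
    for ref, targets in config.pairs.items():
        if ref in config.provenance:
            payload[ref] = {"targets": targets, "provenance": config.provenance[ref]}
        else:
            payload[ref] = targets
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)
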