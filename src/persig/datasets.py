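"""Core in-memory containers shared by every pipeline stage.

The universal currency is :class:`ExpressionDataset`, a validated bundle of a
features × samples value matrix, sample annotations, optional detection calls
and an explicit *scale* tag.  Keeping the scale explicit ("linear" raw
intensities, "log2-vst" transformed intensities, "log-ratio" two-colour style
data) lets downstream stages refuse inputs on the wrong scale instead of
silently producing nonsense.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SCALES = ("linear", "log2-vst", "log-ratio")

UP = 1
DOWN = -1


class PersigError(Exception):
    """Base class for all package errors."""


class ConfigError(PersigError, ValueError):
    """A configuration value violates its documented invariant."""


class InputError(PersigError, ValueError):
    """An input object violates a precondition of an operation."""


class FormatError(PersigError, ValueError):
    """A file on disk is malformed; the message names file/line/field."""


@dataclass
class ExpressionDataset:
    """A features × samples expression matrix with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by unique feature ids (probe ids or gene symbols),
        columns are unique sample ids, cells are floats.
    scale
        One of ``"linear"``, ``"log2-vst"``, ``"log-ratio"``.
    sample_annotations
        Optional DataFrame indexed by sample id with (a subset of) the
        columns ``condition``, ``time``, ``subset``.  Must cover every
        sample in ``values``.
    detection
        Optional boolean DataFrame with the same index/columns as
        ``values``; True means the probe was detected above background in
        that sample.
    """

    values: pd.DataFrame
    scale: str
    sample_annotations: pd.DataFrame | None = None
    detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise InputError("values must be a pandas DataFrame")
        if self.scale not in SCALES:
            raise InputError(
                f"unknown scale tag {self.scale!r}; expected one of {SCALES}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate feature ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise InputError(f"duplicate sample ids: {list(dups[:5])}")
        if self.detection is not None:
            if not (
                self.detection.index.equals(self.values.index)
                and self.detection.columns.equals(self.values.columns)
            ):
                raise InputError(
                    "detection matrix is not aligned with the value matrix"
                )
        if self.sample_annotations is not None:
            missing = self.values.columns.difference(self.sample_annotations.index)
            if len(missing):
                raise InputError(
                    f"samples missing from annotations: {list(missing[:5])}"
                )

    # -- conveniences -----------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionDataset":
        """Return a new dataset with replaced values (and optionally scale),
        carrying annotations over and subsetting detection to the new index."""
        det = self.detection
        if det is not None:
            det = det.loc[values.index, values.columns]
        ann = self.sample_annotations
        if ann is not None:
            ann = ann.loc[ann.index.intersection(values.columns, sort=False)]
        return ExpressionDataset(
            values=values,
            scale=self.scale if scale is None else scale,
            sample_annotations=ann,
            detection=det,
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionDataset":
        idx = pd.Index(feature_ids)
        return self.with_values(self.values.loc[idx])

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids whose annotation matches all of the given key=value pairs."""
        if self.sample_annotations is None:
            raise InputError("dataset has no sample annotations")
        ann = self.sample_annotations.loc[self.sample_ids]
        mask = np.ones(len(ann), dtype=bool)
        for key, val in conditions.items():
            if key not in ann.columns:
                raise InputError(f"annotation column {key!r} not present")
            mask &= (ann[key] == val).to_numpy()
        return list(ann.index[mask])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO biological-process categories) for enrichment."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class GeneSignature:
    """A named, directional, weighted gene list.

    ``entries`` is indexed by unique gene id with columns ``direction``
    (+1 up, −1 down) and ``weight`` (the log2 fold-change at the signature's
    time point).  Invariants: sign(weight) == direction and
    ``|weight| >= log2(fold threshold)`` when a fold threshold is recorded.
    """

    name: str
    entries: pd.DataFrame
    time: str | None = None
    fdr: float | None = None
    fold: float | None = None

    def __post_init__(self) -> None:
        required = {"direction", "weight"}
        if not required.issubset(self.entries.columns):
            raise InputError(f"signature entries need columns {sorted(required)}")
        if self.entries.index.has_duplicates:
            raise InputError("signature gene ids must be unique")
        if len(self.entries):
            d = self.entries["direction"].to_numpy()
            w = self.entries["weight"].to_numpy(dtype=float)
            if not np.all(np.isin(d, (UP, DOWN))):
                raise InputError("directions must be +1 or -1")
            if not np.all(np.sign(w) == d):
                raise InputError("every weight's sign must match its direction")
            if self.fold is not None and self.fold > 1:
                lo = np.log2(self.fold) - 1e-12
                if not np.all(np.abs(w) >= lo):
                    raise InputError(
                        f"|weight| must be >= log2(fold={self.fold})"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> pd.Index:
        return self.entries.index

    @property
    def directions(self) -> pd.Series:
        return self.entries["direction"]

    @property
    def weights(self) -> pd.Series:
        return self.entries["weight"]

    @property
    def n_up(self) -> int:
        return int((self.entries["direction"] == UP).sum())

    @property
    def n_down(self) -> int:
        return int((self.entries["direction"] == DOWN).sum())


@dataclass
class SyntheticTruth:
    """Ground truth record emitted by the simulators.

    planted_genes maps gene id → {time label: log2 effect}; cohort fields are
    filled only by the cohort generator.
    """

    planted_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    cohort_subsets: dict[str, str] = field(default_factory=dict)
    cohort_shifted_genes: dict[str, set[str]] = field(default_factory=dict)
    configs: dict[str, Mapping] = field(default_factory=dict)

    def planted_at(self, time: str) -> dict[str, float]:
        """Gene → effect restricted to genes with a nonzero effect at `time`."""
        return {
            g: eff[time]
            for g, eff in self.planted_genes.items()
            if time in eff and eff[time] != 0.0
        }
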