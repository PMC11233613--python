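"""Core data containers shared by every pipeline stage.

Each container wraps validated pandas/numpy structures. Editing status is
binary presence/absence; unassayed cells count as non-edited, since every
co-occurrence statistic downstream is binary. The optional ``levels`` layer
carries the continuous editing fraction (NaN where missing/unedited).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EditingMatrix",
    "ExpressionBundle",
    "ClinicalTable",
    "GeneSetCollection",
    "CopyNumberSegments",
]


@dataclass
class EditingMatrix:
    """Binary edited/non-edited status per site per sample.

    Attributes
    ----------
    status : DataFrame (sites x samples) of {0,1} int
    levels : optional DataFrame on the same axes, editing fraction in [0,1],
        NaN allowed
    annotations : optional DataFrame indexed by site_id with columns
        ``chrom``, ``pos`` (1-based), ``strand``, ``gene``
    """

    status: pd.DataFrame
    levels: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None

    def __post_init__(self):
        s = self.status
        if s.index.has_duplicates:
            raise ValueError("duplicate site ids")
        if s.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = s.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise ValueError(
                f"non-binary status at site {s.index[bad[0]]!r}, "
                f"sample {s.columns[bad[1]]!r}: {vals[tuple(bad)]!r}"
            )
        self.status = s.astype(np.int8)
        if self.levels is not None:
            lv = self.levels.reindex(index=s.index, columns=s.columns)
            arr = lv.to_numpy(dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("editing levels must lie in [0, 1]")
            self.levels = lv
        if self.annotations is not None:
            missing = s.index.difference(self.annotations.index)
            if len(missing):
                raise ValueError(f"annotations missing for sites: {list(missing)[:5]}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.status.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.status.columns)

    def subset_samples(self, sample_ids) -> "EditingMatrix":
        sub = self.status.loc[:, list(sample_ids)]
        lv = self.levels.loc[:, list(sample_ids)] if self.levels is not None else None
        return EditingMatrix(status=sub, levels=lv, annotations=self.annotations)


@dataclass
class ExpressionBundle:
    """Normalized expression values plus raw counts, with tumor/normal labels.

    ``values`` and ``counts`` are genes x samples; ``sample_class`` maps each
    sample id to 'tumor' or 'normal'.
    """

    values: pd.DataFrame
    counts: pd.DataFrame | None = None
    sample_class: pd.Series | None = None

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise ValueError("duplicate gene or sample ids in expression values")
        if (v.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.counts is not None:
            c = self.counts
            if list(c.columns) != list(v.columns):
                raise ValueError("sample ids differ between values and counts")
            arr = c.to_numpy()
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be non-negative integers")
            self.counts = c.astype(np.int64)
        if self.sample_class is not None:
            sc = self.sample_class.reindex(v.columns)
            if sc.isna().any():
                raise ValueError("sample_class missing for some samples")
            bad = set(sc.unique()) - {"tumor", "normal"}
            if bad:
                raise ValueError(f"sample_class labels must be tumor/normal, got {bad}")
            self.sample_class = sc

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def tumor_samples(self) -> list[str]:
        if self.sample_class is None:
            return self.sample_ids
        return list(self.sample_class.index[self.sample_class == "tumor"])

    def normal_samples(self) -> list[str]:
        if self.sample_class is None:
            return []
        return list(self.sample_class.index[self.sample_class == "normal"])


def filter_expressed_genes(values: pd.DataFrame, min_frac: float = 0.90) -> pd.DataFrame:
    """Keep genes with expression > 0 in at least ``min_frac`` of samples."""
    frac = (values > 0).mean(axis=1)
    return values.loc[frac >= min_frac]


@dataclass
class ClinicalTable:
    """Per-patient covariates plus overall survival.

    Index = patient id (must match tumor sample ids). Columns: ``age``,
    ``gender``, ``bmi``, ``stage`` (1-4, NaN allowed), ``grade`` (1-4, NaN
    allowed), ``afp`` (ng/mL, NaN allowed), ``os_time`` (days), ``os_event``.
    """

    data: pd.DataFrame

    REQUIRED = ("age", "gender", "bmi", "stage", "grade", "afp", "os_time", "os_event")

    def __post_init__(self):
        d = self.data
        if d.index.has_duplicates:
            raise ValueError("duplicate patient ids")
        missing = [c for c in self.REQUIRED if c not in d.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if (d["os_time"] <= 0).any():
            raise ValueError("os_time must be positive")
        if not d["os_event"].isin([0, 1]).all():
            raise ValueError("os_event must be 0/1")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways) with optional descriptions."""

    sets: dict[str, set]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class CopyNumberSegments:
    """Segmented copy-number records: sample, chrom, start, end, log2_ratio.

    Coordinates are stored half-open 0-based internally (converted on read
    from 1-based inclusive input).
    """

    data: pd.DataFrame

    def __post_init__(self):
        d = self.data
        req = {"sample_id", "chrom", "start", "end", "log2_ratio"}
        missing = req - set(d.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {sorted(missing)}")
        if (d["start"] >= d["end"]).any():
            bad = d.index[d["start"] >= d["end"]][0]
            raise ValueError(f"segment with start >= end at row {bad}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())
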