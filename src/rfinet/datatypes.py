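"""Core data containers shared across the analysis stages.

All tabular payloads are pandas objects; the dataclasses below only add
light invariant checking and provenance fields on top.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

SIRE_GROUPS = ("low", "high")


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample metadata table (index: sample id).

    Required columns: ``animal``, ``sire_group``, ``tissue``.  Every animal
    must belong to exactly one sire group and sire groups must be drawn
    from ``{"low", "high"}``.
    """
    required = {"animal", "sire_group", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"sample metadata missing columns: {sorted(missing)}")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids: {dup}")
    bad_groups = set(meta["sire_group"].unique()) - set(SIRE_GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown sire groups: {sorted(bad_groups)}")
    per_animal = meta.groupby("animal")["sire_group"].nunique()
    offenders = per_animal[per_animal > 1].index.tolist()
    if offenders:
        raise ValidationError(f"animals assigned to more than one sire group: {offenders}")
    return meta


@dataclass
class CountMatrix:
    """Raw gene x sample read counts with gene lengths and sample totals.

    ``totals`` are per-sample total mapped reads.  When not supplied they
    default to the column sums of ``counts`` and ``totals_source`` records
    which convention was used.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    totals: Optional[pd.Series] = None
    totals_source: str = "column_sum"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()
            raise ValidationError(f"genes without length: {missing[:5]}")
        if (self.lengths <= 0).any():
            raise ValidationError("gene lengths must be > 0")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0).astype(float)
            self.totals_source = "column_sum"
        else:
            self.totals = self.totals.reindex(self.counts.columns).astype(float)
            if self.totals.isna().any():
                raise ValidationError("totals missing for some samples")
            self.totals_source = "supplied"

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, samples) -> "CountMatrix":
        cm = CountMatrix(
            counts=self.counts.loc[:, samples].copy(),
            lengths=self.lengths.copy(),
            totals=self.totals.loc[samples].copy(),
        )
        cm.totals_source = self.totals_source
        return cm


@dataclass
class ExpressionMatrix:
    """RPKM expression values with optional attached sample metadata."""

    rpkm: pd.DataFrame
    meta: Optional[pd.DataFrame] = None
    log2_offset: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.rpkm.to_numpy() < 0).any():
            raise ValidationError("RPKM must be non-negative")
        if self.meta is not None:
            self.meta = validate_sample_meta(self.meta.loc[self.rpkm.columns])

    @property
    def genes(self) -> pd.Index:
        return self.rpkm.index

    @property
    def samples(self) -> pd.Index:
        return self.rpkm.columns


@dataclass
class GeneAnnotation:
    """Per-gene class flags (is_tf, is_snp) plus optional GO terms."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for col in ("is_tf", "is_snp"):
            if col not in self.table.columns:
                self.table[col] = False
            self.table[col] = self.table[col].astype(bool)

    @property
    def tf_genes(self) -> pd.Index:
        return self.table.index[self.table["is_tf"]]

    @property
    def snp_genes(self) -> pd.Index:
        return self.table.index[self.table["is_snp"]]


def tissue_of(meta: pd.DataFrame, samples) -> np.ndarray:
    return meta.loc[samples, "tissue"].to_numpy()
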