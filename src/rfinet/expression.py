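"""Sample QC, RPKM normalization, expressed-gene filtering and
tissue-specificity classification.

Conventions (documented boundary behaviour):

* ``qc_samples`` keeps samples with total mapped reads >= ``min_reads``
  ("less than 10 million reads ... discarded" is a strict-below rule).
* a gene is *expressed* iff its mean RPKM reaches >= ``threshold`` in at
  least one tissue (strict-below means not expressed).
* a gene is *tissue specific* iff one tissue carries >= ``ts_threshold``
  (default 2/3) of the summed per-tissue mean RPKM (inclusive boundary).
"""
from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 10_000_000
DEFAULT_RPKM_THRESHOLD = 0.2
DEFAULT_TS_THRESHOLD = 2.0 / 3.0
DEFAULT_LOG2_OFFSET = 0.2  # equal to the expressed-gene RPKM threshold


def qc_samples(cm: CountMatrix, min_reads: float = DEFAULT_MIN_READS) -> CountMatrix:
    """Drop samples whose total mapped reads fall below ``min_reads``.

    The boundary is inclusive: a sample with exactly ``min_reads`` is kept.
    Raises if no sample survives.
    """
    keep = cm.totals >= min_reads
    removed = list(cm.samples[~keep])
    if removed:
        logger.info("qc_samples: removed %d samples: %s", len(removed), removed)
    if not keep.any():
        raise ValidationError("qc_samples removed every sample")
    return cm.subset_samples(cm.samples[keep])


def compute_rpkm(cm: CountMatrix, meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    """RPKM_gs = count_gs * 1e9 / (length_g * total_s)."""
    if (cm.totals <= 0).any():
        bad = list(cm.totals.index[cm.totals <= 0])
        raise ValidationError(f"zero/negative total mapped reads for samples: {bad}")
    scale = 1e9 / np.outer(cm.lengths.to_numpy(float), cm.totals.to_numpy(float))
    rpkm = pd.DataFrame(
        cm.counts.to_numpy(float) * scale, index=cm.genes, columns=cm.samples
    )
    if meta is not None:
        meta = meta.loc[rpkm.columns]
    return ExpressionMatrix(rpkm=rpkm, meta=meta)


def tissue_means(expr: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean RPKM per (gene, tissue). Requires attached metadata."""
    if expr.meta is None:
        raise ValidationError("tissue_means requires sample metadata")
    return expr.rpkm.T.groupby(expr.meta["tissue"]).mean().T


def filter_expressed(
    expr: ExpressionMatrix,
    threshold: float = DEFAULT_RPKM_THRESHOLD,
    mode: str = "tissue_mean",
) -> Tuple[pd.Index, pd.Index]:
    """Split genes into (expressed, not_expressed).

    ``mode='tissue_mean'`` (default): expressed iff mean RPKM >= threshold
    in at least one tissue.  ``mode='any_sample'``: expressed iff any single
    sample reaches the threshold.
    """
    if mode == "tissue_mean":
        tm = tissue_means(expr)
        expressed_mask = (tm >= threshold).any(axis=1)
    elif mode == "any_sample":
        expressed_mask = (expr.rpkm >= threshold).any(axis=1)
    else:
        raise ValueError(f"unknown filter mode: {mode!r}")
    expressed = expr.genes[expressed_mask]
    not_expressed = expr.genes[~expressed_mask]
    logger.info(
        "filter_expressed: %d expressed, %d not expressed (threshold %g, mode %s)",
        len(expressed), len(not_expressed), threshold, mode,
    )
    return expressed, not_expressed


def tissue_share(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene tissue shares: share_gj = meanRPKM_gj / sum_j meanRPKM_gj.

    Genes with zero total expression get NaN shares (excluded from TS
    calling downstream).
    """
    tm = tissue_means(expr)
    total = tm.sum(axis=1)
    shares = tm.div(total, axis=0)
    shares[total == 0] = np.nan
    return shares


def classify_tissue_specific(
    shares: pd.DataFrame, threshold: float = DEFAULT_TS_THRESHOLD
) -> pd.DataFrame:
    """Call tissue-specific genes from a gene x tissue share table.

    Returns a frame indexed by gene with columns ``dominant_tissue``,
    ``share`` and ``is_ts``.  The boundary is inclusive (share >= threshold).
    Genes with undefined shares (zero total) are returned with is_ts False
    and NaN share.
    """
    valid = shares.notna().all(axis=1)
    dominant = shares.idxmax(axis=1).where(valid)
    top = shares.max(axis=1)
    is_ts = valid & (top >= threshold)
    return pd.DataFrame(
        {"dominant_tissue": dominant, "share": top, "is_ts": is_ts},
        index=shares.index,
    )


def log2_transform(
    expr: ExpressionMatrix, offset: float = DEFAULT_LOG2_OFFSET
) -> pd.DataFrame:
    """Y = log2(RPKM + offset); offset must be > 0 if zeros are present."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    values = expr.rpkm.to_numpy(float)
    if offset == 0 and (values == 0).any():
        raise ValidationError("zero RPKM present: a positive log2 offset is required")
    out = pd.DataFrame(np.log2(values + offset), index=expr.genes, columns=expr.samples)
    expr.log2_offset = offset
    return out
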