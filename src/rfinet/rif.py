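"""Regulatory impact factor (RIF) scoring of transcription factors.

Scores combine target abundance, target differential expression between
sire groups, and differential TF-target co-expression:

    PIF_i  = 1/2 (e1_i + e2_i) (e1_i - e2_i)
    RIF1_j = (1/n_t) sum_i PIF_i (r1_ij - r2_ij)^2
    RIF2_j = (1/n_t) sum_i [ (e1_i r1_ij)^2 - (e2_i r2_ij)^2 ]

where e1/e2 are group mean log2 expression of target i and r1/r2 the
within-group Pearson correlations between TF j and target i.  Correlations
pool all samples within a sire group across tissues by default (matching
the whole-dataset network construction); restrict ``samples`` beforehand
for a per-tissue variant.
"""
from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import ValidationError

logger = logging.getLogger(__name__)


def _group_columns(meta: pd.DataFrame, columns: pd.Index) -> tuple[pd.Index, pd.Index]:
    meta = meta.loc[columns]
    low = columns[meta["sire_group"].to_numpy() == "low"]
    high = columns[meta["sire_group"].to_numpy() == "high"]
    if len(low) == 0 or len(high) == 0:
        raise ValidationError("both sire groups must be present")
    return low, high


def compute_pif(e1: pd.Series, e2: pd.Series) -> pd.Series:
    """Phenotypic impact factor per target: average abundance x difference."""
    return 0.5 * (e1 + e2) * (e1 - e2)


def _group_correlations(tf_mat: np.ndarray, tg_mat: np.ndarray) -> np.ndarray:
    """Pearson correlations between TF rows and target rows (n_tf x n_targets)."""
    tf_c = tf_mat - tf_mat.mean(axis=1, keepdims=True)
    tg_c = tg_mat - tg_mat.mean(axis=1, keepdims=True)
    tf_sd = np.sqrt((tf_c**2).sum(axis=1))
    tg_sd = np.sqrt((tg_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (tf_c @ tg_c.T) / np.outer(tf_sd, tg_sd)
    return np.clip(corr, -1.0, 1.0)


def compute_rif(
    logexpr: pd.DataFrame,
    meta: pd.DataFrame,
    tf_list: Sequence,
    target_list: Sequence,
) -> pd.DataFrame:
    """RIF1/RIF2 per TF with z-standardization across scored TFs.

    TFs with zero expression variance inside either sire group cannot be
    correlated and are skipped with a warning.  Targets with zero variance
    in a group contribute correlation 0 for that group.
    """
    tf_list = pd.Index(tf_list)
    target_list = pd.Index(target_list)
    missing = tf_list.difference(logexpr.index).tolist() + target_list.difference(logexpr.index).tolist()
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing[:5]}")
    overlap = tf_list.intersection(target_list)
    if len(overlap):
        target_list = target_list.difference(overlap)
    if len(target_list) == 0:
        raise ValidationError("no targets left after removing TFs from the target list")
    low, high = _group_columns(meta, logexpr.columns)
    if len(low) < 3 or len(high) < 3:
        raise ValidationError("need >= 3 samples per sire group")

    e1 = logexpr.loc[target_list, low].mean(axis=1)
    e2 = logexpr.loc[target_list, high].mean(axis=1)
    pif = compute_pif(e1, e2)

    tf_low = logexpr.loc[tf_list, low].to_numpy(float)
    tf_high = logexpr.loc[tf_list, high].to_numpy(float)
    keep = (tf_low.std(axis=1) > 0) & (tf_high.std(axis=1) > 0)
    if not keep.all():
        skipped = tf_list[~keep].tolist()
        warnings.warn(f"skipping {len(skipped)} zero-variance TFs: {skipped[:5]}")
    tf_list = tf_list[keep]
    tf_low, tf_high = tf_low[keep], tf_high[keep]

    tg_low = logexpr.loc[target_list, low].to_numpy(float)
    tg_high = logexpr.loc[target_list, high].to_numpy(float)
    r1 = np.nan_to_num(_group_correlations(tf_low, tg_low))
    r2 = np.nan_to_num(_group_correlations(tf_high, tg_high))

    n_t = len(target_list)
    rif1 = (r1 - r2) ** 2 @ pif.to_numpy() / n_t
    rif2 = ((e1.to_numpy() * r1) ** 2 - (e2.to_numpy() * r2) ** 2).sum(axis=1) / n_t

    mean_expr = logexpr.loc[tf_list].mean(axis=1)
    out = pd.DataFrame(
        {
            "rif1": rif1,
            "rif2": rif2,
            "z_rif1": _standardize(rif1),
            "z_rif2": _standardize(rif2),
            "mean_expr": mean_expr,
        },
        index=tf_list,
    )
    out.index.name = "tf"
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def select_tf(
    scores: pd.DataFrame,
    z_cut: float = 2.0,
    abundance_cut: Optional[float] = None,
) -> pd.Index:
    """TFs that are both differentially wired and abundant.

    Selected iff (|z_RIF1| >= z_cut or |z_RIF2| >= z_cut) and mean log2
    expression >= ``abundance_cut`` (default: the across-TF median).
    """
    if abundance_cut is None:
        abundance_cut = float(scores["mean_expr"].median())
    wired = (scores["z_rif1"].abs() >= z_cut) | (scores["z_rif2"].abs() >= z_cut)
    abundant = scores["mean_expr"] >= abundance_cut
    return scores.index[wired & abundant]
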