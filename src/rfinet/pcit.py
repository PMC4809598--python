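"""Partial-correlation-and-information-theory (PCIT) network inference.

For every trio of nodes (x, y, z) the three first-order partial
correlations are computed; the trio's local tolerance is the average of the
absolute partial-to-direct ratios

    eps = (1/3) * ( |r_xy.z|/|r_xy| + |r_xz.y|/|r_xz| + |r_yz.x|/|r_yz| )

and the x-y connection is *eliminated* when, for at least one z,

    |r_xy| <= eps * |r_xz|   and   |r_xy| <= eps * |r_yz|.

Pairs never eliminated by any trio are "significant".  Significant pairs
are then standardized and accepted when their |z-score| exceeds a cutoff
(default 2 SD).

Ratios whose direct correlation is numerically zero (|r| < ``eps_guard``)
are skipped: the tolerance averages the remaining terms, and a trio with no
valid term eliminates nothing.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ValidationError

logger = logging.getLogger(__name__)

EPS_GUARD = 1e-12


@dataclass
class CorrelationStructure:
    nodes: pd.Index
    R: np.ndarray                       # symmetric, unit diagonal
    mask: np.ndarray | None = None      # PCIT significance (symmetric, no diag)


def correlation_matrix(logexpr: pd.DataFrame) -> CorrelationStructure:
    """Pearson correlations between gene rows across samples.

    Zero-variance rows are excluded with a warning; < 3 samples is an error.
    """
    if logexpr.shape[1] < 3:
        raise ValidationError("need >= 3 samples for correlations")
    sd = logexpr.std(axis=1, ddof=1)
    dropped = logexpr.index[sd == 0]
    if len(dropped):
        warnings.warn(f"excluding {len(dropped)} zero-variance nodes from the network")
        logexpr = logexpr.loc[sd > 0]
    R = np.corrcoef(logexpr.to_numpy(float))
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationStructure(nodes=logexpr.index, R=R)


def partial_correlation(r_xy, r_xz, r_yz):
    """First-order partial r_xy.z = (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2))."""
    r_xz = np.asarray(r_xz, float)
    r_yz = np.asarray(r_yz, float)
    denom2 = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if np.any(denom2 <= 0):
        raise ValidationError("degenerate conditioning: |r_xz| = 1 or |r_yz| = 1")
    out = (np.asarray(r_xy, float) - r_xz * r_yz) / np.sqrt(denom2)
    return out if out.shape else float(out)


def pcit_significant(structure: CorrelationStructure, eps_guard: float = EPS_GUARD) -> np.ndarray:
    """Vectorized trio scan; returns (and stores) the boolean significance mask.

    O(n^3) time via an O(n^2) inner body per conditioning node z.
    """
    R = structure.R
    n = R.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 nodes")
    absR = np.abs(R)
    eliminated = np.zeros((n, n), dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            rz = R[:, z]                                   # r_xz for all x
            one_m = np.maximum(1.0 - rz**2, 0.0)
            # r_xy.z over the (x, y) plane
            den_xy = np.sqrt(np.outer(one_m, one_m))
            p_xy = np.where(den_xy > 0, (R - np.outer(rz, rz)) / den_xy, np.inf)
            one_m_xy = np.maximum(1.0 - R**2, 0.0)
            # r_xz.y : condition the x-z pair on y (columns: y)
            den_xz = np.sqrt(one_m_xy * one_m[None, :])
            p_xz = np.where(den_xz > 0, (rz[:, None] - R * rz[None, :]) / den_xz, np.inf)
            # r_yz.x : condition the y-z pair on x (rows: x)
            den_yz = np.sqrt(one_m_xy * one_m[:, None])
            p_yz = np.where(den_yz > 0, (rz[None, :] - R * rz[:, None]) / den_yz, np.inf)

            ratios = np.zeros((n, n))
            counts = np.zeros((n, n))
            for p, d in ((p_xy, absR), (p_xz, np.broadcast_to(np.abs(rz)[:, None], (n, n))),
                         (p_yz, np.broadcast_to(np.abs(rz)[None, :], (n, n)))):
                valid = (d > eps_guard) & np.isfinite(p)
                ratios += np.where(valid, np.abs(p) / np.where(valid, d, 1.0), 0.0)
                counts += valid
            with np.errstate(invalid="ignore"):
                eps = np.where(counts > 0, ratios / np.maximum(counts, 1), np.nan)
            cond = (
                (counts > 0)
                & (absR <= eps * np.abs(rz)[:, None])
                & (absR <= eps * np.abs(rz)[None, :])
            )
            cond[z, :] = False
            cond[:, z] = False
            np.fill_diagonal(cond, False)
            eliminated |= cond
    mask = ~eliminated
    np.fill_diagonal(mask, False)
    mask &= mask.T
    structure.mask = mask
    return mask


def pcit_significant_reference(R: np.ndarray, eps_guard: float = EPS_GUARD) -> np.ndarray:
    """Naive O(n^3) triple loop; independent reference for the kernel."""
    n = R.shape[0]
    eliminated = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            for z in range(n):
                if z == x or z == y:
                    continue
                trio = []
                for (a, b, c) in ((x, y, z), (x, z, y), (y, z, x)):
                    d2 = (1 - R[a, c] ** 2) * (1 - R[b, c] ** 2)
                    p = (R[a, b] - R[a, c] * R[b, c]) / np.sqrt(d2) if d2 > 0 else np.inf
                    trio.append((p, R[a, b]))
                terms = [abs(p) / abs(d) for p, d in trio
                         if abs(d) > eps_guard and np.isfinite(p)]
                if not terms:
                    continue
                eps = sum(terms) / len(terms)
                if abs(R[x, y]) <= eps * abs(R[x, z]) and abs(R[x, y]) <= eps * abs(R[y, z]):
                    eliminated[x, y] = eliminated[y, x] = True
                    break
    mask = ~eliminated
    np.fill_diagonal(mask, False)
    return mask


def threshold_edges(
    structure: CorrelationStructure,
    k: float = 2.0,
    stat: str = "raw",
    standardize: str = "all",
) -> pd.DataFrame:
    """Standardize pair weights and accept PCIT-significant pairs with |z| >= k.

    ``stat='raw'`` uses the raw Pearson correlations (default);
    ``stat='partial'`` uses, for each surviving pair, its minimum-|.|
    first-order partial correlation over all conditioning nodes.

    ``standardize='all'`` (default) takes the standardization mean/SD over
    every node pair, so the rule keeps the tails of the whole correlation
    distribution; ``standardize='significant'`` standardizes within the
    PCIT-surviving pairs only.  The latter is self-referential: survivors
    are already the strong tail, so on structured data almost nothing sits
    two of their own SDs out.

    Returns an edge list (gene_a < gene_b) with columns r, z, accepted.
    """
    if structure.mask is None:
        raise ValidationError("run pcit_significant first")
    if standardize not in ("all", "significant"):
        raise ValueError(f"unknown standardization population: {standardize!r}")
    R, mask, nodes = structure.R, structure.mask, structure.nodes
    iu = np.triu_indices(R.shape[0], k=1)
    sig = mask[iu]
    ia, ib = iu[0][sig], iu[1][sig]
    if stat == "raw":
        weights = R[ia, ib]
        population = R[iu] if standardize == "all" else weights
    elif stat == "partial":
        weights = _min_abs_partial(R, ia, ib)
        population = weights  # partials are only computed for survivors
    else:
        raise ValueError(f"unknown stat: {stat!r}")
    n_sig = len(weights)
    if len(population) < 2 or n_sig < 1:
        warnings.warn("fewer than 2 pairs to standardize: rejecting all edges")
        z = np.zeros(n_sig)
        accepted = np.zeros(n_sig, dtype=bool)
    else:
        sd = population.std(ddof=1)
        if sd == 0:
            warnings.warn("all correlations equal: rejecting all edges")
            z = np.zeros(n_sig)
            accepted = np.zeros(n_sig, dtype=bool)
        else:
            z = (weights - population.mean()) / sd
            accepted = np.abs(z) >= k
    return pd.DataFrame(
        {
            "gene_a": nodes[ia],
            "gene_b": nodes[ib],
            "r": R[ia, ib],
            "z": z,
            "accepted": accepted,
        }
    )


def _min_abs_partial(R: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    n = R.shape[0]
    out = np.empty(len(ia))
    with np.errstate(divide="ignore", invalid="ignore"):
        for idx, (x, y) in enumerate(zip(ia, ib)):
            rz_x, rz_y = R[x, :], R[y, :]
            d2 = (1 - rz_x**2) * (1 - rz_y**2)
            p = np.where(d2 > 0, (R[x, y] - rz_x * rz_y) / np.sqrt(np.where(d2 > 0, d2, 1)), np.inf)
            p[x] = p[y] = np.inf
            finite = np.isfinite(p)
            out[idx] = p[finite][np.argmin(np.abs(p[finite]))] if finite.any() else R[x, y]
    return out


def infer_network(
    logexpr: pd.DataFrame, k: float = 2.0, stat: str = "raw", standardize: str = "all"
) -> pd.DataFrame:
    """Convenience: correlations -> PCIT mask -> thresholded edge list."""
    structure = correlation_matrix(logexpr)
    pcit_significant(structure)
    return threshold_edges(structure, k=k, stat=stat, standardize=standardize)
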