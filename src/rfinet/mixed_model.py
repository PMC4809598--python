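"""Crossed random-effects model for log2 expression.

Model per observation (gene i, tissue j, animal k, sire group l):

    Y_ijkl = mu + G_i + GT_ij + GA_ik + GS_il + e_ijkl

with every effect random and iid normal within its factor.  Because no two
genes share a random effect, genes are independent replicates with a common
sample-by-sample covariance matrix

    V = s2_G * J + s2_GT * M_T + s2_GA * M_A + s2_GS * M_S + s2_e * I

where M_F[s, s'] indicates samples sharing the level of factor F.  REML is
maximised directly over log variance components; BLUP solutions follow from
u_F = s2_F * Z_F' V^{-1} (y_i - mu).

Differential expression between sire groups is called from the gene-by-sire
contrast d_i = GS_i,low - GS_i,high standardized across genes: a gene is DE
when |z_i| >= k (default 2).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .datatypes import SIRE_GROUPS, ValidationError, validate_sample_meta

logger = logging.getLogger(__name__)

COMPONENTS = ("G", "GT", "GA", "GS", "e")


class ConvergenceError(RuntimeError):
    pass


def _indicator(levels: np.ndarray) -> tuple[np.ndarray, list]:
    uniq = sorted(pd.unique(levels))
    Z = np.asarray(levels)[:, None] == np.asarray(uniq)[None, :]
    return Z.astype(float), uniq


@dataclass
class _Design:
    """Sample-side design shared by every gene."""

    Z: Dict[str, np.ndarray]        # factor -> n_samples x n_levels indicator
    levels: Dict[str, list]
    gram: Dict[str, np.ndarray]     # factor -> n x n same-level matrix
    n: int

    @classmethod
    def from_meta(cls, meta: pd.DataFrame, samples) -> "_Design":
        meta = validate_sample_meta(meta.loc[samples])
        n = len(samples)
        Z, levels, gram = {}, {}, {}
        for name, col in (("GT", "tissue"), ("GA", "animal"), ("GS", "sire_group")):
            z, lv = _indicator(meta[col].to_numpy())
            if len(lv) < 2:
                raise ValidationError(f"factor {name} has <2 levels; design is degenerate")
            Z[name], levels[name], gram[name] = z, lv, z @ z.T
        Z["G"] = np.ones((n, 1))
        levels["G"] = ["gene"]
        gram["G"] = np.ones((n, n))
        gram["e"] = np.eye(n)
        return cls(Z=Z, levels=levels, gram=gram, n=n)

    def V(self, comps: Dict[str, float]) -> np.ndarray:
        V = comps["e"] * gram_e(self.n)
        for name in ("G", "GT", "GA", "GS"):
            V = V + comps[name] * self.gram[name]
        return V


def gram_e(n: int) -> np.ndarray:
    return np.eye(n)


@dataclass
class MixedModelFit:
    mu: float
    varcomp: Dict[str, float]
    converged: bool
    n_iter: int
    loglik: float
    design: _Design = field(repr=False)
    samples: pd.Index = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "mu": self.mu,
            "varcomp": dict(self.varcomp),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "reml_loglik": self.loglik,
        }


def _reml_neg2ll(
    log_theta: np.ndarray, design: _Design, A: np.ndarray, ybar: np.ndarray, m: int
) -> float:
    comps = dict(zip(COMPONENTS, np.exp(log_theta)))
    V = design.V(comps)
    try:
        c, low = linalg.cho_factor(V, check_finite=False)
    except linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    ones = np.ones(design.n)
    Wi1 = linalg.cho_solve((c, low), ones, check_finite=False)
    s11 = ones @ Wi1                       # 1' V^-1 1
    mu = (Wi1 @ ybar) / s11
    WiA = linalg.cho_solve((c, low), A, check_finite=False)
    quad = np.trace(WiA) - 2.0 * mu * m * (Wi1 @ ybar) + m * mu * mu * s11
    return m * logdet + np.log(m * s11) + quad


def fit_variance_components(
    Y: pd.DataFrame,
    meta: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixedModelFit:
    """REML estimation of (s2_G, s2_GT, s2_GA, s2_GS, s2_e).

    ``Y`` is a gene x sample matrix of log2 expression.  Estimates are
    non-negative by construction (log parametrization) and clamped to 0
    when numerically negligible.  Raises :class:`ConvergenceError` if the
    optimizer does not converge within ``max_iter`` iterations.
    """
    values = Y.to_numpy(float)
    if not np.isfinite(values).any() or not np.isfinite(values).all():
        raise ValidationError("Y must be finite")
    m, n = values.shape
    if m < 2:
        raise ValidationError("need >= 2 genes")
    design = _Design.from_meta(meta, Y.columns)

    total_var = float(values.var())
    if total_var == 0.0:
        # constant response: all components zero, mu is the constant
        fit = MixedModelFit(
            mu=float(values.ravel()[0]),
            varcomp={c: 0.0 for c in COMPONENTS},
            converged=True, n_iter=0, loglik=0.0,
            design=design, samples=Y.columns,
        )
        return fit

    A = values.T @ values               # sum_i y_i y_i'  (n x n)
    ybar = values.mean(axis=0)

    # Nelder-Mead on log variances: derivative-free, robust to the +inf
    # wall where V leaves the PD cone; the objective is cheap (one n x n
    # Cholesky per evaluation, independent of the number of genes)
    x0 = np.log(np.full(len(COMPONENTS), total_var / len(COMPONENTS)))
    res = optimize.minimize(
        _reml_neg2ll, x0, args=(design, A, ybar, m),
        method="Nelder-Mead",
        options={"maxiter": max_iter * 10, "maxfev": max_iter * 10,
                 "xatol": tol, "fatol": tol},
    )
    if not res.success:
        raise ConvergenceError(f"REML failed to converge: {res.message}")
    comps = dict(zip(COMPONENTS, np.exp(res.x)))
    clamp = 1e-8 * total_var
    comps = {k: (0.0 if v < clamp else float(v)) for k, v in comps.items()}
    if comps["e"] == 0.0:
        comps["e"] = clamp  # keep V invertible for BLUP back-solving

    V = design.V(comps)
    c, low = linalg.cho_factor(V)
    ones = np.ones(n)
    Wi1 = linalg.cho_solve((c, low), ones)
    mu = float((Wi1 @ ybar) / (ones @ Wi1))
    return MixedModelFit(
        mu=mu, varcomp=comps, converged=bool(res.success),
        n_iter=int(res.nit), loglik=float(-0.5 * res.fun),
        design=design, samples=Y.columns,
    )


@dataclass
class BlupSolutions:
    """BLUP solutions for every random factor, per gene."""

    G: pd.Series                 # gene effect
    GT: pd.DataFrame             # gene x tissue
    GA: pd.DataFrame             # gene x animal
    GS: pd.DataFrame             # gene x sire group
    residuals: pd.DataFrame      # gene x sample

    @property
    def sire_contrast(self) -> pd.Series:
        """d_i = GS_i,low - GS_i,high (log2 units)."""
        return self.GS["low"] - self.GS["high"]


def solve_blups(Y: pd.DataFrame, meta: pd.DataFrame, fit: MixedModelFit) -> BlupSolutions:
    """Solve the mixed-model equations at the fitted variance ratios."""
    if not fit.converged:
        raise ConvergenceError("refusing to solve BLUPs from a non-converged fit")
    design = fit.design
    values = Y.loc[:, fit.samples].to_numpy(float)
    R = values - fit.mu
    V = design.V(fit.varcomp)
    c, low = linalg.cho_factor(V)
    WR = linalg.cho_solve((c, low), R.T).T     # m x n,  (y_i - mu)' V^-1 rows
    out = {}
    for name in ("G", "GT", "GA", "GS"):
        out[name] = fit.varcomp[name] * (WR @ design.Z[name])
    resid = fit.varcomp["e"] * WR
    genes = Y.index
    return BlupSolutions(
        G=pd.Series(out["G"][:, 0], index=genes, name="G"),
        GT=pd.DataFrame(out["GT"], index=genes, columns=design.levels["GT"]),
        GA=pd.DataFrame(out["GA"], index=genes, columns=design.levels["GA"]),
        GS=pd.DataFrame(out["GS"], index=genes, columns=design.levels["GS"]),
        residuals=pd.DataFrame(resid, index=genes, columns=fit.samples),
    )


def tissue_fold_changes(Y: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue log2 fold change: mean(low) - mean(high) of log2 expression."""
    meta = meta.loc[Y.columns]
    fcs = {}
    for tissue, sub in meta.groupby("tissue"):
        low = sub.index[sub["sire_group"] == "low"]
        high = sub.index[sub["sire_group"] == "high"]
        fcs[tissue] = Y[low].mean(axis=1) - Y[high].mean(axis=1)
    return pd.DataFrame(fcs)


def call_de(
    solutions: BlupSolutions,
    k: float = 2.0,
    tissue_fc: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Flag DE genes whose standardized sire contrast is >= k SDs from the mean.

    Returns a frame with columns ``d`` (gene-by-sire contrast), ``z``
    (standardized across genes), ``is_de`` and, when supplied, per-tissue
    log2 fold-change columns ``log2fc_<tissue>``.
    """
    d = solutions.sire_contrast
    if len(d) < 10:
        raise ValidationError("need >= 10 genes to estimate the contrast SD")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        warnings.warn("all gene-by-sire contrasts identical: no DE calls possible")
        z = pd.Series(0.0, index=d.index)
        is_de = pd.Series(False, index=d.index)
    else:
        z = (d - d.mean()) / sd
        is_de = z.abs() >= k
    result = pd.DataFrame({"d": d, "z": z, "is_de": is_de})
    if tissue_fc is not None:
        for t in tissue_fc.columns:
            result[f"log2fc_{t}"] = tissue_fc[t]
    return result
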