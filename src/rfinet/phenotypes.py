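"""Feedlot phenotype derivations and the RNA-seq power calculation.

Residual feed intake (RFI) is the residual of the intercept-containing
ordinary least-squares regression

    DMI = b0 + b1 * ADG + b2 * MMW + RFI

fit across all animals within a period, so mean(RFI) = 0 by construction.
ADG is the slope of body weight on days; MMW = (mean period weight)^0.75.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

logger = logging.getLogger(__name__)


def compute_adg(days: Sequence[float], weights: Sequence[float]) -> float:
    """Average daily gain: least-squares slope of weight (kg) on days."""
    days = np.asarray(days, float)
    weights = np.asarray(weights, float)
    if len(days) < 3:
        raise ValidationError("need >= 3 weigh dates for ADG")
    slope, _ = np.polyfit(days, weights, 1)
    return float(slope)


def compute_mmw(weights: Sequence[float]) -> float:
    """Metabolic mid-weight: (arithmetic mean of period body weights)^0.75."""
    weights = np.asarray(weights, float)
    if (weights <= 0).any():
        raise ValidationError("body weights must be positive")
    return float(np.mean(weights) ** 0.75)


@dataclass
class RFIFit:
    period: str
    b0: float
    b1: float
    b2: float
    table: pd.DataFrame  # per-animal: dmi, adg, mmw, rfi

    @property
    def rfi(self) -> pd.Series:
        return self.table["rfi"]


def compute_rfi(
    dmi: pd.Series, adg: pd.Series, mmw: pd.Series, period: str = "growing"
) -> RFIFit:
    """OLS of mean daily DMI on ADG and MMW with intercept; RFI = residual."""
    idx = dmi.index
    if not (adg.index.equals(idx) and mmw.index.equals(idx)):
        adg, mmw = adg.reindex(idx), mmw.reindex(idx)
        if adg.isna().any() or mmw.isna().any():
            raise ValidationError("animal sets of DMI/ADG/MMW differ")
    if len(idx) < 4:
        if len(idx) == 3:
            logger.warning("saturated RFI fit: 3 animals, 3 parameters")
        else:
            raise ValidationError("need >= 3 animals for the RFI regression")
    X = np.column_stack([np.ones(len(idx)), adg.to_numpy(float), mmw.to_numpy(float)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValidationError("rank-deficient RFI design (ADG/MMW collinear)")
    beta, *_ = np.linalg.lstsq(X, dmi.to_numpy(float), rcond=None)
    resid = dmi.to_numpy(float) - X @ beta
    table = pd.DataFrame(
        {"dmi": dmi, "adg": adg, "mmw": mmw, "rfi": resid}, index=idx
    )
    return RFIFit(period=period, b0=float(beta[0]), b1=float(beta[1]),
                  b2=float(beta[2]), table=table)


def compute_fcr(dmi: pd.Series, adg: pd.Series) -> pd.Series:
    """Feed conversion ratio DMI/ADG per animal; ADG == 0 yields NaN."""
    adg = adg.replace(0.0, np.nan)
    if adg.isna().any():
        logger.warning("FCR undefined for animals with zero ADG")
    return dmi / adg


def carcass_specific_gravity(cw: float, cw_h2o: float) -> float:
    """CW / (CW - CW_H2O); requires CW > CW_H2O >= 0."""
    if cw_h2o < 0 or cw <= cw_h2o:
        raise ValidationError("require CW > CW_H2O >= 0")
    return cw / (cw - cw_h2o)


def summarize_feeding(events: pd.DataFrame, n_days: float) -> dict:
    """Bunk-visit summaries: visits/d, min/visit, min/d.

    ``events`` needs a ``duration_min`` column (one row per visit).
    """
    if n_days <= 0:
        raise ValidationError("zero recorded days")
    n = len(events)
    total = float(events["duration_min"].sum()) if n else 0.0
    return {
        "visits_per_day": n / n_days,
        "min_per_visit": float(events["duration_min"].mean()) if n else float("nan"),
        "min_per_day": total / n_days,
    }


def group_difference(
    values: pd.Series, groups: pd.Series, equal_var: bool = False
) -> dict:
    """Sire-group difference (low - high) with a two-sample t-test p-value.

    Welch's test by default (``equal_var=False``); set True for the
    pooled-variance variant.
    """
    groups = groups.reindex(values.index)
    low = values[groups == "low"].to_numpy(float)
    high = values[groups == "high"].to_numpy(float)
    if len(low) < 2 or len(high) < 2:
        raise ValidationError("need >= 2 animals per sire group")
    diff = float(low.mean() - high.mean())
    if np.var(low) == 0 and np.var(high) == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        _, p = stats.ttest_ind(low, high, equal_var=equal_var)
        p = float(p)
    return {"difference": diff, "p_value": p, "mean_low": float(low.mean()),
            "mean_high": float(high.mean())}


# ---------------------------------------------------------------------------
# Differential-expression power
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Two-group RNA-seq DE power problem.

    fold_change is on the ratio scale (> 1); ``depth`` is the expected
    counts per gene (the high-depth regime has 1/depth << cv^2).
    """

    n_per_group: int
    fold_change: float
    cv: float = 0.4
    alpha: float = 0.05
    depth: float = math.inf

    def __post_init__(self) -> None:
        if self.fold_change < 1.0:
            raise ValidationError("fold_change must be >= 1")
        if self.cv <= 0 or not (0 < self.alpha < 1) or self.depth <= 0:
            raise ValidationError("invalid power specification")

    @property
    def unit_variance(self) -> float:
        tech = 0.0 if math.isinf(self.depth) else 1.0 / self.depth
        return tech + self.cv**2


def de_power(spec: PowerSpec) -> float:
    """Analytic two-sided power of the NB Wald comparison of log means.

    power = Phi(lam - z_{1-a/2}) + Phi(-lam - z_{1-a/2}) with noncentrality
    lam = ln(FC) * sqrt(n / (2 * (1/depth + CV^2))).  At FC = 1 this reduces
    to alpha exactly.
    """
    za = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    lam = math.log(spec.fold_change) * math.sqrt(
        spec.n_per_group / (2.0 * spec.unit_variance)
    )
    return float(stats.norm.cdf(lam - za) + stats.norm.cdf(-lam - za))


def required_n(spec: PowerSpec, target_power: float = 0.8) -> int:
    """Smallest per-group n reaching the target analytic power.

    Closed form: n = 2 (z_{1-a/2} + z_power)^2 (1/depth + CV^2) / ln(FC)^2,
    rounded up.
    """
    if spec.fold_change == 1.0:
        if target_power > spec.alpha:
            raise ValidationError("no n can beat alpha at fold change 1")
        return 2
    za = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    zb = stats.norm.ppf(target_power)
    n = 2.0 * (za + zb) ** 2 * spec.unit_variance / math.log(spec.fold_change) ** 2
    return max(int(math.ceil(n)), 2)


def simulate_power(
    spec: PowerSpec,
    n_genes: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical power by negative-binomial simulation.

    Each simulated gene is an independent replicate: counts for group 1 are
    NB(depth, cv) and for group 2 NB(depth * FC, cv); the per-gene test is
    the Wald comparison of log group means with delta-method variance (the
    normal-reference Wald is mildly liberal at small n, matching the
    asymptotic analytic formula).  Returns the rejection fraction.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    depth = spec.depth if math.isfinite(spec.depth) else 1e4
    n = spec.n_per_group
    size = 1.0 / spec.cv**2          # NB shape: var = mu + mu^2/size
    def draw(mu):
        p = size / (size + mu)
        return rng.negative_binomial(size, p, size=(n_genes, n)).astype(float)
    x1 = draw(depth)
    x2 = draw(depth * spec.fold_change)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    ok = (m1 > 0) & (m2 > 0) & (v1 + v2 > 0)
    se = np.sqrt(v1[ok] / (n * m1[ok] ** 2) + v2[ok] / (n * m2[ok] ** 2))
    z = (np.log(m2[ok]) - np.log(m1[ok])) / se
    reject = 2.0 * stats.norm.sf(np.abs(z)) < spec.alpha
    return float(reject.mean())
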