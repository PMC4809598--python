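"""Synthetic multi-tissue RNA-seq counts and feedlot phenotypes with
planted ground truth.

Expression generator
--------------------
Log2 expected expression is built additively from: a log-normal gene
baseline, a Dirichlet tissue-share profile (tissue-specific genes get a
dominant-tissue spike drawn uniform in [ts_share, 0.95]), a gene-by-animal
effect, a signed gene-by-sire shift for planted DE genes, and a latent
standard-normal factor per hub TF loaded onto the TF and its module
members.  Counts are negative binomial with dispersion = biological_cv^2
around depth-normalized expected counts (expected per-sample total equals
``depth_mean`` exactly).

Hub modules: each hub TF is (up to its own noise) the realization of a
latent standard-normal factor.  Module members split into two roles, both
drawn from pools that stay network nodes downstream:

* SNP-gene members load on the factor in both sire groups with a
  member-factor correlation of ``0.85 * hub_loading``.  TF-member
  correlations then sit clearly above the member-member correlations
  (which decay as the loading squared), so the TF is the degree hub of a
  recoverable star.
* planted-DE members load at ``hub_loading`` in the low sire group and at
  ``hub_loading * (1 - hub_wiring_contrast)`` in the high group, and every
  DE member of one module shares the sign of its planted fold change (the
  TF drives its targets co-directionally).  Hubs are thereby
  differentially wired between groups by construction — the structure the
  regulatory-impact score is designed to detect.

Phenotype generator
-------------------
Per-animal linear growth (weights every 14 d), daily dry matter intake
from DMI = b0 + b1*ADG + b2*MMW + sire shift + noise, Poisson bunk-visit
events with sire-specific rate, and carcass weights in air and water
consistent with a target specific gravity.  Growth parameters are mirrored
between sire groups (pair matching), which makes the planted sire RFI
shift exactly orthogonal to ADG and MMW.

All randomness flows through substreams spawned deterministically from the
design seed; identical seed and parameters give bit-identical output.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GeneAnnotation, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_TISSUES = ("pituitary", "muscle", "liver", "adipose", "duodenum")


@dataclass
class ExperimentDesign:
    n_sires: int = 2
    animals_per_sire: int = 8
    tissues: Tuple[str, ...] = DEFAULT_TISSUES
    n_genes: int = 2000
    n_tf: int = 100
    n_snp_genes: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sires != 2:
            raise ValidationError("exactly 2 sire groups are supported")
        if self.animals_per_sire < 2:
            raise ValidationError("need >= 2 animals per sire group")
        if len(self.tissues) == 0 or len(set(self.tissues)) != len(self.tissues):
            raise ValidationError("tissue labels must be non-empty and unique")
        if self.n_tf + self.n_snp_genes > self.n_genes:
            raise ValidationError("n_tf + n_snp_genes must be <= n_genes")

    @property
    def n_samples(self) -> int:
        return 2 * self.animals_per_sire * len(self.tissues)


@dataclass
class SimParams:
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    ts_fraction: float = 0.05
    ts_share: float = 2.0 / 3.0
    de_fraction: float = 0.075
    de_log2fc: float = 0.85  # log2(1.8): the detectable fold change of the power claim
    biological_cv: float = 0.4
    animal_sd: float = 0.25
    depth_mean: float = 2e6
    n_hub_tf: int = 5
    hub_module_size: int = 60
    hub_loading: float = 0.85
    hub_wiring_contrast: float = 0.8
    hub_factor_scale: float = 2.5
    nonts_concentration: float = 7.0
    length_range: Tuple[int, int] = (500, 5000)

    def __post_init__(self) -> None:
        if self.biological_cv <= 0:
            raise ValidationError("biological_cv must be > 0")
        for name in ("ts_fraction", "de_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0 < self.hub_loading < 1:
            raise ValidationError("hub_loading must be in (0, 1)")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be > 0")


@dataclass
class GroundTruth:
    true_ts: Dict[str, str]
    true_de: Dict[str, float]
    true_hubs: Dict[str, list]

    def as_dict(self) -> dict:
        return {"true_ts": self.true_ts, "true_de": self.true_de,
                "true_hubs": self.true_hubs}


def _substreams(seed: int, n: int) -> list:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_expression(
    design: ExperimentDesign, params: SimParams
) -> Tuple[CountMatrix, pd.DataFrame, GeneAnnotation, GroundTruth]:
    """Generate (CountMatrix, sample metadata, gene annotation, ground truth)."""
    if params.n_hub_tf * params.hub_module_size > design.n_genes:
        raise ValidationError("infeasible design: hub modules exceed the gene count")
    if params.n_hub_tf > design.n_tf:
        raise ValidationError("infeasible design: more hub TFs than TFs")

    (rng_genes, rng_profiles, rng_effects, rng_factors, rng_counts) = _substreams(
        design.seed, 5
    )
    n_genes, tissues = design.n_genes, list(design.tissues)
    n_tis = len(tissues)
    width = max(5, len(str(n_genes)))
    genes = pd.Index([f"G{i:0{width}d}" for i in range(1, n_genes + 1)], name="gene")

    # --- sample layout -----------------------------------------------------
    animals, sires = [], []
    for grp, label in (("L", "low"), ("H", "high")):
        for a in range(1, design.animals_per_sire + 1):
            animals.append(f"{grp}{a:02d}")
            sires.append(label)
    sample_rows = []
    for animal, sire in zip(animals, sires):
        for tissue in tissues:
            sample_rows.append((f"{animal}_{tissue}", animal, sire, tissue))
    meta = pd.DataFrame(
        sample_rows, columns=["sample", "animal", "sire_group", "tissue"]
    ).set_index("sample")
    n_samples = len(meta)
    tissue_idx = np.array([tissues.index(t) for t in meta["tissue"]])
    animal_idx = np.array([animals.index(a) for a in meta["animal"]])
    is_low = (meta["sire_group"] == "low").to_numpy()

    # --- gene-level assignments -------------------------------------------
    lengths = pd.Series(
        rng_genes.integers(params.length_range[0], params.length_range[1] + 1, n_genes),
        index=genes, name="length",
    )
    baseline = rng_genes.normal(params.baseline_log_mean, params.baseline_log_sd, n_genes)

    perm = rng_genes.permutation(n_genes)
    tf_pos = perm[: design.n_tf]
    snp_pos = perm[design.n_tf : design.n_tf + design.n_snp_genes]
    is_tf = np.zeros(n_genes, bool); is_tf[tf_pos] = True
    is_snp = np.zeros(n_genes, bool); is_snp[snp_pos] = True

    n_de = int(round(params.de_fraction * n_genes))
    de_pool = np.flatnonzero(~is_tf)
    de_pos = rng_genes.choice(de_pool, size=n_de, replace=False) if n_de else np.array([], int)
    de_sign = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)  # balanced up/down
    de_effect = np.zeros(n_genes)
    de_effect[de_pos] = de_sign * params.de_log2fc

    n_ts = int(round(params.ts_fraction * n_genes))
    ts_pool = np.flatnonzero(~is_tf & (de_effect == 0))
    n_ts = min(n_ts, len(ts_pool))
    ts_pos = rng_genes.choice(ts_pool, size=n_ts, replace=False) if n_ts else np.array([], int)
    ts_tissue = np.asarray(tissues)[np.arange(n_ts) % n_tis]

    # --- tissue-share profiles --------------------------------------------
    shares = rng_profiles.dirichlet(
        np.full(n_tis, params.nonts_concentration), size=n_genes
    )
    if n_ts:
        dom = rng_profiles.uniform(params.ts_share, 0.95, n_ts)
        rest = rng_profiles.dirichlet(np.ones(n_tis - 1), size=n_ts)
        for i, (pos, tis, d) in enumerate(zip(ts_pos, ts_tissue, dom)):
            j = tissues.index(tis)
            prof = np.empty(n_tis)
            prof[j] = d
            others = [c for c in range(n_tis) if c != j]
            prof[others] = (1.0 - d) * rest[i]
            shares[pos] = prof

    # --- hub modules -------------------------------------------------------
    # residual log2-scale noise (NB biological noise + animal effects) used
    # to convert target member-factor correlations into factor loadings
    sigma_resid = float(np.sqrt(
        np.log1p(params.biological_cv**2) / np.log(2.0) ** 2 + params.animal_sd**2
    ))

    def _loading(rho: float) -> float:
        rho = min(max(rho, 0.0), 0.999)
        return sigma_resid * rho / np.sqrt(1.0 - rho**2)

    true_hubs: Dict[str, list] = {}
    hub_of = np.full(n_genes, -1)
    loading_low = np.zeros(n_genes)
    loading_high = np.zeros(n_genes)
    if params.n_hub_tf:
        n_de_m = params.hub_module_size // 3
        n_snp_m = params.hub_module_size - n_de_m
        ts_set = set(ts_pos.tolist())
        de_plus = [p for p, s in zip(de_pos, de_sign) if s > 0 and p not in ts_set]
        de_minus = [p for p, s in zip(de_pos, de_sign) if s < 0 and p not in ts_set]
        # members must not be planted-TS: module profiles are flattened and
        # would destroy the planted tissue spike
        snp_members = [p for p in snp_pos if de_effect[p] == 0 and p not in ts_set]
        n_plus_modules = (params.n_hub_tf + 1) // 2
        n_minus_modules = params.n_hub_tf // 2
        if (n_de_m * n_plus_modules > len(de_plus)
                or n_de_m * n_minus_modules > len(de_minus)
                or n_snp_m * params.n_hub_tf > len(snp_members)):
            raise ValidationError(
                "infeasible design: not enough DE/SNP genes to populate hub modules"
            )
        de_plus = list(rng_genes.permutation(de_plus))
        de_minus = list(rng_genes.permutation(de_minus))
        snp_members = list(rng_genes.permutation(snp_members))
        rho_snp = 0.85 * params.hub_loading
        for h, tf_p in enumerate(tf_pos[: params.n_hub_tf]):
            pool = de_plus if h % 2 == 0 else de_minus
            k = (h // 2) * n_de_m
            de_m = pool[k: k + n_de_m]
            snp_m = snp_members[h * n_snp_m: (h + 1) * n_snp_m]
            members = list(de_m) + list(snp_m)
            true_hubs[genes[tf_p]] = sorted(genes[m] for m in members)
            hub_of[members] = h
            hub_of[tf_p] = h
            # DE members: wired in the low group, rewired away in the high
            loading_low[de_m] = _loading(params.hub_loading)
            loading_high[de_m] = _loading(
                params.hub_loading * (1.0 - params.hub_wiring_contrast)
            )
            # SNP members: consistent moderate wiring in both groups
            loading_low[snp_m] = loading_high[snp_m] = _loading(rho_snp)
            # the TF is the factor, up to its own residual noise
            loading_low[tf_p] = loading_high[tf_p] = params.hub_factor_scale
            # hub TFs are well-expressed regulators: one-SD baseline boost
            baseline[tf_p] = params.baseline_log_mean + params.baseline_log_sd
            # flatten profiles of module genes so the factor dominates
            shares[members] = 1.0 / n_tis
            shares[tf_p] = 1.0 / n_tis

    # --- assemble log2 expected expression --------------------------------
    log2 = np.tile(baseline[:, None], (1, n_samples))
    log2 += np.log2(np.maximum(shares[:, tissue_idx] * n_tis, 1e-300))
    if params.animal_sd > 0:
        ga = rng_effects.normal(0.0, params.animal_sd, size=(n_genes, len(animals)))
        log2 += ga[:, animal_idx]
    sire_sign = np.where(is_low, 0.5, -0.5)
    log2 += de_effect[:, None] * sire_sign[None, :]
    if params.n_hub_tf:
        factors = rng_factors.normal(0.0, 1.0, size=(params.n_hub_tf, n_samples))
        loading = np.where(is_low[None, :], loading_low[:, None], loading_high[:, None])
        fac = factors[np.maximum(hub_of, 0)] * loading
        fac[hub_of < 0] = 0.0
        log2 += fac

    # --- counts ------------------------------------------------------------
    # gamma-Poisson (negative binomial with dispersion cv^2) biological
    # noise, then per-sample renormalization: sequencing fixes the depth,
    # so totals concentrate at depth_mean while per-gene counts stay NB
    rel = np.exp2(log2 - log2.max()) * lengths.to_numpy()[:, None]
    disp = params.biological_cv**2
    if disp >= 1e-6:
        shape = 1.0 / disp
        rel = rel * rng_counts.gamma(shape, 1.0 / shape, size=rel.shape)
    p = rel / rel.sum(axis=0, keepdims=True)
    counts = rng_counts.poisson(params.depth_mean * p)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=meta.index),
        lengths=lengths,
    )
    annotation = GeneAnnotation(
        table=pd.DataFrame({"is_tf": is_tf, "is_snp": is_snp}, index=genes)
    )
    truth = GroundTruth(
        true_ts={genes[p_]: t for p_, t in zip(ts_pos, ts_tissue)},
        true_de={genes[p_]: float(de_effect[p_]) for p_ in de_pos},
        true_hubs=true_hubs,
    )
    return cm, meta, annotation, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenoParams:
    initial_weight_mean: float = 254.0
    initial_weight_sd: float = 10.0
    slope_mean: float = 1.71
    slope_sd: float = 0.15
    weight_noise_sd: float = 0.0
    n_weighings: int = 6
    interval_days: int = 14
    b0: float = 1.0
    b1: float = 2.0
    b2: float = 0.07
    rfi_shift: float = -0.6          # planted low - high RFI difference, kg DM/d
    dmi_noise_sd: float = 0.3
    visit_rate_low: float = 51.2     # bunk visits per day
    visit_rate_high: float = 64.1
    visit_duration_mean: float = 1.87
    visit_duration_sd: float = 0.4
    dressing: float = 0.60
    sg_mean: float = 1.08
    sg_sd: float = 0.002
    sg_shift: float = 0.0045         # planted low - high specific gravity difference
    period: str = "growing"

    def __post_init__(self) -> None:
        if self.initial_weight_mean <= 0:
            raise ValidationError("initial weight must be positive")
        if self.n_weighings < 3:
            raise ValidationError("need >= 3 weighings per animal")


@dataclass
class PhenotypeTable:
    animals: pd.DataFrame      # index animal; sire_group
    weights: pd.DataFrame      # animal, day, weight_kg
    dmi: pd.DataFrame          # animal, day, dmi_kg
    events: pd.DataFrame       # animal, day, duration_min
    carcass: pd.DataFrame      # index animal; cw_kg, cw_h2o_kg
    period: str
    truth: dict = field(default_factory=dict)


def simulate_phenotypes(
    design: ExperimentDesign, params: Optional[PhenoParams] = None
) -> PhenotypeTable:
    params = params or PhenoParams()
    rng_growth, rng_intake, rng_visits, rng_carcass = _substreams(design.seed + 1_000_003, 4)

    n = design.animals_per_sire
    animals = [f"L{a:02d}" for a in range(1, n + 1)] + [f"H{a:02d}" for a in range(1, n + 1)]
    sires = ["low"] * n + ["high"] * n
    # growth parameters mirrored between groups: the planted RFI shift is
    # exactly orthogonal to ADG and MMW in-sample
    w0 = np.clip(rng_growth.normal(params.initial_weight_mean, params.initial_weight_sd, n), 1.0, None)
    slope = rng_growth.normal(params.slope_mean, params.slope_sd, n)
    w0 = np.concatenate([w0, w0])
    slope = np.concatenate([slope, slope])

    days = np.arange(params.n_weighings) * params.interval_days
    n_days = int(days[-1]) if days[-1] > 0 else params.interval_days

    weight_rows, dmi_rows, event_rows = [], [], []
    carcass_rows = []
    shift = np.where(np.array(sires) == "low", params.rfi_shift / 2.0, -params.rfi_shift / 2.0)
    for i, (animal, sire) in enumerate(zip(animals, sires)):
        w = w0[i] + slope[i] * days
        if params.weight_noise_sd > 0:
            w = w + rng_growth.normal(0.0, params.weight_noise_sd, len(days))
        if (w <= 0).any():
            raise ValidationError("simulated non-positive body weight; check parameters")
        for d, wt in zip(days, w):
            weight_rows.append((animal, int(d), float(wt)))
        adg = slope[i]
        mmw = float(np.mean(w) ** 0.75)
        dmi_mean = params.b0 + params.b1 * adg + params.b2 * mmw + shift[i]
        noise = rng_intake.normal(0.0, params.dmi_noise_sd) if params.dmi_noise_sd > 0 else 0.0
        daily = np.clip(dmi_mean + noise, 0.0, None)
        for d in range(1, n_days + 1):
            dmi_rows.append((animal, d, float(daily)))
        rate = params.visit_rate_low if sire == "low" else params.visit_rate_high
        visits_per_day = rng_visits.poisson(rate, n_days)
        for d, v in enumerate(visits_per_day, start=1):
            if v == 0:
                continue
            durations = np.clip(
                rng_visits.normal(params.visit_duration_mean, params.visit_duration_sd, v),
                0.1, None,
            )
            for dur in durations:
                event_rows.append((animal, d, float(dur)))
        final_weight = w[-1]
        cw = params.dressing * final_weight
        sg = rng_carcass.normal(params.sg_mean, params.sg_sd) + (
            params.sg_shift / 2.0 if sire == "low" else -params.sg_shift / 2.0
        )
        sg = max(sg, 1.0 + 1e-6)
        cw_h2o = cw * (1.0 - 1.0 / sg)
        carcass_rows.append((animal, float(cw), float(cw_h2o)))

    return PhenotypeTable(
        animals=pd.DataFrame({"sire_group": sires}, index=pd.Index(animals, name="animal")),
        weights=pd.DataFrame(weight_rows, columns=["animal", "day", "weight_kg"]),
        dmi=pd.DataFrame(dmi_rows, columns=["animal", "day", "dmi_kg"]),
        events=pd.DataFrame(event_rows, columns=["animal", "day", "duration_min"]),
        carcass=pd.DataFrame(carcass_rows, columns=["animal", "cw_kg", "cw_h2o_kg"]).set_index("animal"),
        period=params.period,
        truth={
            "rfi_shift": params.rfi_shift,
            "visit_rate_low": params.visit_rate_low,
            "visit_rate_high": params.visit_rate_high,
            "sg_shift": params.sg_shift,
        },
    )
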