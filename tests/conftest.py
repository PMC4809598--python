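import numpy as np
import pandas as pd
import pytest

from rfinet.datatypes import CountMatrix
from rfinet.simulate import ExperimentDesign, SimParams, simulate_expression

TISSUES = ["pituitary", "muscle", "liver", "adipose", "duodenum"]


def balanced_meta(n_animals_per_sire=8, tissues=TISSUES):
    """Sample metadata for the full 2 x n x tissues layout."""
    rows = []
    for grp, label in (("L", "low"), ("H", "high")):
        for a in range(1, n_animals_per_sire + 1):
            animal = f"{grp}{a:02d}"
            for t in tissues:
                rows.append((f"{animal}_{t}", animal, label, t))
    return (
        pd.DataFrame(rows, columns=["sample", "animal", "sire_group", "tissue"])
        .set_index("sample")
    )


def simulate_mixed_model_y(
    meta,
    n_genes,
    varcomp,
    rng,
    mu=2.0,
    sire_effects=None,
):
    """Draw log2 expression directly from the crossed random-effects model.

    ``sire_effects``: optional (n_genes,) array added to low-group samples
    and subtracted from high-group samples (half each), planting DE.
    """
    tissues = sorted(meta["tissue"].unique())
    animals = sorted(meta["animal"].unique())
    t_idx = meta["tissue"].map({t: i for i, t in enumerate(tissues)}).to_numpy()
    a_idx = meta["animal"].map({a: i for i, a in enumerate(animals)}).to_numpy()
    s_idx = (meta["sire_group"] == "high").to_numpy().astype(int)
    n = len(meta)
    Y = np.full((n_genes, n), float(mu))
    Y += rng.normal(0, np.sqrt(varcomp["G"]), (n_genes, 1))
    Y += rng.normal(0, np.sqrt(varcomp["GT"]), (n_genes, len(tissues)))[:, t_idx]
    Y += rng.normal(0, np.sqrt(varcomp["GA"]), (n_genes, len(animals)))[:, a_idx]
    Y += rng.normal(0, np.sqrt(varcomp["GS"]), (n_genes, 2))[:, s_idx]
    Y += rng.normal(0, np.sqrt(varcomp["e"]), (n_genes, n))
    if sire_effects is not None:
        sign = np.where(s_idx == 0, 0.5, -0.5)
        Y += np.asarray(sire_effects)[:, None] * sign[None, :]
    return pd.DataFrame(
        Y, index=[f"g{i:04d}" for i in range(n_genes)], columns=meta.index
    )


@pytest.fixture(scope="session")
def meta80():
    return balanced_meta()


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic dataset shared across tests."""
    design = ExperimentDesign(seed=11, n_genes=400, n_tf=30, n_snp_genes=60)
    params = SimParams(
        ts_fraction=0.1, de_fraction=0.1, n_hub_tf=3, hub_module_size=10,
        depth_mean=5e5,
    )
    return design, params, simulate_expression(design, params)


def toy_counts(counts, lengths=None, totals=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    if lengths is None:
        lengths = pd.Series(1000.0, index=counts.index)
    else:
        lengths = pd.Series(np.asarray(lengths, float), index=counts.index)
    if totals is not None:
        totals = pd.Series(np.asarray(totals, float), index=counts.columns)
    return CountMatrix(counts=counts, lengths=lengths, totals=totals)
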