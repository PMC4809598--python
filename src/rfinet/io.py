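"""Plain-text readers/writers and input validation for the pipeline formats.

Formats (all uncompressed text):

* counts.tsv        gene x sample integer counts, first column ``gene``
* gene_lengths.tsv  gene, length_bp
* samples.tsv       sample, animal, sire_group, tissue
* annotation.tsv    gene, is_tf, is_snp[, go_terms (';'-separated)]
* phenotypes.csv    long: animal, sire_group, day, weight_kg, dmi_kg
* events.csv        animal, day, duration_min
* truth.json        planted ground truth from the simulator
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GeneAnnotation, ValidationError, validate_sample_meta
from .simulate import GroundTruth, PhenotypeTable


def write_counts(cm: CountMatrix, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene")
    cm.lengths.rename("length_bp").to_csv(outdir / "gene_lengths.tsv", sep="\t", index_label="gene")


def read_counts(counts_path: Path, lengths_path: Path, totals: pd.Series | None = None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene")["length_bp"]
    return CountMatrix(counts=counts, lengths=lengths, totals=totals)


def write_samples(meta: pd.DataFrame, outdir: Path) -> None:
    meta.to_csv(Path(outdir) / "samples.tsv", sep="\t", index_label="sample")


def read_samples(path: Path) -> pd.DataFrame:
    return validate_sample_meta(pd.read_csv(path, sep="\t", index_col="sample"))


def write_annotation(annotation: GeneAnnotation, outdir: Path) -> None:
    annotation.table.to_csv(Path(outdir) / "annotation.tsv", sep="\t", index_label="gene")


def read_annotation(path: Path) -> GeneAnnotation:
    return GeneAnnotation(table=pd.read_csv(path, sep="\t", index_col="gene"))


def write_truth(truth: GroundTruth, outdir: Path) -> None:
    with open(Path(outdir) / "truth.json", "w") as fh:
        json.dump(truth.as_dict(), fh, indent=1, sort_keys=True)


def read_truth(path: Path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(true_ts=d["true_ts"], true_de=d["true_de"], true_hubs=d["true_hubs"])


def write_phenotypes(table: PhenotypeTable, outdir: Path) -> None:
    outdir = Path(outdir)
    long = table.weights.merge(table.dmi, on=["animal", "day"], how="outer")
    long = long.merge(table.animals, left_on="animal", right_index=True)
    long = long.sort_values(["animal", "day"]).reset_index(drop=True)
    long[["animal", "sire_group", "day", "weight_kg", "dmi_kg"]].to_csv(
        outdir / "phenotypes.csv", index=False
    )
    table.events.to_csv(outdir / "events.csv", index=False)
    table.carcass.to_csv(outdir / "carcass.csv", index_label="animal")


def read_phenotypes(pheno_path: Path, events_path: Path | None = None,
                    carcass_path: Path | None = None, period: str = "growing") -> PhenotypeTable:
    long = pd.read_csv(pheno_path)
    animals = long[["animal", "sire_group"]].drop_duplicates().set_index("animal")
    weights = long.dropna(subset=["weight_kg"])[["animal", "day", "weight_kg"]].reset_index(drop=True)
    dmi = long.dropna(subset=["dmi_kg"])[["animal", "day", "dmi_kg"]].reset_index(drop=True)
    events = pd.read_csv(events_path) if events_path else pd.DataFrame(columns=["animal", "day", "duration_min"])
    carcass = pd.read_csv(carcass_path, index_col="animal") if carcass_path else pd.DataFrame()
    return PhenotypeTable(animals=animals, weights=weights, dmi=dmi, events=events,
                          carcass=carcass, period=period)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Diagnostics:
    findings: List[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.findings.append(msg)

    @property
    def ok(self) -> bool:
        return not self.findings


def validate_inputs(
    counts_path: Path | None = None,
    lengths_path: Path | None = None,
    samples_path: Path | None = None,
    annotation_path: Path | None = None,
    phenotypes_path: Path | None = None,
) -> Diagnostics:
    """Schema checks with row/column-addressed findings (does not raise)."""
    diag = Diagnostics()
    counts = None
    if counts_path is not None:
        try:
            counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
        except Exception as exc:
            diag.add(f"{counts_path}: unreadable ({exc})")
        else:
            arr = counts.to_numpy()
            bad = np.argwhere(~(arr >= 0)) if arr.size else np.empty((0, 2), int)
            for r, c in bad[:20]:
                diag.add(
                    f"{counts_path}: negative or non-numeric count at gene "
                    f"{counts.index[r]!r}, sample {counts.columns[c]!r}"
                )
            if counts.index.duplicated().any():
                diag.add(f"{counts_path}: duplicate gene ids")
    if lengths_path is not None:
        try:
            lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene")["length_bp"]
        except Exception as exc:
            diag.add(f"{lengths_path}: unreadable ({exc})")
        else:
            for gene in lengths.index[lengths <= 0][:20]:
                diag.add(f"{lengths_path}: non-positive length for gene {gene!r}")
            if counts is not None:
                missing = counts.index.difference(lengths.index)
                if len(missing):
                    diag.add(f"{lengths_path}: {len(missing)} genes without length")
    if samples_path is not None:
        try:
            meta = pd.read_csv(samples_path, sep="\t", index_col="sample")
            validate_sample_meta(meta)
        except ValidationError as exc:
            diag.add(f"{samples_path}: {exc}")
        except Exception as exc:
            diag.add(f"{samples_path}: unreadable ({exc})")
    if annotation_path is not None:
        try:
            pd.read_csv(annotation_path, sep="\t", index_col="gene")
        except Exception as exc:
            diag.add(f"{annotation_path}: unreadable ({exc})")
    if phenotypes_path is not None:
        try:
            long = pd.read_csv(phenotypes_path)
        except Exception as exc:
            diag.add(f"{phenotypes_path}: unreadable ({exc})")
        else:
            required = {"animal", "sire_group", "day", "weight_kg", "dmi_kg"}
            missing = required - set(long.columns)
            if missing:
                diag.add(f"{phenotypes_path}: missing columns {sorted(missing)}")
            elif "weight_kg" in long:
                bad_rows = long.index[long["weight_kg"] <= 0].tolist()
                for r in bad_rows[:20]:
                    diag.add(f"{phenotypes_path}: non-positive weight at row {r + 2}")
                per_animal = long.groupby("animal")["sire_group"].nunique()
                for a in per_animal[per_animal > 1].index:
                    diag.add(f"{phenotypes_path}: animal {a!r} appears in two sire groups")
    return diag
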