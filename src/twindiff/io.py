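"""Readers and writers for the pipeline's on-disk formats.

Everything is plain TSV/GMT/JSON/YAML. Readers validate container invariants
on load and reject rather than coerce, with one documented exception: Beta
values at or beyond the (0, 1) boundary are clamped to [1e-6, 1 - 1e-6] with
a warning, since boundary Betas are routine artefacts of array preprocessing
and the downstream M-value transform requires the open interval.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    BETA_EPS,
    CountMatrix,
    GeneSetCollection,
    MethylationSet,
    SampleSheet,
    ValidationError,
)


def read_counts(path) -> CountMatrix:
    """Read a gene x sample count TSV (first column gene id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pair_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, members."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields (name, description, members)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_methylation(beta_path, manifest_path) -> MethylationSet:
    """Read a Beta-value TSV and a 4-column probe manifest (chrom, position, probe, gene).

    Beta values outside the open interval (0, 1) are clamped to
    [1e-6, 1 - 1e-6] with a warning; the manifest may use either the
    positional BED-like column order or named columns.
    """
    beta = pd.read_csv(beta_path, sep="\t", index_col=0).astype(float)
    manifest = pd.read_csv(manifest_path, sep="\t")
    expected = ["chrom", "position", "probe_id", "gene_id"]
    if not set(expected) <= set(manifest.columns):
        manifest = pd.read_csv(
            manifest_path, sep="\t", header=None, names=expected
        )
    manifest["probe_id"] = manifest["probe_id"].astype(str)
    beta.index = beta.index.astype(str)

    vals = beta.to_numpy()
    out_of_range = (vals <= 0.0) | (vals >= 1.0)
    n_clamped = int(out_of_range.sum())
    if n_clamped:
        warnings.warn(
            f"clamped {n_clamped} Beta values to [{BETA_EPS}, {1 - BETA_EPS}]",
            stacklevel=2,
        )
        beta = beta.clip(lower=BETA_EPS, upper=1.0 - BETA_EPS)
    return MethylationSet(beta, manifest)


def write_methylation(meth: MethylationSet, beta_path, manifest_path) -> None:
    meth.beta.to_csv(beta_path, sep="\t", index_label="probe_id")
    meth.manifest[["chrom", "position", "probe_id", "gene_id"]].to_csv(
        manifest_path, sep="\t", index=False
    )


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV."""
    df.to_csv(path, sep="\t", index=index)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: run config must be a YAML mapping")
    return cfg
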