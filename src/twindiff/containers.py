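"""Core in-memory containers for the twin-cohort pipeline.

All tabular data is held in pandas objects; the dataclasses below add the
domain invariants (pair structure, value ranges, manifest completeness) that
plain DataFrames cannot enforce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GROUPS = ("discordant", "concordant_case", "control")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample count table.

    `counts` is a DataFrame indexed by gene id with sample ids as columns.
    Library sizes are always the column sums of the current matrix, so they
    stay consistent under gene filtering.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
                raise ValidationError(
                    f"non-integer count at gene {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if vals.size and vals.min() < 0:
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)])


@dataclass
class SampleSheet:
    """Per-sample metadata: twin-pair membership, study group, case status, sex.

    Groups follow the three-arm discordant-twin design: ``discordant`` pairs
    have exactly one affected co-twin, ``concordant_case`` pairs have two,
    ``control`` pairs have none. Singleton samples (co-twin missing) are
    permitted on load but excluded from paired analyses.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "pair_id", "group", "case", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        bad_groups = set(t["group"]) - set(VALID_GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown groups: {sorted(bad_groups)}")
        if not t["case"].isin([0, 1]).all():
            raise ValidationError("case must be 0/1")
        for pair_id, sub in t.groupby("pair_id"):
            if len(sub) > 2:
                raise ValidationError(f"pair {pair_id!r} has {len(sub)} samples (max 2)")
            if len(sub) < 2:
                continue
            group = sub["group"].iloc[0]
            if sub["group"].nunique() > 1:
                raise ValidationError(f"pair {pair_id!r} spans multiple groups")
            ncase = int(sub["case"].sum())
            if group == "discordant" and ncase != 1:
                raise ValidationError(
                    f"discordant pair {pair_id!r} has {ncase} cases (expected 1)"
                )
            if group == "concordant_case" and ncase != 2:
                raise ValidationError(
                    f"concordant_case pair {pair_id!r} has {ncase} cases (expected 2)"
                )
            if group == "control" and ncase != 0:
                raise ValidationError(
                    f"control pair {pair_id!r} has {ncase} cases (expected 0)"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def complete_pairs(self) -> pd.DataFrame:
        """Rows belonging to pairs with both co-twins present."""
        sizes = self.table.groupby("pair_id")["sample_id"].transform("size")
        return self.table[sizes == 2].reset_index(drop=True)

    def subset(self, sample_ids) -> "SampleSheet":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleSheet(keep.reset_index(drop=True))

    def pair_members(self) -> dict:
        """pair_id -> list of sample ids in sheet order, complete pairs only."""
        cp = self.complete_pairs()
        return {pid: list(sub["sample_id"]) for pid, sub in cp.groupby("pair_id", sort=False)}


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT semantics)."""

    sets: dict  # name -> list of member gene ids (order preserved)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str):
        return self.sets[name]


BETA_EPS = 1e-6


@dataclass
class MethylationSet:
    """Beta-value probe x sample matrix plus a genomic probe manifest.

    The manifest maps each probe to (chrom, 1-based position, gene id); every
    probe in the beta matrix must have a manifest row. Beta values are kept
    strictly inside (0, 1) — readers clamp boundary values to
    [BETA_EPS, 1 - BETA_EPS] before constructing this container.
    """

    beta: pd.DataFrame  # probes x samples
    manifest: pd.DataFrame  # columns: probe_id, chrom, position, gene_id

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            raise ValidationError("duplicate probe ids in beta matrix")
        req = {"probe_id", "chrom", "position", "gene_id"}
        missing = req - set(self.manifest.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        if self.manifest["probe_id"].duplicated().any():
            raise ValidationError("duplicate probe ids in manifest")
        manifest_probes = set(self.manifest["probe_id"])
        unmapped = set(self.beta.index) - manifest_probes
        if unmapped:
            raise ValidationError(
                f"{len(unmapped)} probes missing from manifest, e.g. {sorted(unmapped)[:3]}"
            )
        if (self.manifest["position"] < 0).any():
            raise ValidationError("negative probe positions")
        extra = manifest_probes - set(self.beta.index)
        if extra:
            warnings.warn(
                f"dropping {len(extra)} manifest probes absent from beta matrix",
                stacklevel=2,
            )
            self.manifest = self.manifest[
                self.manifest["probe_id"].isin(set(self.beta.index))
            ].reset_index(drop=True)
        vals = self.beta.to_numpy(dtype=float)
        if vals.size and (vals.min() <= 0.0 or vals.max() >= 1.0):
            raise ValidationError("beta values must lie strictly in (0, 1); clamp on load")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    def probes_for_gene(self, gene_id: str) -> list:
        m = self.manifest
        return list(m.loc[m["gene_id"] == gene_id, "probe_id"])
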