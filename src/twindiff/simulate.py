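"""Synthetic twin-cohort generator with known ground truth.

Emulates the data structure of a discordant monozygotic (MZ) twin study of
blood transcriptomes: three study arms (discordant pairs with one affected
co-twin, concordant affected pairs, unaffected control pairs), negative
binomial RNA-seq counts with shared within-pair effects, and sparse
array-style CpG methylation with spatially correlated probe signal.

Counts for gene g in sample s are drawn as

    y_gs ~ NB(mu_gs, phi_g),   Var = mu + phi * mu^2

    ln mu_gs = b_g + u_{p(s),g} * ln2 + case_s * 1[g in DE] * beta_g * ln2
               + ln(L_s / 1e6)

where b_g = baseline logCPM * ln2, u_{p,g} is a per-pair per-gene effect
(log2 scale, sd ``pair_effect_sd``) shared by both co-twins, beta_g is the
true log2 fold change and L_s the target library size. The natural-log link
with an ln(L/1e6) offset makes b_g directly interpretable as logCPM * ln2,
matching the convention of the downstream GLM.

Methylation M-values for the probes of one gene follow a stationary AR(1)
along genomic position with parameter ``meth_spatial_rho``; affected samples
of differentially methylated genes are shifted by ``meth_case_delta_m``
M-units, and Beta = 2^M / (2^M + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, MethylationSet, SampleSheet, ValidationError
from . import io as tdio

LN2 = float(np.log(2.0))

_META_BASELINE_SD = 1.5  # sd of per-probe baseline M-values
_META_NOISE_SD = 1.0  # marginal sd of the AR(1) probe noise (M-units)
_GENE_SPACING_BP = 1_000_000  # genes far apart so cis windows never cross genes
_N_CHROMS = 22


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror a desk-scale version of
    the study cohort (5 discordant + 4 concordant-affected + 8 control
    complete pairs = 34 samples)."""

    n_pairs_discordant: int = 5
    n_pairs_concordant_case: int = 4
    n_pairs_control: int = 8
    n_singletons: int = 0
    n_genes: int = 2000
    n_de_genes: int = 50
    de_logfc: float = 2.0
    pair_effect_sd: float = 0.5
    baseline_logcpm_range: tuple = (0.0, 8.0)
    dispersion_shape: float = 2.0
    dispersion_rate: float = 10.0
    library_size_range: tuple = (1_000_000, 5_000_000)
    n_probes_per_gene_mean: float = 1.5
    meth_case_delta_m: float = 2.0
    meth_spatial_rho: float = 0.6
    probe_spacing_bp: int = 500
    n_linked_genes: int = 10
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_pairs_discordant, self.n_pairs_concordant_case,
               self.n_pairs_control, self.n_singletons) < 0:
            raise ValidationError("pair/singleton counts must be >= 0")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ValidationError("need 0 <= n_de_genes <= n_genes")
        if not np.isfinite(self.de_logfc):
            raise ValidationError("de_logfc must be finite")
        if not (0.0 <= self.meth_spatial_rho < 1.0):
            raise ValidationError("meth_spatial_rho must lie in [0, 1)")
        if self.n_linked_genes > self.n_de_genes:
            raise ValidationError("n_linked_genes must be <= n_de_genes")
        if self.dispersion_shape <= 0 or self.dispersion_rate <= 0:
            raise ValidationError("gamma dispersion hyperparameters must be > 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValidationError("library_size_range must be positive and ordered")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    de_genes: dict  # gene id -> true log2 fold change
    dm_genes: list  # gene ids with a true methylation case effect
    linked_genes: list  # genes with effects in BOTH assays
    true_dispersions: dict  # gene id -> phi_g
    true_pair_effects: dict  # pair id -> list of per-gene log2 effects

    def to_json_dict(self) -> dict:
        return asdict(self)


def _build_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []

    def add_pair(pair_id, group, cases):
        sex = "M" if rng.random() < 0.7 else "F"
        for i, case in enumerate(cases, start=1):
            rows.append(
                {"sample_id": f"{pair_id}t{i}", "pair_id": pair_id,
                 "group": group, "case": case, "sex": sex}
            )

    for i in range(config.n_pairs_discordant):
        cases = [1, 0] if rng.random() < 0.5 else [0, 1]
        add_pair(f"D{i + 1:02d}", "discordant", cases)
    for i in range(config.n_pairs_concordant_case):
        add_pair(f"Q{i + 1:02d}", "concordant_case", [1, 1])
    for i in range(config.n_pairs_control):
        add_pair(f"K{i + 1:02d}", "control", [0, 0])
    groups = ["discordant", "concordant_case", "control"]
    for i in range(config.n_singletons):
        group = groups[i % 3]
        case = {"discordant": int(rng.random() < 0.5), "concordant_case": 1, "control": 0}[group]
        sex = "M" if rng.random() < 0.7 else "F"
        rows.append(
            {"sample_id": f"X{i + 1:02d}t1", "pair_id": f"X{i + 1:02d}",
             "group": group, "case": case, "sex": sex}
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig):
    """Generate (CountMatrix, MethylationSet, SampleSheet, GroundTruth).

    Deterministic given ``config.seed``: calling twice with the same config
    yields bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sheet_df = _build_sheet(config, rng)
    n_samples = len(sheet_df)
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    # --- expression ---------------------------------------------------------
    baseline_logcpm = rng.uniform(*config.baseline_logcpm_range, size=config.n_genes)
    phi = rng.gamma(config.dispersion_shape, 1.0 / config.dispersion_rate,
                    size=config.n_genes)
    phi = np.maximum(phi, 1e-4)

    de_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    de_idx.sort()
    de_sign = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    true_logfc = np.zeros(config.n_genes)
    true_logfc[de_idx] = config.de_logfc * de_sign

    pair_ids = list(dict.fromkeys(sheet_df["pair_id"]))
    pair_effects = {
        pid: rng.normal(0.0, config.pair_effect_sd, size=config.n_genes)
        for pid in pair_ids
    }

    lib_sizes = rng.integers(config.library_size_range[0],
                             config.library_size_range[1] + 1, size=n_samples)
    case = sheet_df["case"].to_numpy()

    log_mu = (baseline_logcpm[:, None] * LN2
              + np.column_stack([pair_effects[p] for p in sheet_df["pair_id"]]) * LN2
              + true_logfc[:, None] * LN2 * case[None, :]
              + np.log(lib_sizes / 1e6)[None, :])
    mu = np.exp(log_mu)
    shape = 1.0 / phi[:, None]
    counts = rng.poisson(rng.gamma(shape, mu / shape))
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids,
                                  columns=list(sheet_df["sample_id"]), dtype=np.int64))

    # --- methylation --------------------------------------------------------
    # linked genes: first n_linked DE genes; an equal number of non-DE genes
    # receive a methylation-only effect so integration has true negatives to
    # rank against.
    linked_idx = de_idx[: config.n_linked_genes]
    non_de = np.setdiff1d(np.arange(config.n_genes), de_idx)
    n_dm_only = min(config.n_linked_genes, len(non_de))
    dm_only_idx = rng.choice(non_de, size=n_dm_only, replace=False) if n_dm_only else np.array([], dtype=int)
    dm_idx = np.sort(np.concatenate([linked_idx, dm_only_idx]).astype(int))
    dm_set = set(dm_idx.tolist())

    n_probes = rng.poisson(config.n_probes_per_gene_mean, size=config.n_genes)
    n_probes[dm_idx] = np.maximum(n_probes[dm_idx], 1)

    probe_rows = []
    m_blocks = []
    rho = config.meth_spatial_rho
    innov_sd = _META_NOISE_SD * np.sqrt(max(1.0 - rho * rho, 0.0))
    for g in range(config.n_genes):
        k = int(n_probes[g])
        if k == 0:
            continue
        chrom = f"chr{g % _N_CHROMS + 1}"
        start = 1 + (g // _N_CHROMS) * _GENE_SPACING_BP
        base = rng.normal(0.0, _META_BASELINE_SD, size=k)
        noise = np.empty((k, n_samples))
        noise[0] = rng.normal(0.0, _META_NOISE_SD, size=n_samples)
        for i in range(1, k):
            noise[i] = rho * noise[i - 1] + rng.normal(0.0, innov_sd, size=n_samples)
        m = base[:, None] + noise
        if g in dm_set:
            m = m + config.meth_case_delta_m * case[None, :]
        m_blocks.append(m)
        for i in range(k):
            probe_rows.append(
                {"probe_id": f"cg{g + 1:05d}_{i + 1}", "chrom": chrom,
                 "position": start + i * config.probe_spacing_bp,
                 "gene_id": gene_ids[g]}
            )

    manifest = pd.DataFrame(probe_rows,
                            columns=["probe_id", "chrom", "position", "gene_id"])
    m_all = np.vstack(m_blocks) if m_blocks else np.empty((0, n_samples))
    beta = np.exp2(m_all) / (np.exp2(m_all) + 1.0)
    beta = np.clip(beta, 1e-6, 1.0 - 1e-6)
    meth = MethylationSet(
        pd.DataFrame(beta, index=list(manifest["probe_id"]),
                     columns=list(sheet_df["sample_id"])),
        manifest,
    )

    truth = GroundTruth(
        de_genes={gene_ids[i]: float(true_logfc[i]) for i in de_idx},
        dm_genes=[gene_ids[i] for i in dm_idx],
        linked_genes=[gene_ids[i] for i in linked_idx],
        true_dispersions={gene_ids[i]: float(phi[i]) for i in range(config.n_genes)},
        true_pair_effects={p: [float(v) for v in eff] for p, eff in pair_effects.items()},
    )
    return cm, meth, SampleSheet(sheet_df), truth


def write_fixture(dir_path, config: SimulationConfig | None = None, cohort=None):
    """Simulate (or reuse a passed cohort) and write the five fixture files.

    Returns a dict of the paths written: counts, beta, manifest, sheet, truth.
    """
    if cohort is None:
        if config is None:
            config = SimulationConfig()
        cohort = simulate_cohort(config)
    cm, meth, sheet, truth = cohort
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": dir_path / "counts.tsv",
        "beta": dir_path / "beta.tsv",
        "manifest": dir_path / "probes.tsv",
        "sheet": dir_path / "sheet.tsv",
        "truth": dir_path / "truth.json",
    }
    tdio.write_counts(cm, paths["counts"])
    tdio.write_methylation(meth, paths["beta"], paths["manifest"])
    tdio.write_sample_sheet(sheet, paths["sheet"])
    tdio.write_truth(truth.to_json_dict(), paths["truth"])
    return paths
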