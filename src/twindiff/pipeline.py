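"""End-to-end orchestration of the twin-cohort analyses.

Stage order: low-expression filter -> QC -> (optional SVA) -> paired NB
differential expression (discordant-group and/or case-control) ->
within-pair |logFC| comparisons -> gene-set enrichment -> methylation
integration. Every stochastic stage draws from its own generator, derived
from the master seed and the stage name, so toggling one stage never
perturbs another. Outputs are plain TSV/JSON plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tdio
from . import qc as tdqc
from .containers import CountMatrix, SampleSheet, ValidationError
from .de import build_design, estimate_dispersions, lrt_case, per_pair_logfc, tmm_factors
from .genesets import run_collection
from .integration import _probe_frame, beta_to_m, diff_methylation, estimate_acf, integrate, slk_adjust
from .sva import augment_design, estimate_svs
from .withinpair import collect_abs_logfc

__version__ = "0.1.0"

ANALYSES = ("discordant_group", "case_control")


@dataclass
class RunConfig:
    counts: str
    sheet: str
    out_dir: str
    beta: str | None = None
    manifest: str | None = None
    gmt: str | None = None
    analyses: tuple = ANALYSES
    fdr_threshold: float = 0.1
    min_cpm: float = 1.0
    min_samples: int = 3
    dist: int = 2000
    top_k: int = 20
    n_perm: int = 10000
    prior_df: float = 10.0
    sva: bool = False
    sva_alpha: float = 0.05
    male_only: bool = False
    remove_outliers: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fdr_threshold < 1):
            raise ValidationError("fdr_threshold must lie in (0, 1)")
        if not (0 < self.sva_alpha < 1):
            raise ValidationError("sva_alpha must lie in (0, 1)")
        for a in self.analyses:
            if a not in ANALYSES:
                raise ValidationError(f"unknown analysis {a!r}")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master
    seed and the stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def subgroup_filter(sheet: SampleSheet, male_only: bool) -> SampleSheet:
    """Retain complete male pairs only (whole pairs, never half a pair)."""
    if not male_only:
        return sheet
    t = sheet.table
    male_pairs = {pid for pid, sub in t.groupby("pair_id")
                  if len(sub) == 2 and (sub["sex"] == "M").all()}
    if not male_pairs:
        raise ValidationError("no complete male pairs remain")
    return SampleSheet(t[t["pair_id"].isin(male_pairs)].reset_index(drop=True))


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_warnings: list = []

    cm = tdio.read_counts(config.counts)
    sheet = tdio.read_sample_sheet(config.sheet)
    sheet = subgroup_filter(sheet, config.male_only)
    cm = cm.subset_samples([s for s in cm.sample_ids if s in set(sheet.sample_ids)])

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        cm = tdqc.filter_low_expression(cm, config.min_cpm, config.min_samples)
        lcm = tdqc.cpm(cm, log=True)
        qc_report = tdqc.pairwise_correlation(lcm, sheet)
        flagged = tdqc.flag_outliers(qc_report)
        pd.DataFrame({
            "metric": ["median_within_pair_r", "median_unrelated_r", "outliers"],
            "value": [qc_report.median_within_pair_r,
                      qc_report.median_unrelated_r, ";".join(map(str, flagged))],
        }).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        if config.remove_outliers and flagged:
            keep = [s for s in cm.sample_ids if s not in set(flagged)]
            cm = cm.subset_samples(keep)
            sheet = sheet.subset(keep)
            lcm = tdqc.cpm(cm, log=True)

        norm = tmm_factors(cm)
        de_tables = {}
        for analysis in config.analyses:
            design = build_design(sheet, analysis)
            if config.sva:
                svs = estimate_svs(lcm, design, alpha=config.sva_alpha,
                                   seed=stage_seed(config.seed, f"sva:{analysis}"))
                if svs.n_sv:
                    pd.DataFrame(svs.sv, index=svs.sample_ids,
                                 columns=[f"sv{i+1}" for i in range(svs.n_sv)]
                                 ).to_csv(out / f"sv_{analysis}.tsv", sep="\t")
                design = augment_design(design, svs)
            disp = estimate_dispersions(cm, design, norm, prior_df=config.prior_df)
            de = lrt_case(cm, sheet, analysis, norm=norm, design=design,
                          dispersions=disp)
            de_tables[analysis] = de
            tdio.write_table(
                de[["gene_id", "logFC", "logCPM", "p_value", "fdr",
                    "consistent_direction"]],
                out / f"de_{analysis}.tsv")

        pp = per_pair_logfc(cm, sheet, norm)
        wp = collect_abs_logfc(pp, sheet)
        with open(out / "within_pair.tsv", "w") as fh:
            fh.write(f"# caveat: {wp.caveat}\n")
            wp.tests.to_csv(fh, sep="\t", index=False)

        if config.gmt is not None:
            gmt = tdio.read_gmt(config.gmt)
            for analysis, de in de_tables.items():
                gse = run_collection(de, gmt, n_perm=config.n_perm,
                                     seed=stage_seed(config.seed, f"gse:{analysis}"))
                tdio.write_table(gse, out / f"gse_{analysis}.tsv")

        if config.beta is not None and config.manifest is not None:
            meth = tdio.read_methylation(config.beta, config.manifest)
            shared = [s for s in sheet.sample_ids if s in set(meth.sample_ids)]
            msheet = sheet.subset(shared)
            m = beta_to_m(meth.beta.loc[:, shared])
            for analysis, de in de_tables.items():
                mdesign = build_design(msheet, analysis)
                probe_res = diff_methylation(m, mdesign)
                probes = _probe_frame(probe_res, meth.manifest)
                acf = estimate_acf(probes, max_dist=config.dist)
                probes = slk_adjust(probes, acf, dist=config.dist)
                full, top = integrate(de, probes, cm, meth, norm=norm,
                                      top_k=config.top_k)
                tdio.write_table(full, out / f"integration_{analysis}.tsv")
                tdio.write_table(top, out / f"integration_{analysis}_top{config.top_k}.tsv")

        run_warnings = [str(w.message) for w in caught]

    manifest = {
        "config": asdict(config),
        "version": __version__,
        "input_checksums": {
            k: _md5(v) for k, v in
            [("counts", config.counts), ("sheet", config.sheet),
             ("beta", config.beta), ("manifest", config.manifest),
             ("gmt", config.gmt)] if v is not None},
        "n_genes_post_filter": int(cm.n_genes),
        "n_samples": int(cm.n_samples),
        "warnings": run_warnings,
    }
    tmp = out / "run_manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    tmp.replace(out / "run_manifest.json")
    return out
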