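"""Post-quantification QC: low-expression filtering, sample correlation
structure, hierarchical clustering and MDS on leading log fold changes.

Outlier flagging is advisory (a robust-z rule on each sample's median
correlation to all others); removal is an explicit downstream choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .containers import CountMatrix, SampleSheet, ValidationError

DEFAULT_PRIOR = 0.5


def cpm(cm: CountMatrix, log: bool = True, prior: float = DEFAULT_PRIOR) -> pd.DataFrame:
    """Counts per million, optionally log2 with a prior count.

    log form: log2((y + prior) / (L + 2 * prior) * 1e6); the prior keeps
    zeros finite and 2*prior on the library size keeps the transform
    consistent with the usual logCPM convention.
    """
    L = cm.library_sizes.to_numpy(dtype=float)
    if np.any(L <= 0):
        bad = cm.sample_ids[np.flatnonzero(L <= 0)[0]]
        raise ValidationError(f"zero library size for sample {bad!r}")
    y = cm.counts.to_numpy(dtype=float)
    if log:
        vals = np.log2((y + prior) / (L + 2.0 * prior)[None, :] * 1e6)
    else:
        vals = (y + prior) / (L + 2.0 * prior)[None, :] * 1e6
    return pd.DataFrame(vals, index=cm.gene_ids, columns=cm.sample_ids)


def filter_low_expression(cm: CountMatrix, min_cpm: float = 1.0,
                          min_samples: int = 3) -> CountMatrix:
    """Keep genes with CPM >= min_cpm in at least min_samples samples."""
    c = cpm(cm, log=False, prior=0.0)
    keep = (c.to_numpy() >= min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts.loc[keep])


@dataclass
class QcReport:
    correlation: pd.DataFrame  # sample x sample Pearson matrix
    median_within_pair_r: float = np.nan
    median_unrelated_r: float = np.nan
    outlier_samples: list = field(default_factory=list)
    cluster_linkage: np.ndarray | None = None
    mds_coordinates: pd.DataFrame | None = None


def pairwise_correlation(lcm: pd.DataFrame, sheet: SampleSheet | None = None) -> QcReport:
    """Full sample x sample Pearson correlation over genes, with medians for
    co-twin pairs and for all unrelated sample pairs when a sheet is given."""
    if lcm.shape[1] < 2:
        raise ValidationError("need >= 2 samples for correlation")
    vals = lcm.to_numpy(dtype=float)
    if np.any(vals.std(axis=0) == 0):
        bad = lcm.columns[np.flatnonzero(vals.std(axis=0) == 0)[0]]
        raise ValidationError(f"constant expression vector for sample {bad!r}")
    corr = pd.DataFrame(np.corrcoef(vals, rowvar=False),
                        index=lcm.columns, columns=lcm.columns)
    report = QcReport(correlation=corr)
    if sheet is not None:
        pair_of = dict(zip(sheet.table["sample_id"], sheet.table["pair_id"]))
        within, between = [], []
        samples = list(lcm.columns)
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                r = corr.loc[a, b]
                if pair_of.get(a) is not None and pair_of.get(a) == pair_of.get(b):
                    within.append(r)
                else:
                    between.append(r)
        report.median_within_pair_r = float(np.median(within)) if within else np.nan
        report.median_unrelated_r = float(np.median(between)) if between else np.nan
    return report


def hierarchical_cluster(lcm: pd.DataFrame, method: str = "complete") -> np.ndarray:
    """Agglomerative clustering of samples on Euclidean distance between
    logCPM columns; returns a scipy linkage matrix (leaves in sample order)."""
    if lcm.shape[1] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    X = lcm.to_numpy(dtype=float).T
    return linkage(X, method=method, metric="euclidean")


def _leading_logfc_distance(vals: np.ndarray, top: int) -> np.ndarray:
    """Pairwise distance: RMS of the `top` largest absolute logCPM
    differences for each sample pair."""
    n = vals.shape[1]
    D = np.zeros((n, n))
    top = min(top, vals.shape[0])
    for i in range(n):
        for j in range(i + 1, n):
            d2 = (vals[:, i] - vals[:, j]) ** 2
            if top < d2.size:
                d2 = np.partition(d2, d2.size - top)[-top:]
            D[i, j] = D[j, i] = np.sqrt(d2.mean())
    return D


def mds_leading_logfc(lcm: pd.DataFrame, top: int = 500, k: int = 6) -> pd.DataFrame:
    """Classical (Torgerson) MDS on the leading-logFC distance matrix.

    Distances use, per sample pair, the root mean square of that pair's
    `top` largest absolute logCPM differences, so each pair is compared on
    the genes that separate it most.
    """
    n = lcm.shape[1]
    if k >= n:
        raise ValidationError(f"k={k} must be < n_samples={n}")
    D = _leading_logfc_distance(lcm.to_numpy(dtype=float), top)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.maximum(evals[:k], 0.0)
    coords = evecs[:, :k] * np.sqrt(pos)[None, :]
    return pd.DataFrame(coords, index=lcm.columns,
                        columns=[f"dim{i + 1}" for i in range(k)])


def flag_outliers(report: QcReport, z_thresh: float = 3.0) -> list:
    """Flag samples whose median correlation to all other samples falls
    below median - z_thresh * 1.4826 * MAD of that statistic."""
    corr = report.correlation.to_numpy(dtype=float).copy()
    n = corr.shape[0]
    if n <= 2:
        warnings.warn("outlier statistic undefined for <= 2 samples", stacklevel=2)
        return []
    np.fill_diagonal(corr, np.nan)
    stat = np.nanmedian(corr, axis=1)
    med = np.median(stat)
    mad = np.median(np.abs(stat - med))
    cutoff = med - z_thresh * 1.4826 * mad
    flagged = [report.correlation.index[i] for i in range(n) if stat[i] < cutoff]
    report.outlier_samples = flagged
    return flagged
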