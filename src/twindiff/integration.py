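"""Expression-methylation integrative analysis (cis eQTM screen).

Stages, per the gene-level integration strategy:

1. Beta -> M-value transform, M = log2(Beta / (1 - Beta)).
2. Per-probe ordinary least squares of M on the paired design; two-sided t
   test of the case coefficient.
3. Spatial adjustment of probe p-values by the Stouffer-Liptak-Kechris
   (SLK) combination over a +-2000 bp window, using a distance-binned
   autocorrelation function estimated from the probe z-scores themselves.
4. Gene-level methylation summary: minimum SLK-adjusted p over the gene's
   probes.
5. Combination with the expression LRT p-value by empirical Brown's method,
   whose scaled-chi-square null moments are estimated from the per-gene
   expression and methylation data vectors.
6. Spearman correlation of gene CPM against median Beta, and ranking of
   genes measured in both assays by combined p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, MethylationSet, ValidationError
from .de import DesignMatrix, NormFactors, tmm_factors

_P_FLOOR = 1e-15


def beta_to_m(beta: pd.DataFrame) -> pd.DataFrame:
    """M = log2(beta / (1 - beta)); inverse is beta = 2^M / (2^M + 1)."""
    vals = beta.to_numpy(dtype=float) if isinstance(beta, pd.DataFrame) else np.asarray(beta, float)
    if np.any(vals <= 0) or np.any(vals >= 1):
        raise ValidationError("beta values must lie strictly in (0, 1)")
    m = np.log2(vals / (1.0 - vals))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m):
    vals = np.asarray(m, dtype=float)
    return np.exp2(vals) / (np.exp2(vals) + 1.0)


def diff_methylation(m: pd.DataFrame, design: DesignMatrix) -> pd.DataFrame:
    """Per-probe OLS of M-values on the design; effect and two-sided t-test
    p for the case coefficient (no variance moderation).

    Probes with zero residual variance get p = 1 and a `degenerate` flag.
    Returns columns probe_id, effect, p_raw, degenerate.
    """
    X = design.matrix
    n, p = X.shape
    df_resid = n - np.linalg.matrix_rank(X)
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")
    M = m.loc[:, design.sample_ids].to_numpy(dtype=float)
    XtXinv = np.linalg.pinv(X.T @ X)
    B = M @ (XtXinv @ X.T).T  # probes x p
    resid = M - B @ X.T
    rss = (resid ** 2).sum(axis=1)
    sigma2 = rss / df_resid
    se = np.sqrt(np.maximum(sigma2 * XtXinv[design.case_index, design.case_index],
                            0.0))
    effect = B[:, design.case_index]
    # zero residual variance up to floating point (e.g. a constant probe)
    scale = np.maximum((M ** 2).mean(axis=1), 1.0)
    degenerate = sigma2 <= 1e-20 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, effect / np.where(se > 0, se, 1.0))
    p_raw = 2.0 * stats.t.sf(np.abs(t), df_resid)
    p_raw = np.where(degenerate, 1.0, np.clip(p_raw, _P_FLOOR, 1.0))
    return pd.DataFrame({"probe_id": m.index, "effect": effect,
                         "p_raw": p_raw, "degenerate": degenerate})


def _probe_frame(probe_results: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    df = probe_results.merge(
        manifest[["probe_id", "chrom", "position", "gene_id"]], on="probe_id")
    return df.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)


@dataclass
class AcfTable:
    """Distance-binned autocorrelation of probe z-scores; lag 0 (the matrix
    diagonal) is 1 by definition and is not stored."""

    bin_upper: np.ndarray  # bp, ordered
    correlation: np.ndarray  # floored at 0
    pair_counts: np.ndarray

    def lookup(self, dist: float) -> float:
        if dist <= self.bin_upper[0]:
            return float(self.correlation[0])
        idx = int(np.searchsorted(self.bin_upper, dist, side="left"))
        if idx >= self.bin_upper.size:
            return 0.0
        return float(self.correlation[idx])


def estimate_acf(probes: pd.DataFrame, max_dist: int = 2000,
                 bin_width: int = 500, min_pairs: int = 10) -> AcfTable:
    """Autocorrelation of z = Phi^-1(1 - p) between same-chromosome probe
    pairs, binned by separation: (0, bw], (bw, 2bw], ... up to max_dist.

    Bins with fewer than `min_pairs` pairs inherit the nearest populated
    bin's value; negative estimates are floored at 0.
    """
    z = stats.norm.isf(np.clip(probes["p_raw"].to_numpy(dtype=float),
                               _P_FLOOR, 1.0 - _P_FLOOR))
    pos = probes["position"].to_numpy()
    chrom = probes["chrom"].to_numpy()
    uppers = np.arange(bin_width, max_dist + 1, bin_width)
    pairs_x = [[] for _ in uppers]
    pairs_y = [[] for _ in uppers]
    any_pair = False
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        cpos = pos[idx]
        order = np.argsort(cpos, kind="stable")
        idx, cpos = idx[order], cpos[order]
        for a in range(idx.size):
            b = a + 1
            while b < idx.size and cpos[b] - cpos[a] <= max_dist:
                d = cpos[b] - cpos[a]
                k = int(np.searchsorted(uppers, max(d, 1), side="left"))
                pairs_x[k].append(z[idx[a]])
                pairs_y[k].append(z[idx[b]])
                any_pair = True
                b += 1
    if not any_pair:
        warnings.warn("no same-chromosome probe pairs within max_dist; "
                      "ACF set to 0", stacklevel=2)
        return AcfTable(uppers, np.zeros(uppers.size), np.zeros(uppers.size, int))

    corr = np.full(uppers.size, np.nan)
    counts = np.zeros(uppers.size, dtype=int)
    for k in range(uppers.size):
        counts[k] = len(pairs_x[k])
        if counts[k] >= max(min_pairs, 2):
            x, y = np.asarray(pairs_x[k]), np.asarray(pairs_y[k])
            if x.std() > 0 and y.std() > 0:
                corr[k] = np.corrcoef(x, y)[0, 1]
            else:
                corr[k] = 1.0 if np.allclose(x, y) else 0.0
    # sparse bins inherit the nearest populated estimate
    filled = np.flatnonzero(~np.isnan(corr))
    if filled.size == 0:
        corr[:] = 0.0
    else:
        for k in np.flatnonzero(np.isnan(corr)):
            corr[k] = corr[filled[np.argmin(np.abs(filled - k))]]
    corr = np.clip(corr, 0.0, 1.0)
    return AcfTable(uppers, corr, counts)


def slk_adjust(probes: pd.DataFrame, acf: AcfTable, dist: int = 2000) -> pd.DataFrame:
    """Stouffer-Liptak combination of each probe's z with its neighbours
    within +-dist bp on the same chromosome:

        z_comb(i) = sum_{j in N_i} z_j / sqrt(sum_{j,k in N_i} sigma_jk)

    with sigma_jk = acf(|pos_j - pos_k|) off the diagonal and 1 on it;
    p_slk = 1 - Phi(z_comb). An isolated probe keeps its raw p exactly.
    """
    out = probes.copy()
    z = stats.norm.isf(np.clip(out["p_raw"].to_numpy(dtype=float),
                               _P_FLOOR, 1.0 - _P_FLOOR))
    pos = out["position"].to_numpy()
    chrom = out["chrom"].to_numpy()
    p_slk = np.empty(len(out))
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        order = np.argsort(pos[idx], kind="stable")
        idx = idx[order]
        cpos = pos[idx]
        lo = np.searchsorted(cpos, cpos - dist, side="left")
        hi = np.searchsorted(cpos, cpos + dist, side="right")
        for a in range(idx.size):
            nb = idx[lo[a]:hi[a]]
            if nb.size == 1:
                p_slk[idx[a]] = out["p_raw"].iloc[idx[a]]
                continue
            zz = z[nb]
            dmat = np.abs(cpos[lo[a]:hi[a], None] - cpos[None, lo[a]:hi[a]])
            sigma = np.ones_like(dmat, dtype=float)
            off = ~np.eye(nb.size, dtype=bool)
            sigma[off] = [acf.lookup(d) for d in dmat[off]]
            denom = sigma.sum()
            z_comb = zz.sum() / np.sqrt(denom)
            p_slk[idx[a]] = stats.norm.sf(z_comb)
    out["p_slk"] = np.clip(p_slk, _P_FLOOR, 1.0)
    return out


def gene_min_p(probes: pd.DataFrame) -> pd.Series:
    """Gene-level methylation p: minimum p_slk over the gene's probes.
    The minimum is not multiplicity-adjusted; it is an evidence summary."""
    return probes.groupby("gene_id")["p_slk"].min()


def empirical_brown(p_expr: float, p_meth: float, x, y):
    """Combine two dependent p-values by empirical Brown's method.

    x and y are the per-sample data vectors the two p-values derive from
    (expression CPM and methylation summary over the same samples). Each is
    reduced to evidence scores w_s = -2 ln(ECDF(v_s)) with the max-rank
    ECDF rank/n, so the sample maximum maps to w = 0. With
    c = cov(w_x, w_y), the Fisher statistic X = -2(ln p_expr + ln p_meth)
    is referred to a scaled chi-square with

        f = 2 E^2 / Var,  gamma = Var / (2 E),  E = 4,  Var = 8 + 2c.

    c = 0 recovers Fisher's method exactly. Returns
    (p_combined, df, scale, cov_w).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need matching data vectors over >= 3 samples")
    if not (0.0 < p_expr <= 1.0 and 0.0 < p_meth <= 1.0):
        raise ValidationError("p-values must lie in (0, 1]")
    n = x.size
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant data vector; falling back to Fisher (c = 0)",
                      stacklevel=2)
        c = 0.0
    else:
        wx = -2.0 * np.log(stats.rankdata(x, method="max") / n)
        wy = -2.0 * np.log(stats.rankdata(y, method="max") / n)
        c = float(np.cov(wx, wy, ddof=1)[0, 1])
    E = 4.0
    var = 8.0 + 2.0 * c
    if var <= 0:
        warnings.warn("non-positive Brown variance; falling back to Fisher",
                      stacklevel=2)
        var, c = 8.0, 0.0
    f = 2.0 * E * E / var
    scale = var / (2.0 * E)
    X = -2.0 * (np.log(p_expr) + np.log(p_meth))
    p_comb = float(stats.chi2.sf(X / scale, df=f))
    return min(max(p_comb, _P_FLOOR), 1.0), f, scale, c


def spearman_gene(x, y) -> float:
    """Spearman rank correlation between a gene's CPM vector and its
    median-Beta vector over shared samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("need >= 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant vector has no rank correlation")
    return float(stats.spearmanr(x, y).statistic)


def integrate(de: pd.DataFrame, probes: pd.DataFrame, cm: CountMatrix,
              meth: MethylationSet, norm: NormFactors | None = None,
              top_k: int = 20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-gene integration records for genes measured in BOTH
    assays; returns (full_table, top_k_slice), sorted by combined p then
    gene id, with a 1-based rank column.
    """
    shared = [s for s in cm.sample_ids if s in set(meth.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("assay sample intersection too small (< 3)")
    if norm is None:
        norm = tmm_factors(cm)
    eff = norm.effective_library_sizes.loc[shared].to_numpy(dtype=float)
    cpm_shared = pd.DataFrame(
        cm.counts.loc[:, shared].to_numpy(dtype=float) / eff[None, :] * 1e6,
        index=cm.gene_ids, columns=shared)

    p_expr = de.set_index("gene_id")["p_value"]
    p_meth = gene_min_p(probes)
    beta = meth.beta.loc[:, shared]
    gene_probes = probes.groupby("gene_id")["probe_id"].agg(list)

    genes = sorted(set(p_expr.index) & set(p_meth.index) & set(cm.gene_ids))
    if not genes:
        raise ValidationError("no genes measured in both assays")
    rows = []
    for g in genes:
        x = cpm_shared.loc[g].to_numpy()
        y = beta.loc[gene_probes[g]].median(axis=0).to_numpy()
        pe = float(np.clip(p_expr[g], _P_FLOOR, 1.0))
        pm = float(np.clip(p_meth[g], _P_FLOOR, 1.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_comb, f, scale, c = empirical_brown(pe, pm, x, y)
            try:
                rho = spearman_gene(x, y)
            except ValidationError:
                rho = np.nan
        rows.append({"gene_id": g, "p_expr": pe, "p_meth_gene": pm,
                     "cov_w": c, "df_brown": f, "scale_brown": scale,
                     "p_combined": p_comb, "spearman_rho": rho})
    full = (pd.DataFrame(rows)
            .sort_values(["p_combined", "gene_id"], kind="stable")
            .reset_index(drop=True))
    full["rank"] = np.arange(1, len(full) + 1)
    return full, full.head(top_k).copy()
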