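"""Paired negative-binomial differential expression.

The analysis model, per gene g and sample s, is

    y_gs ~ NB(mu_gs, phi_g),      Var(y) = mu + phi * mu^2
    ln mu_gs = x_s' beta_g + ln(L_s * f_s)

with a design of intercept + twin-pair indicators + a binary case indicator,
TMM-scaled effective library sizes as offsets, and a likelihood-ratio test
of the case coefficient against chi-square(1). Dispersions are estimated by
grid-maximising the Cox-Reid adjusted profile likelihood per gene and
shrinking towards a logCPM-binned trend with a fixed prior weight.

Coefficients are estimated on the natural-log scale; reported logFC is the
case coefficient divided by ln 2 (log2 units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, rankdata

from .containers import CountMatrix, SampleSheet, ValidationError

LN2 = float(np.log(2.0))
_ETA_MIN, _ETA_MAX = -30.0, 30.0


# --------------------------------------------------------------------------
# TMM normalisation
# --------------------------------------------------------------------------

@dataclass
class NormFactors:
    factors: pd.Series  # per-sample TMM factor, geometric mean 1
    library_sizes: pd.Series

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors


def _tmm_pair(y_s, y_r, L_s, L_r, trim_m=0.30, trim_a=0.05) -> float:
    """TMM factor of one sample against the reference (edgeR-style doubly
    trimmed weighted mean of M-values)."""
    keep = (y_s > 0) & (y_r > 0)
    ys, yr = y_s[keep].astype(float), y_r[keep].astype(float)
    if ys.size == 0:
        raise ValidationError("no genes expressed in both sample and reference")
    M = np.log2((ys / L_s) / (yr / L_r))
    A = 0.5 * np.log2((ys / L_s) * (yr / L_r))
    # precision weights from the delta-method variance of M
    w = 1.0 / (1.0 / ys - 1.0 / L_s + 1.0 / yr - 1.0 / L_r)
    n = M.size
    rm, ra = rankdata(M), rankdata(A)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0
    f = 2.0 ** (np.sum(w[keep2] * M[keep2]) / np.sum(w[keep2]))
    return 1.0 if not np.isfinite(f) or f <= 0 else float(f)


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors, rescaled to geometric mean 1.

    The reference defaults to the sample whose 75th CPM percentile is
    closest to the mean of those percentiles across samples.
    """
    if cm.n_samples < 2:
        raise ValidationError("TMM needs >= 2 samples")
    Y = cm.counts.to_numpy(dtype=float)
    L = cm.library_sizes.to_numpy(dtype=float)
    uq = np.percentile(Y / L[None, :] * 1e6, 75, axis=0)
    if ref_sample is None:
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(cm.sample_ids).index(ref_sample)
    f = np.array([
        _tmm_pair(Y[:, s], Y[:, ref_idx], L[s], L[ref_idx])
        for s in range(cm.n_samples)
    ])
    f = f / np.exp(np.mean(np.log(f)))
    return NormFactors(pd.Series(f, index=cm.sample_ids),
                       cm.library_sizes.astype(float))


# --------------------------------------------------------------------------
# Design matrices
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    matrix: np.ndarray  # samples x coefficients
    names: list
    case_index: int
    sample_ids: list

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def drop_case(self) -> np.ndarray:
        keep = [j for j in range(self.matrix.shape[1]) if j != self.case_index]
        return self.matrix[:, keep]


def build_design(sheet: SampleSheet, analysis: str = "discordant_group") -> DesignMatrix:
    """Intercept + pair indicators (reference pair dropped) + case indicator.

    ``discordant_group`` uses complete discordant pairs only; ``case_control``
    uses all complete pairs. Pair indicator columns aliased with other
    columns (concordant and control pairs make case collinear with their
    pair indicator) are dropped with a warning; a design in which the case
    column itself is aliased is rejected.
    """
    if analysis not in ("discordant_group", "case_control"):
        raise ValidationError(f"unknown analysis {analysis!r}")
    cp = sheet.complete_pairs()
    if analysis == "discordant_group":
        dropped = cp[cp["group"] != "discordant"]
        if len(dropped):
            warnings.warn(
                f"dropping {dropped['pair_id'].nunique()} non-discordant pairs "
                "from the discordant-group design", stacklevel=2)
        cp = cp[cp["group"] == "discordant"]
    n_dropped_singletons = len(sheet.table) - len(sheet.complete_pairs())
    if n_dropped_singletons:
        warnings.warn(f"dropping {n_dropped_singletons} singleton samples "
                      "(no co-twin)", stacklevel=2)
    if cp["pair_id"].nunique() < 2:
        raise ValidationError("need >= 2 complete pairs")

    samples = list(cp["sample_id"])
    pairs = list(dict.fromkeys(cp["pair_id"]))
    case = cp["case"].to_numpy(dtype=float)
    if case.min() == case.max():
        raise ValidationError("case status is constant; case effect unestimable")

    cols = [np.ones(len(samples))]
    names = ["intercept"]
    for p in pairs[1:]:
        cols.append((cp["pair_id"] == p).to_numpy(dtype=float))
        names.append(f"pair_{p}")
    X_pairs = np.column_stack(cols)

    # greedy rank selection with case ordered right after the intercept, so
    # aliasing is resolved by dropping pair columns, never the case column
    probe = np.column_stack([X_pairs[:, :1], case[:, None], X_pairs[:, 1:]])
    kept, rank = [], 0
    for j in range(probe.shape[1]):
        cand = probe[:, kept + [j]]
        if np.linalg.matrix_rank(cand) > rank:
            kept.append(j)
            rank += 1
    if 1 not in kept:
        raise ValidationError("case confounded with pair structure (singular design)")
    keep_pair_cols = sorted(j - 2 for j in kept if j >= 2)
    dropped_pairs = [names[1 + j] for j in range(len(pairs) - 1) if j not in keep_pair_cols]
    if dropped_pairs:
        warnings.warn(
            f"dropping {len(dropped_pairs)} pair columns aliased with "
            f"intercept/case: {dropped_pairs[:4]}...", stacklevel=2)
    X = np.column_stack(
        [X_pairs[:, :1]]
        + [X_pairs[:, 1 + j:2 + j] for j in keep_pair_cols]
        + [case[:, None]]
    )
    kept_names = (["intercept"] + [names[1 + j] for j in keep_pair_cols] + ["case"])
    return DesignMatrix(X, kept_names, X.shape[1] - 1, samples)


# --------------------------------------------------------------------------
# NB GLM fitting (vectorised IRLS across genes)
# --------------------------------------------------------------------------

def nb_loglik(Y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """NB log-likelihood summed over samples, per gene. Shapes (G, n)."""
    phi = np.asarray(phi, dtype=float).reshape(-1, 1)
    phi = np.maximum(phi, 1e-12)
    r = 1.0 / phi
    pm = phi * mu
    return (gammaln(Y + r) - gammaln(r) - gammaln(Y + 1)
            + Y * np.log(pm / (1.0 + pm)) - r * np.log1p(pm)).sum(axis=1)


def _irls_batch(Y, X, offset, phi, max_iter=100, tol=1e-8, beta0=None):
    """Fit the NB GLM for all genes at once by iteratively reweighted least
    squares with step halving.

    Y (G, n); X (n, p); offset (n,) or (G, n); phi scalar or (G,).
    `beta0` warm-starts the coefficients (used by the dispersion grid).
    Returns beta (G, p), loglik (G,), mu (G, n), converged (G,) bool.
    """
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (G, n)) \
        if np.ndim(offset) > 1 else np.asarray(offset, dtype=float)[None, :]
    phi = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1), (G,))

    if beta0 is None:
        pinvX = np.linalg.pinv(X)
        beta = (np.log(Y + 0.5) - offset) @ pinvX.T
    else:
        beta = np.array(beta0, dtype=float)
    eta = np.clip(beta @ X.T + offset, _ETA_MIN, _ETA_MAX)
    mu = np.exp(eta)
    ll = nb_loglik(Y, mu, phi)
    converged = np.zeros(G, dtype=bool)
    diag = np.arange(p)

    for _ in range(max_iter):
        w = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offset) + (Y - mu) / mu
        Xw = w[:, :, None] * X[None, :, :]  # (G, n, p)
        A = Xw.transpose(0, 2, 1) @ X  # batched X'WX via BLAS
        A[:, diag, diag] += 1e-10
        b = ((w * z)[:, None, :] @ X)[:, 0, :]
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = beta_new - beta

        step = np.ones(G)
        for _ in range(30):
            cand = beta + step[:, None] * delta
            eta_c = np.clip(cand @ X.T + offset, _ETA_MIN, _ETA_MAX)
            ll_c = nb_loglik(Y, np.exp(eta_c), phi)
            worse = ll_c < ll - 1e-10
            if not worse.any():
                break
            step[worse] *= 0.5
        beta = beta + step[:, None] * delta
        eta = np.clip(beta @ X.T + offset, _ETA_MIN, _ETA_MAX)
        mu = np.exp(eta)
        ll_new = nb_loglik(Y, mu, phi)
        converged = np.abs(ll_new - ll) < tol
        ll = ll_new
        if converged.all():
            break
    return beta, ll, mu, converged


def fit_nb_glm(y: np.ndarray, X: np.ndarray, offsets: np.ndarray, phi: float):
    """Fit one gene's NB GLM; returns (coefficients, log-likelihood,
    fitted means, converged flag)."""
    if phi <= 0:
        raise ValidationError("dispersion must be > 0")
    beta, ll, mu, conv = _irls_batch(np.asarray(y, float)[None, :], X, offsets, phi)
    if not conv[0]:
        warnings.warn("NB GLM did not converge", stacklevel=2)
    return beta[0], float(ll[0]), mu[0], bool(conv[0])


# --------------------------------------------------------------------------
# Dispersion estimation
# --------------------------------------------------------------------------

@dataclass
class DispersionEstimates:
    common: float
    trend: pd.Series  # per-gene trend value (phi at the gene's logCPM bin)
    tagwise: pd.Series  # per-gene shrunk dispersion
    mle: pd.Series  # per-gene unshrunk grid MLE
    ave_logcpm: pd.Series
    prior_df: float


def _interp_argmax(xgrid: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Quadratic-interpolated argmax along the last axis of `vals` over the
    (uniform) grid `xgrid`; boundary maxima are returned as-is."""
    vals = np.atleast_2d(vals)
    K = xgrid.size
    step = xgrid[1] - xgrid[0]
    i = np.argmax(vals, axis=-1)
    x = xgrid[i].astype(float)
    interior = (i > 0) & (i < K - 1)
    ii = i[interior]
    rows = np.nonzero(interior)[0]
    y0 = vals[rows, ii - 1]
    y1 = vals[rows, ii]
    y2 = vals[rows, ii + 1]
    denom = y0 - 2.0 * y1 + y2
    shift = np.where(denom < -1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    x[interior] = xgrid[ii] + np.clip(shift, -1.0, 1.0) * step
    return x


def average_log_cpm(cm: CountMatrix, norm: NormFactors | None = None,
                    prior: float = 0.5) -> pd.Series:
    L = (norm.effective_library_sizes if norm is not None
         else cm.library_sizes.astype(float))
    L = L.loc[cm.sample_ids].to_numpy(dtype=float)
    y = cm.counts.to_numpy(dtype=float)
    lcpm = np.log2((y + prior) / (L + 2 * prior)[None, :] * 1e6)
    return pd.Series(lcpm.mean(axis=1), index=cm.gene_ids)


def estimate_dispersions(cm: CountMatrix, design: DesignMatrix,
                         norm: NormFactors | None = None,
                         prior_df: float = 10.0,
                         grid_range=(-20.0, 5.0), grid_points: int = 41,
                         n_bins: int = 20) -> DispersionEstimates:
    """Cox-Reid adjusted profile likelihood dispersions on a log2-spaced grid.

    Per-gene APL(phi) = loglik(beta_hat(phi); phi) - 0.5 * ln det(X'WX).
    The trend maximises the bin-averaged APL within 20 logCPM bins; tagwise
    estimates maximise APL_g + prior_df * (bin-average APL), which shrinks
    each gene towards its bin's trend with weight prior_df (equivalent prior
    genes). prior_df = 0 gives the raw MLE, prior_df = inf the trend.
    """
    if norm is None:
        norm = tmm_factors(cm)
    X = design.matrix
    n, p = X.shape
    if n - np.linalg.matrix_rank(X) < 1:
        raise ValidationError(
            "zero residual df: estimate a common dispersion on a reduced design")
    cm = cm.subset_samples(design.sample_ids)
    Y = cm.counts.to_numpy(dtype=float)
    G = Y.shape[0]
    offsets = np.log(norm.effective_library_sizes.loc[design.sample_ids].to_numpy())

    log2_grid = np.linspace(grid_range[0], grid_range[1], grid_points)
    grid = 2.0 ** log2_grid
    apl = np.empty((G, grid_points))
    beta = None
    for k, phi in enumerate(grid):
        # warm-start each grid point at the previous phi's coefficients
        beta, ll, mu, _ = _irls_batch(Y, X, offsets, phi, beta0=beta)
        w = mu / (1.0 + phi * mu)
        Xw = w[:, :, None] * X[None, :, :]
        A = Xw.transpose(0, 2, 1) @ X
        A[:, np.arange(p), np.arange(p)] += 1e-10
        _, logdet = np.linalg.slogdet(A)
        apl[:, k] = ll - 0.5 * logdet

    common = float(2.0 ** _interp_argmax(log2_grid, apl.mean(axis=0))[0])
    phi_mle = 2.0 ** _interp_argmax(log2_grid, apl)

    ave_lcpm = average_log_cpm(cm, norm)
    n_bins = max(1, min(n_bins, G))
    bins = pd.qcut(ave_lcpm.rank(method="first"), n_bins, labels=False)
    bin_of = bins.to_numpy()
    apl_bar = np.empty((n_bins, grid_points))
    for b in range(n_bins):
        apl_bar[b] = apl[bin_of == b].mean(axis=0)
    phi_trend_bin = 2.0 ** _interp_argmax(log2_grid, apl_bar)
    phi_trend = phi_trend_bin[bin_of]

    if np.isinf(prior_df):
        phi_tag = phi_trend.copy()
    else:
        objective = apl + prior_df * apl_bar[bin_of]
        phi_tag = 2.0 ** _interp_argmax(log2_grid, objective)
        lo = np.minimum(phi_mle, phi_trend)
        hi = np.maximum(phi_mle, phi_trend)
        phi_tag = np.clip(phi_tag, lo, hi)

    idx = cm.gene_ids
    return DispersionEstimates(
        common=common,
        trend=pd.Series(phi_trend, index=idx),
        tagwise=pd.Series(phi_tag, index=idx),
        mle=pd.Series(phi_mle, index=idx),
        ave_logcpm=ave_lcpm,
        prior_df=prior_df,
    )


# --------------------------------------------------------------------------
# Likelihood-ratio test, FDR, per-pair fold changes
# --------------------------------------------------------------------------

def benjamini_hochberg(p) -> np.ndarray:
    """Step-up BH adjusted p-values, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValidationError("NaN p-values passed to benjamini_hochberg")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    fdr_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = fdr_sorted
    return out


def per_pair_logfc(cm: CountMatrix, sheet: SampleSheet,
                   norm: NormFactors | None = None) -> pd.DataFrame:
    """Per-pair per-gene log2 fold change with a 0.5 prior count on
    TMM-effective library sizes: case vs co-twin for discordant pairs,
    twin 2 vs twin 1 (sheet order) otherwise. Columns = pair ids."""
    if norm is None:
        norm = tmm_factors(cm)
    eff = norm.effective_library_sizes
    out = {}
    for pid, sub in sheet.complete_pairs().groupby("pair_id", sort=False):
        sub = sub.reset_index(drop=True)
        if sub["group"].iloc[0] == "discordant":
            a = sub.loc[sub["case"] == 1, "sample_id"].iloc[0]
            b = sub.loc[sub["case"] == 0, "sample_id"].iloc[0]
        else:
            a, b = sub["sample_id"].iloc[1], sub["sample_id"].iloc[0]
        ya = cm.counts[a].to_numpy(dtype=float)
        yb = cm.counts[b].to_numpy(dtype=float)
        out[pid] = (np.log2((ya + 0.5) / (eff[a] + 1.0))
                    - np.log2((yb + 0.5) / (eff[b] + 1.0)))
    singles = set(sheet.table["pair_id"]) - set(out)
    if singles:
        warnings.warn(f"skipping {len(singles)} singleton pairs", stacklevel=2)
    if not out:
        raise ValidationError("no complete pairs")
    return pd.DataFrame(out, index=cm.gene_ids)


def direction_consistency(pp: pd.DataFrame, gene: str) -> str:
    """'up' if every pair's logFC > 0, 'down' if every < 0, else 'none'."""
    v = pp.loc[gene].to_numpy(dtype=float)
    if np.all(v > 0):
        return "up"
    if np.all(v < 0):
        return "down"
    return "none"


def _annotate_direction(pp: pd.DataFrame) -> pd.Series:
    v = pp.to_numpy(dtype=float)
    out = np.where((v > 0).all(axis=1), "up",
                   np.where((v < 0).all(axis=1), "down", "none"))
    return pd.Series(out, index=pp.index)


def lrt_case(cm: CountMatrix, sheet: SampleSheet,
             analysis: str = "discordant_group",
             norm: NormFactors | None = None,
             design: DesignMatrix | None = None,
             dispersions: DispersionEstimates | None = None,
             prior_df: float = 10.0) -> pd.DataFrame:
    """Likelihood-ratio test of the case coefficient for every gene.

    Returns a DataFrame with columns gene_id, logFC (log2), logCPM,
    p_value, fdr, consistent_direction, sorted by (p_value, gene_id).
    The direction flag is computed across complete discordant pairs.
    """
    if design is None:
        design = build_design(sheet, analysis)
    if norm is None:
        norm = tmm_factors(cm)
    sub = cm.subset_samples(design.sample_ids)
    Y = sub.counts.to_numpy(dtype=float)
    offsets = np.log(norm.effective_library_sizes.loc[design.sample_ids].to_numpy())
    if dispersions is None:
        dispersions = estimate_dispersions(cm, design, norm, prior_df=prior_df)
    phi = dispersions.tagwise.loc[sub.gene_ids].to_numpy()

    beta_full, ll_full, _, conv_full = _irls_batch(Y, design.matrix, offsets, phi)
    X_red = design.drop_case()
    _, ll_red, _, _ = _irls_batch(Y, X_red, offsets, phi)
    D = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    pvals = np.clip(chi2.sf(D, df=1), 1e-300, 1.0)

    disc = sheet.subset(
        sheet.complete_pairs().loc[
            sheet.complete_pairs()["group"] == "discordant", "sample_id"])
    if disc.complete_pairs()["pair_id"].nunique() >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            direction = _annotate_direction(per_pair_logfc(
                cm.subset_samples(disc.sample_ids), disc, norm=norm))
        direction = direction.reindex(sub.gene_ids).fillna("none")
    else:
        direction = pd.Series("none", index=sub.gene_ids)

    res = pd.DataFrame({
        "gene_id": sub.gene_ids,
        "logFC": beta_full[:, design.case_index] / LN2,
        "logCPM": average_log_cpm(sub, norm).to_numpy(),
        "p_value": pvals,
        "fdr": benjamini_hochberg(pvals),
        "consistent_direction": direction.to_numpy(),
        "converged": conv_full,
    })
    res = res.sort_values(["p_value", "gene_id"], kind="stable").reset_index(drop=True)
    return res
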