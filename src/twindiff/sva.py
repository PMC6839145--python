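"""Surrogate variable estimation from residual expression structure.

A two-step estimator: residualise logCPM on the known design, take the
SVD of the residual matrix, and keep the leading right singular vectors
whose variance fractions exceed what row-wise permutation of the residuals
produces (the Buja-Eyuboglu parallel-analysis criterion). The surrogate
variables are orthonormal and, by construction of the residualisation,
orthogonal to the design's column space. User-supplied covariates (e.g.
inferred cell-composition scores) can be appended to a design the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ValidationError
from .de import DesignMatrix


@dataclass
class SurrogateVariables:
    n_sv: int
    sv: np.ndarray  # samples x n_sv, orthonormal columns
    eigen_fractions: np.ndarray  # variance fractions of ALL residual components
    sample_ids: list


def estimate_svs(lcm: pd.DataFrame, design: DesignMatrix,
                 n_perm: int = 100, alpha: float = 0.05,
                 seed: int = 0) -> SurrogateVariables:
    """Estimate surrogate variables from the residuals of logCPM on X.

    Component k is kept if its variance fraction exceeds the (1 - alpha)
    quantile of the k-th fraction under `n_perm` independent row-wise
    permutations of the residual matrix; retention stops at the first
    component that fails. n_sv may be 0.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    X = design.matrix
    n, p = X.shape
    if n < p + 1:
        raise ValidationError("need more samples than design columns")
    Y = lcm.loc[:, design.sample_ids].to_numpy(dtype=float)  # genes x samples
    hat = X @ np.linalg.pinv(X)
    R = Y - Y @ hat.T  # residualise each gene's row over samples

    def fractions(mat):
        s = np.linalg.svd(mat, compute_uv=False)
        s2 = s ** 2
        tot = s2.sum()
        return s2 / tot if tot > 0 else s2

    _, s, Vt = np.linalg.svd(R, full_matrices=False)
    s2 = s ** 2
    frac = s2 / s2.sum() if s2.sum() > 0 else s2

    # n_sv stays below the residual df so downstream fits keep >= 1 df
    max_k = max(0, n - int(np.linalg.matrix_rank(X)) - 1)
    rng = np.random.default_rng(seed)
    perm_frac = np.empty((n_perm, frac.size))
    for i in range(n_perm):
        # permuted residuals are re-residualised so both spectra live in the
        # same rank-reduced sample space
        P = rng.permuted(R, axis=1)
        perm_frac[i] = fractions(P - P @ hat.T)
    thresh = np.quantile(perm_frac, 1.0 - alpha, axis=0)

    n_sv = 0
    for k in range(min(max_k, frac.size)):
        if frac[k] > thresh[k]:
            n_sv += 1
        else:
            break
    sv = Vt[:n_sv].T
    return SurrogateVariables(n_sv=n_sv, sv=sv, eigen_fractions=frac,
                              sample_ids=list(design.sample_ids))


def augment_design(design: DesignMatrix, svs) -> DesignMatrix:
    """Append surrogate-variable (or covariate) columns to a design; the
    tested-coefficient index is preserved."""
    cols = svs.sv if isinstance(svs, SurrogateVariables) else np.asarray(svs, float)
    if cols.ndim == 1:
        cols = cols[:, None]
    if cols.shape[1] == 0:
        return design
    if cols.shape[0] != design.matrix.shape[0]:
        raise ValidationError("covariate rows must match design samples")
    X = np.column_stack([design.matrix, cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("augmented design is rank-deficient")
    names = design.names + [f"sv{i + 1}" for i in range(cols.shape[1])]
    return DesignMatrix(X, names, design.case_index, design.sample_ids)
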