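"""Differential-expression engine: TMM against a literal re-implementation,
NB-GLM fits against brute-force grid maximisation, BH arithmetic, design
construction, dispersion shrinkage limits and per-pair fold changes."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import rankdata

from twindiff.containers import CountMatrix, SampleSheet, ValidationError
from twindiff.de import (
    LN2,
    DispersionEstimates,
    _annotate_direction,
    average_log_cpm,
    benjamini_hochberg,
    build_design,
    direction_consistency,
    estimate_dispersions,
    fit_nb_glm,
    lrt_case,
    per_pair_logfc,
    tmm_factors,
)


def _cm(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                                    columns=samples))


# ---------------------------------------------------------------- TMM ----

def _tmm_oracle(y_s, y_r, L_s, L_r):
    """Literal re-implementation of the doubly trimmed weighted mean of
    M-values, written without reusing the package's helper."""
    M, A, w = [], [], []
    for ys, yr in zip(y_s, y_r):
        if ys > 0 and yr > 0:
            M.append(np.log2((ys / L_s) / (yr / L_r)))
            A.append(0.5 * np.log2((ys / L_s) * (yr / L_r)))
            w.append(1.0 / (1.0 / ys - 1.0 / L_s + 1.0 / yr - 1.0 / L_r))
    M, A, w = map(np.array, (M, A, w))
    n = len(M)
    rm, ra = rankdata(M), rankdata(A)
    keep = ((rm >= np.floor(n * 0.3) + 1) & (rm <= n - np.floor(n * 0.3))
            & (ra >= np.floor(n * 0.05) + 1) & (ra <= n - np.floor(n * 0.05)))
    return 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))


def test_tmm_identical_samples_factor_one():
    y = np.array([[10, 10], [50, 50], [200, 200]])
    f = tmm_factors(_cm(y)).factors
    assert np.allclose(f, 1.0)


def test_tmm_pure_depth_difference_factor_one():
    rng = np.random.default_rng(0)
    a = rng.integers(5, 500, size=50)
    f = tmm_factors(_cm(np.column_stack([a, 2 * a]))).factors
    assert np.allclose(f, 1.0, atol=1e-12)


def test_tmm_matches_literal_oracle_on_20_gene_toy():
    rng = np.random.default_rng(7)
    a = rng.integers(20, 2000, size=20)
    b = a.copy()
    b[:2] *= 16  # two genes massively up in sample B
    cm = _cm(np.column_stack([a, b]), samples=["A", "B"])
    norm = tmm_factors(cm, ref_sample="A")
    raw_fB = _tmm_oracle(b, a, b.sum(), a.sum())
    raw_fA = _tmm_oracle(a, a, a.sum(), a.sum())
    geo = np.sqrt(raw_fA * raw_fB)
    assert norm.factors["B"] == pytest.approx(raw_fB / geo, abs=1e-10)
    assert np.exp(np.mean(np.log(norm.factors))) == pytest.approx(1.0, abs=1e-12)


def test_tmm_invariant_to_global_rescaling():
    rng = np.random.default_rng(1)
    y = rng.integers(1, 300, size=(40, 4))
    f1 = tmm_factors(_cm(y)).factors
    f2 = tmm_factors(_cm(10 * y)).factors
    assert np.allclose(f1, f2, atol=1e-8)


# ------------------------------------------------------------- design ----

def _sheet(rows):
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "pair_id",
                                                   "group", "case", "sex"]))


def _disc_sheet(n_pairs):
    rows = []
    for i in range(n_pairs):
        rows += [(f"p{i}a", f"P{i}", "discordant", 1, "M"),
                 (f"p{i}b", f"P{i}", "discordant", 0, "M")]
    return _sheet(rows)


def test_design_discordant_dimensions_and_rank():
    d = build_design(_disc_sheet(5), "discordant_group")
    assert d.matrix.shape == (10, 6)  # intercept + 4 pairs + case
    assert d.rank == 6
    assert d.names[-1] == "case" and d.case_index == 5


def test_design_case_control_mixed_groups_full_rank():
    # with discordant pairs present, case varies within a pair and is not
    # aliased with the pair blocks
    rows = [("d1a", "D1", "discordant", 1, "M"), ("d1b", "D1", "discordant", 0, "M"),
            ("d2a", "D2", "discordant", 1, "M"), ("d2b", "D2", "discordant", 0, "M"),
            ("q1a", "Q1", "concordant_case", 1, "M"), ("q1b", "Q1", "concordant_case", 1, "M"),
            ("k1a", "K1", "control", 0, "F"), ("k1b", "K1", "control", 0, "F")]
    d = build_design(_sheet(rows), "case_control")
    assert d.matrix.shape == (8, 5)
    assert d.rank == 5 and d.names[-1] == "case"


def test_design_case_control_drops_aliased_pair_columns():
    # concordant + control pairs only: case equals a combination of pair
    # blocks, so one pair column must be sacrificed, never the case column
    rows = [("q1a", "Q1", "concordant_case", 1, "M"), ("q1b", "Q1", "concordant_case", 1, "M"),
            ("q2a", "Q2", "concordant_case", 1, "M"), ("q2b", "Q2", "concordant_case", 1, "M"),
            ("k1a", "K1", "control", 0, "F"), ("k1b", "K1", "control", 0, "F")]
    with pytest.warns(UserWarning, match="aliased"):
        d = build_design(_sheet(rows), "case_control")
    assert d.names[-1] == "case"
    assert d.rank == d.matrix.shape[1]


def test_design_all_control_rejected():
    rows = [("k1a", "K1", "control", 0, "F"), ("k1b", "K1", "control", 0, "F"),
            ("k2a", "K2", "control", 0, "M"), ("k2b", "K2", "control", 0, "M")]
    with pytest.raises(ValidationError, match="constant"):
        build_design(_sheet(rows), "case_control")


# ------------------------------------------------------------ NB GLM ----

def _nb_ll(y, mu, phi):
    r = 1.0 / phi
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + y * np.log(phi * mu / (1 + phi * mu))
                        - r * np.log1p(phi * mu)))


def _grid_maximise(y, X, offsets, phi, centre, span=2.0):
    """Brute-force oracle: nested grid over the coefficient vector at
    resolution refined from ~1e-1 down to ~1e-5."""
    best = -np.inf
    beta = np.array(centre, dtype=float)
    for _ in range(5):
        grids = [np.linspace(b - span, b + span, 21) for b in beta]
        mesh = np.meshgrid(*grids, indexing="ij")
        flat = np.stack([m.ravel() for m in mesh], axis=1)
        ll = np.array([_nb_ll(y, np.exp(X @ b + offsets), phi) for b in flat])
        k = int(np.argmax(ll))
        best, beta = ll[k], flat[k]
        span /= 8.0
    return best, beta


# three printed 8-sample toys: (counts, case pattern, offsets)
TOYS = [
    (np.array([12, 7, 30, 19, 4, 9, 22, 15]),
     np.array([0, 1, 0, 1, 0, 1, 0, 1]), np.zeros(8)),
    (np.array([0, 3, 1, 8, 2, 5, 0, 11]),
     np.array([0, 0, 0, 0, 1, 1, 1, 1]), np.log(np.r_[1.0, 1.2, 0.8, 1.1, 0.9, 1.3, 1.0, 1.05])),
    (np.array([100, 85, 110, 95, 160, 170, 150, 140]),
     np.array([0, 0, 0, 0, 1, 1, 1, 1]), np.full(8, np.log(2.0))),
]


@pytest.mark.parametrize("y,case,offsets", TOYS)
def test_fit_nb_glm_matches_grid_oracle(y, case, offsets):
    X = np.column_stack([np.ones(8), case])
    beta, ll, mu, conv = fit_nb_glm(y, X, offsets, phi=0.1)
    centre = [np.log(y.mean() + 0.5), 0.0]
    ll_oracle, _ = _grid_maximise(y.astype(float), X, offsets, 0.1, centre)
    assert conv
    assert ll == pytest.approx(ll_oracle, abs=1e-4)
    assert ll >= ll_oracle - 1e-4  # the IRLS optimum is never worse


def test_fit_nb_glm_poisson_limit_closed_form():
    y = np.array([4, 9, 2, 7], dtype=float)
    offsets = np.log(np.array([1.0, 2.0, 0.5, 1.5]))
    X = np.ones((4, 1))
    beta, ll, mu, conv = fit_nb_glm(y, X, offsets, phi=1e-10)
    assert beta[0] == pytest.approx(np.log(y.sum() / np.exp(offsets).sum()), abs=1e-5)


def test_fit_nb_glm_all_zero_gene_gives_null_lrt():
    y = np.zeros(8)
    case = np.array([0, 1] * 4, dtype=float)
    X = np.column_stack([np.ones(8), case])
    _, ll_full, _, _ = fit_nb_glm(y, X, np.zeros(8), phi=0.1)
    _, ll_red, _, _ = fit_nb_glm(y, np.ones((8, 1)), np.zeros(8), phi=0.1)
    D = 2 * (ll_full - ll_red)
    assert D == pytest.approx(0.0, abs=1e-6)


# -------------------------------------------------------- dispersions ----

@pytest.fixture(scope="module")
def disc_fit(small_cohort):
    (cm, _, sheet, _), _ = small_cohort
    from twindiff.qc import filter_low_expression
    cm = filter_low_expression(cm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = build_design(sheet, "discordant_group")
        norm = tmm_factors(cm)
    return cm, sheet, design, norm


def test_dispersion_shrinkage_limits(disc_fit):
    cm, _, design, norm = disc_fit
    mle = estimate_dispersions(cm, design, norm, prior_df=0.0)
    trend = estimate_dispersions(cm, design, norm, prior_df=np.inf)
    assert np.allclose(mle.tagwise, mle.mle)
    assert np.allclose(trend.tagwise, trend.trend)
    mid = estimate_dispersions(cm, design, norm, prior_df=10.0)
    lo = np.minimum(mid.mle, mid.trend)
    hi = np.maximum(mid.mle, mid.trend)
    assert ((mid.tagwise >= lo - 1e-12) & (mid.tagwise <= hi + 1e-12)).all()


def test_common_dispersion_recovery_constant_phi():
    from twindiff.simulate import SimulationConfig, simulate_cohort
    from twindiff.qc import filter_low_expression
    cfg = SimulationConfig(n_genes=2000, n_de_genes=0, n_linked_genes=0,
                           dispersion_shape=2e6, dispersion_rate=1e7, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cm, _, sheet, _ = simulate_cohort(cfg)
        cm = filter_low_expression(cm)
        design = build_design(sheet, "discordant_group")
        disp = estimate_dispersions(cm, design, tmm_factors(cm))
    assert 0.15 <= disp.common <= 0.25


def test_zero_residual_df_rejected():
    from twindiff.de import DesignMatrix
    sheet = _disc_sheet(2)
    samples = list(sheet.table["sample_id"])
    cm = _cm(np.arange(1, 13).reshape(3, 4), samples=samples)
    saturated = DesignMatrix(np.eye(4), [f"c{i}" for i in range(4)], 3, samples)
    with pytest.raises(ValidationError, match="residual"):
        estimate_dispersions(cm, saturated, tmm_factors(cm))


# ------------------------------------------------------------ BH FDR ----

def test_bh_hand_example_and_boundaries():
    assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)
    assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValidationError):
        benjamini_hochberg([0.1, np.nan])


def test_bh_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(5)
    p = rng.uniform(size=200)
    ours = benjamini_hochberg(p)
    _, theirs, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(ours, theirs, atol=1e-12)


def test_bh_monotone_after_sorting():
    rng = np.random.default_rng(6)
    p = rng.uniform(size=97)
    fdr = benjamini_hochberg(p)
    order = np.argsort(p)
    assert (np.diff(fdr[order]) >= -1e-15).all()
    assert (fdr >= p).all()


# ---------------------------------------------- per-pair logFC + LRT ----

def test_per_pair_identical_cotwins_zero_logfc():
    sheet = _disc_sheet(2)
    y = np.array([[10, 10, 40, 40], [5, 5, 80, 80], [100, 100, 7, 7]])
    cm = _cm(y, samples=list(sheet.table["sample_id"]))
    pp = per_pair_logfc(cm, sheet, tmm_factors(cm))
    assert np.allclose(pp.to_numpy(), 0.0, atol=1e-12)


def test_per_pair_fourfold_ratio_large_counts():
    sheet = _disc_sheet(2)
    base = np.full(50, 10_000)
    a = np.r_[40_000, base]  # case twin has 4x gene0
    b = np.r_[10_000, base]
    cm = _cm(np.column_stack([a, b, np.r_[9000, base], np.r_[9000, base]]),
             samples=list(sheet.table["sample_id"]))
    pp = per_pair_logfc(cm, sheet, tmm_factors(cm))
    assert pp.iloc[0, 0] == pytest.approx(2.0, abs=0.15)


def test_direction_consistency_rules():
    pp = pd.DataFrame({"P1": [1.0, 1.0, -1.0, 0.0],
                       "P2": [2.0, -0.5, -2.0, 1.0]},
                      index=list("wxyz"))
    assert direction_consistency(pp, "w") == "up"
    assert direction_consistency(pp, "x") == "none"
    assert direction_consistency(pp, "y") == "down"
    assert direction_consistency(pp, "z") == "none"  # zero -> none
    ann = _annotate_direction(pp)
    assert list(ann) == ["up", "none", "down", "none"]


def test_lrt_strong_effect_found_with_consistent_signs(disc_fit, small_cohort):
    cm, sheet, design, norm = disc_fit
    (_, _, _, truth), _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        de = lrt_case(cm, sheet, "discordant_group", norm=norm, design=design)
    assert set(de.columns) >= {"gene_id", "logFC", "logCPM", "p_value", "fdr",
                               "consistent_direction"}
    assert (np.diff(de["p_value"]) >= 0).all()
    hits = de[de["fdr"] < 0.1]
    true_pos = [g for g in hits["gene_id"] if g in truth.de_genes]
    assert len(true_pos) >= 0.5 * len(truth.de_genes)
    # strongly DE genes should mostly carry a consistent direction flag
    top = de.head(10)
    flagged = (top["consistent_direction"] != "none").mean()
    assert flagged >= 0.5
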