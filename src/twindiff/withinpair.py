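"""Within-pair |logFC| comparisons across the three study groups.

Pools absolute per-pair log fold changes over genes and pairs within each
group and compares group means (Welch t) and whole distributions
(two-sample Kolmogorov-Smirnov). Pooled values are strongly gene-gene
dependent; no dependence correction is applied, and every report carries a
caveat to that effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SampleSheet, ValidationError

DEPENDENCE_CAVEAT = (
    "pooled |logFC| values are dependent across genes; test p-values are "
    "descriptive, not dependence-corrected"
)


@dataclass
class GroupLogFcDistributions:
    pooled: dict  # group -> 1-D array of |logFC| over genes x pairs
    means: dict  # group -> mean |logFC|
    tests: pd.DataFrame  # pairwise group comparisons (t, p_t, ks_d, p_ks)
    caveat: str = DEPENDENCE_CAVEAT


def welch_t(a, b):
    """Welch unequal-variance t statistic and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t needs >= 2 observations per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValidationError("degenerate zero-variance samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def ks_two_sample(a, b):
    """Two-sample KS: exact supremum D over the pooled order statistics,
    p from the asymptotic Kolmogorov distribution at effective
    n = n_a * n_b / (n_a + n_b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("ks_two_sample needs non-empty samples")
    d = float(stats.ks_2samp(a, b, method="asymp").statistic)
    en = a.size * b.size / (a.size + b.size)
    p = float(stats.kstwobign.sf(np.sqrt(en) * d))
    return d, min(max(p, 0.0), 1.0)


def collect_abs_logfc(pp: pd.DataFrame, sheet: SampleSheet) -> GroupLogFcDistributions:
    """Pool |logFC| by study group over all genes and complete pairs, then
    run Welch t and KS tests for every pair of groups."""
    cp = sheet.complete_pairs()
    group_of = dict(cp.drop_duplicates("pair_id")[["pair_id", "group"]].values)
    pooled: dict = {}
    for pid in pp.columns:
        g = group_of.get(pid)
        if g is None:
            continue
        pooled.setdefault(g, []).append(np.abs(pp[pid].to_numpy(dtype=float)))
    present = sorted(pooled)
    if not present:
        raise ValidationError("no complete pairs with a known group")
    pooled = {g: np.concatenate(v) for g, v in pooled.items()}
    means = {g: float(v.mean()) for g, v in pooled.items()}

    rows = []
    for i, ga in enumerate(present):
        for gb in present[i + 1:]:
            t, pt = welch_t(pooled[ga], pooled[gb])
            d, pk = ks_two_sample(pooled[ga], pooled[gb])
            rows.append({"group_a": ga, "group_b": gb,
                         "mean_a": means[ga], "mean_b": means[gb],
                         "t": t, "p_t": pt, "ks_d": d, "p_ks": pk})
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_a", "mean_b",
                                        "t", "p_t", "ks_d", "p_ks"])
    return GroupLogFcDistributions(pooled=pooled, means=means, tests=tests)
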