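"""Two-library differential expression on block counts.

The test is a pooled two-proportion z-test (difference in proportions) on
raw weighted counts against library totals — the totals provide the
normalization, so no RPM scaling is applied before testing. RPM enters
only through the low-expression prefilter and the reported fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

RPM_MIN = 20.0
FC_MIN = 2.0
ALPHA = 0.05

#: the standard eight-library design and its six pairwise contrasts
PAPER_LIBRARIES = (
    "cotyledon_dark",
    "cotyledon_fr",
    "hook_concave_dark",
    "hook_concave_fr",
    "hook_convex_dark",
    "hook_convex_fr",
    "hypocotyl_dark",
    "hypocotyl_fr",
)

PAPER_COMPARISONS = (
    ("cotyledon_fr_vs_dark", "cotyledon_fr", "cotyledon_dark"),
    ("hypocotyl_fr_vs_dark", "hypocotyl_fr", "hypocotyl_dark"),
    ("hook_convex_fr_vs_dark", "hook_convex_fr", "hook_convex_dark"),
    ("hook_concave_fr_vs_dark", "hook_concave_fr", "hook_concave_dark"),
    ("hook_convex_vs_concave_fr", "hook_convex_fr", "hook_concave_fr"),
    ("hook_convex_vs_concave_dark", "hook_convex_dark", "hook_concave_dark"),
)


def dip_test(x1: float, n1: float, x2: float, n2: float) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided normal p-value.

    z = (x1/n1 - x2/n2) / sqrt(pbar (1 - pbar) (1/n1 + 1/n2)) with
    pbar = (x1 + x2) / (n1 + n2). z**2 equals the Pearson chi-square
    statistic of the corresponding 2x2 table without continuity correction.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie within totals")
    if x1 == 0 and x2 == 0:
        raise ValueError("dip_test undefined for x1 = x2 = 0")
    p1, p2 = x1 / n1, x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    denom = np.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
    if denom == 0.0:  # pbar == 1: both libraries are all this block
        return 0.0, 1.0
    z = (p1 - p2) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """p_adj = min(1, p * m); m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m == 0:
        return np.array([])
    return np.minimum(1.0, p * m)


def run_comparison(
    count_matrix: pd.DataFrame,
    lib_a: str,
    lib_b: str,
    *,
    totals: pd.Series | None = None,
    rpm_min: float = RPM_MIN,
    fc_min: float = FC_MIN,
    alpha: float = ALPHA,
    label: str | None = None,
) -> pd.DataFrame:
    """DIP test every block passing the RPM prefilter in one comparison.

    Totals default to the column sums of the matrix (the genome-perfect
    weighted totals, by conservation). Status per block:
    not_tested (failed the RPM prefilter), tested_ns, de_up (higher in
    lib_a), de_down. Significance requires Bonferroni-adjusted p < alpha
    AND fold change >= fc_min in either direction; fold change is computed
    on RPM-scaled counts (infinite over a zero denominator).
    """
    for lib in (lib_a, lib_b):
        if lib not in count_matrix.columns:
            raise KeyError(f"unknown library id: {lib}")
    if totals is None:
        totals = count_matrix.sum(axis=0)
    n1, n2 = float(totals[lib_a]), float(totals[lib_b])
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both libraries need positive totals")

    ca = count_matrix[lib_a].astype(float)
    cb = count_matrix[lib_b].astype(float)
    rpm_a = ca * 1e6 / n1
    rpm_b = cb * 1e6 / n2
    tested = (rpm_a > rpm_min) | (rpm_b > rpm_min)

    rows = []
    tested_ids = count_matrix.index[tested]
    pvals = {}
    zvals = {}
    for bid in tested_ids:
        z, p = dip_test(ca[bid], n1, cb[bid], n2)
        zvals[bid], pvals[bid] = z, p
    m = len(tested_ids)
    padj = dict(zip(tested_ids, bonferroni([pvals[b] for b in tested_ids], m)))

    for bid in count_matrix.index:
        a, b = float(ca[bid]), float(cb[bid])
        if not tested[bid]:
            rows.append(
                dict(block_id=bid, comparison=label or f"{lib_a}_vs_{lib_b}",
                     count_a=a, count_b=b, total_a=n1, total_b=n2,
                     z=np.nan, p=np.nan, p_adj=np.nan, fold_change=np.nan,
                     status="not_tested")
            )
            continue
        if rpm_b[bid] > 0:
            fc = rpm_a[bid] / rpm_b[bid]
        else:
            fc = np.inf
        eff_fc = fc if fc >= 1 else (np.inf if fc == 0 else 1.0 / fc)
        sig = padj[bid] < alpha and eff_fc >= fc_min
        if sig:
            status = "de_up" if rpm_a[bid] >= rpm_b[bid] else "de_down"
        else:
            status = "tested_ns"
        rows.append(
            dict(block_id=bid, comparison=label or f"{lib_a}_vs_{lib_b}",
                 count_a=a, count_b=b, total_a=n1, total_b=n2,
                 z=zvals[bid], p=pvals[bid], p_adj=float(padj[bid]),
                 fold_change=float(fc), status=status)
        )
    return pd.DataFrame(rows).set_index("block_id")


def run_all_comparisons(
    count_matrix: pd.DataFrame,
    comparisons=PAPER_COMPARISONS,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run a set of labelled comparisons (defaults to the six-contrast preset)."""
    out = {}
    for item in comparisons:
        label, lib_a, lib_b = item
        out[label] = run_comparison(count_matrix, lib_a, lib_b, label=label, **kwargs)
    return out
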