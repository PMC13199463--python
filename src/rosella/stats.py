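"""Grouping, control-normalization and normality-gated paired testing.

The statistical treatment mirrors a common small-n design in organoid and
culture studies: raw per-field measurements are averaged to one value per
(condition, cell line, independent experiment, timepoint, metric); values
are expressed relative to the mean of the controls (either across all
timepoints, preserving temporal trends, or within each timepoint); and
control-vs-disease comparisons are paired by experiment, using a paired
t-test when both groups pass Shapiro–Wilk normality at α = 0.05 and the
Wilcoxon signed-rank test otherwise. Significance stars follow the usual
strict cutpoints: p < 0.05 (*), < 0.01 (**), < 0.001 (***), < 0.0001 (****).

The signed-rank null is evaluated by full enumeration of all 2^n sign
assignments for n ≤ 12 pairs (exact even with rank ties) and by a normal
approximation with tie and continuity corrections above.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedMeasurement",
    "TestResult",
    "aggregate",
    "normalize_to_control",
    "normality_check",
    "signed_rank_test",
    "compare_groups",
    "star_annotation",
]

GROUP_KEYS = ["condition", "line_id", "experiment_id", "timepoint", "metric"]

STAR_CUTPOINTS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class GroupedMeasurement:
    condition: str
    line_id: str
    experiment_id: str
    timepoint: float
    metric: str
    value: float


@dataclass
class TestResult:
    metric: str
    timepoint: float | str
    test_used: str  # wilcoxon_signed_rank | t_test | mann_whitney | untestable
    statistic: float
    p_value: float
    n_pairs: int
    stars: str
    normality_p: dict[str, float]


def aggregate(
    raw: pd.DataFrame,
    keys: list[str] | None = None,
    value_col: str = "value",
) -> pd.DataFrame:
    """Mean value per (condition, line, experiment, timepoint, metric).

    Returns a long-format table with the group keys, the mean ``value`` and
    the contributing ``n``. Rows with missing values are dropped (an empty
    group simply does not appear).
    """
    keys = keys or [k for k in GROUP_KEYS if k in raw.columns]
    missing = [k for k in keys if k not in raw.columns]
    if missing:
        raise ValueError(f"raw table lacks key columns: {missing}")
    clean = raw.dropna(subset=[value_col])
    out = (
        clean.groupby(keys, as_index=False, sort=True)[value_col]
        .agg(value="mean", n="count")
        .rename(columns={})
    )
    return out


def normalize_to_control(
    table: pd.DataFrame,
    mode: str = "across_all_timepoints",
    control_label: str = "control",
    value_col: str = "value",
) -> pd.DataFrame:
    """Divide every value by the mean of the controls in its stratum.

    ``mode='across_all_timepoints'`` uses one control mean per metric
    (comparisons over time stay on a common scale);
    ``mode='per_timepoint'`` uses the control mean within each
    (metric, timepoint) stratum. Either way the control mean of the
    normalizing stratum becomes exactly 1.
    """
    if mode == "across_all_timepoints":
        strata = ["metric"]
    elif mode == "per_timepoint":
        strata = ["metric", "timepoint"]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = table.copy()

    def _norm(group: pd.DataFrame) -> pd.DataFrame:
        ctrl = group.loc[group.condition == control_label, value_col]
        if ctrl.empty:
            raise ValueError(
                f"no control values in stratum {group.name!r}; cannot normalize"
            )
        divisor = ctrl.mean()
        if divisor == 0:
            raise ValueError(f"control mean is 0 in stratum {group.name!r}")
        group = group.copy()
        group[value_col] = group[value_col] / divisor
        return group

    normed = (
        out.groupby(strata, group_keys=False, sort=False)[out.columns]
        .apply(_norm)
        .reset_index(drop=True)
    )
    return normed


def normality_check(values: np.ndarray) -> tuple[float, float] | None:
    """Shapiro–Wilk (W, p); ``None`` flags an untestable sample (n < 3)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or np.ptp(values) == 0:
        return None
    w, p = sps.shapiro(values)
    return float(w), float(p)


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray, int]:
    d = diffs[diffs != 0]  # Wilcoxon's convention: zero differences dropped
    n = len(d)
    ranks = sps.rankdata(np.abs(d))  # ties share mid-ranks
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks, n


def signed_rank_test(diffs: np.ndarray, exact_max_n: int = 12) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns ``(W+, p, n_used)``. For ``n_used <= exact_max_n`` the null
    distribution of W+ is built by enumerating all 2^n sign assignments
    (exact even under rank ties); above that a normal approximation with tie
    and continuity corrections is used. ``n_used`` counts nonzero
    differences; fewer than 2 usable pairs yields ``p = nan``.
    """
    diffs = np.asarray(diffs, dtype=float)
    w_plus, ranks, n = _signed_rank_statistic(diffs)
    if n < 2:
        return w_plus, float("nan"), n
    if n <= exact_max_n:
        # distribution of W+ over all sign assignments
        signs = np.array(list(product((0.0, 1.0), repeat=n)))
        w_all = signs @ ranks
        p_le = np.mean(w_all <= w_plus + 1e-9)
        p_ge = np.mean(w_all >= w_plus - 1e-9)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, float(p), n
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the no-tie variance
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((counts**3 - counts).sum()) / 48.0
    if var <= 0:
        return w_plus, float("nan"), n
    z = (w_plus - mean - np.sign(w_plus - mean) * 0.5) / np.sqrt(var)
    return w_plus, float(2 * sps.norm.sf(abs(z))), n


def star_annotation(p: float) -> str:
    """Map a p-value to its significance stars (strict inequalities)."""
    if np.isnan(p):
        return "ns"
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for cut, label in STAR_CUTPOINTS:
        if p < cut:
            return label
    return "ns"


def compare_groups(
    control: np.ndarray,
    treated: np.ndarray,
    paired: bool = True,
    normality_alpha: float = 0.05,
    metric: str = "",
    timepoint: float | str = "",
) -> TestResult:
    """Normality-gated control-vs-disease comparison.

    Paired design (values aligned on the pairing key, e.g. experiment ×
    timepoint): paired t-test if both groups pass Shapiro–Wilk at
    ``normality_alpha``, else the Wilcoxon signed-rank test. Unpaired
    fallback: Welch t-test or Mann–Whitney U. Two-sided throughout.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    norm_c = normality_check(control)
    norm_t = normality_check(treated)
    normality_p = {
        "control": norm_c[1] if norm_c else float("nan"),
        "treated": norm_t[1] if norm_t else float("nan"),
    }
    both_normal = (
        norm_c is not None
        and norm_t is not None
        and norm_c[1] >= normality_alpha
        and norm_t[1] >= normality_alpha
    )

    if paired:
        if len(control) != len(treated):
            raise ValueError("paired comparison needs equal-length groups")
        n_pairs = len(control)
        diffs = treated - control
        usable = int((diffs != 0).sum())
        if n_pairs < 2 or usable < 2:
            return TestResult(
                metric, timepoint, "untestable", float("nan"), float("nan"),
                n_pairs, "ns", normality_p,
            )
        if both_normal:
            stat, p = sps.ttest_rel(treated, control)
            test = "t_test"
            n_used = n_pairs
        else:
            stat, p, n_used = signed_rank_test(diffs)
            test = "wilcoxon_signed_rank"
            if np.isnan(p):
                return TestResult(
                    metric, timepoint, "untestable", stat, p, n_used, "ns",
                    normality_p,
                )
        return TestResult(
            metric, timepoint, test, float(stat), float(p), n_used,
            star_annotation(float(p)), normality_p,
        )

    if len(control) < 2 or len(treated) < 2:
        return TestResult(
            metric, timepoint, "untestable", float("nan"), float("nan"),
            min(len(control), len(treated)), "ns", normality_p,
        )
    if both_normal:
        stat, p = sps.ttest_ind(treated, control, equal_var=False)
        test = "t_test"
    else:
        stat, p = sps.mannwhitneyu(treated, control, alternative="two-sided")
        test = "mann_whitney"
    return TestResult(
        metric, timepoint, test, float(stat), float(p),
        min(len(control), len(treated)), star_annotation(float(p)), normality_p,
    )


def compare_table(
    table: pd.DataFrame,
    pairing_keys: list[str] | None = None,
    control_label: str = "control",
    per_timepoint: bool = False,
) -> pd.DataFrame:
    """Run compare_groups per metric (optionally per timepoint) on a table.

    Values are paired on ``pairing_keys`` (default: experiment_id, plus
    timepoint when pooling timepoints); rows without a partner in the other
    condition are dropped.
    """
    results = []
    strata = ["metric"] + (["timepoint"] if per_timepoint else [])
    pairing_keys = pairing_keys or (
        ["experiment_id"] + ([] if per_timepoint else ["timepoint"])
    )
    for key, group in table.groupby(strata, sort=True):
        wide = group.pivot_table(
            index=pairing_keys, columns="condition", values="value", aggfunc="mean"
        ).dropna()
        other = [c for c in wide.columns if c != control_label]
        if not other or control_label not in wide.columns:
            continue
        res = compare_groups(
            wide[control_label].to_numpy(),
            wide[other[0]].to_numpy(),
            metric=key[0] if isinstance(key, tuple) else key,
            timepoint=key[1] if isinstance(key, tuple) and len(key) > 1 else "all",
        )
        mean_ratio = (
            wide[other[0]].mean() / wide[control_label].mean()
            if wide[control_label].mean() != 0
            else float("nan")
        )
        results.append(
            {
                "metric": res.metric,
                "timepoint": res.timepoint,
                "test_used": res.test_used,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_pairs": res.n_pairs,
                "stars": res.stars,
                "treated_over_control": mean_ratio,
            }
        )
    return pd.DataFrame(results)
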