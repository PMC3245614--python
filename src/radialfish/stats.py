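"""Condition-level aggregation and shell-wise comparison.

Per-nucleus normalized shell profiles are averaged into a condition
histogram (mean ± SEM across nuclei), conditions are compared shell by
shell with Welch's unequal-variance two-tailed t-test, and a mean profile
is summarized into a peripheral / intermediate / interior label via its
shell center of mass.

No multiple-testing correction is applied across the five shells by
default, matching the per-shell P < 0.05 convention of erosion analyses; a
Bonferroni option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import AggregationError, SmallCohortWarning
from .shells import ShellProfile

__all__ = [
    "ShellComparison",
    "PopulationResult",
    "aggregate",
    "compare",
    "classify_position",
    "plot_profile",
]

#: cohort size below which a warning is emitted (erosion analyses
#: conventionally use >= 50 nuclei per condition)
RECOMMENDED_MIN_NUCLEI = 50


@dataclass(frozen=True)
class ShellComparison:
    """Welch test result for one shell."""

    shell: int
    t: float
    df: float
    p_value: float
    significant: bool
    degenerate: bool = False


@dataclass
class PopulationResult:
    """Aggregated shell profile of one condition.

    ``values`` keeps the raw per-nucleus normalized profiles (n_nuclei × 5)
    so that comparisons can be run later; ``comparisons`` collects test
    results keyed by the reference condition's label.
    """

    condition: str
    n_nuclei: int
    mean: np.ndarray
    sem: np.ndarray
    values: np.ndarray
    comparisons: dict = field(default_factory=dict)


def aggregate(profiles: list[ShellProfile], condition: str = "") -> PopulationResult:
    """Average per-nucleus normalized profiles into a condition result.

    SEM is the sample standard deviation (ddof=1) divided by sqrt(n).

    Raises
    ------
    AggregationError
        With fewer than 2 profiles.  Cohorts below
        ``RECOMMENDED_MIN_NUCLEI`` nuclei trigger a warning, not an error.
    """
    if len(profiles) < 2:
        raise AggregationError(
            f"condition {condition!r}: need >= 2 profiles, got {len(profiles)}"
        )
    if len(profiles) < RECOMMENDED_MIN_NUCLEI:
        warnings.warn(
            f"condition {condition!r}: only {len(profiles)} nuclei "
            f"(recommended >= {RECOMMENDED_MIN_NUCLEI})",
            SmallCohortWarning,
            stacklevel=2,
        )
    values = np.vstack([p.normalized for p in profiles])
    n = values.shape[0]
    return PopulationResult(
        condition=condition,
        n_nuclei=n,
        mean=values.mean(axis=0),
        sem=values.std(axis=0, ddof=1) / np.sqrt(n),
        values=values,
    )


def _welch_one_shell(x: np.ndarray, y: np.ndarray, alpha: float) -> ShellComparison:
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        # degenerate by convention: equal means -> no evidence (P = 1);
        # unequal means with zero spread -> P = 0 limit
        if x.mean() == y.mean():
            return ShellComparison(0, 0.0, float(len(x) + len(y) - 2), 1.0, False, True)
        t = -np.inf if x.mean() < y.mean() else np.inf
        return ShellComparison(0, float(t), float(len(x) + len(y) - 2), 0.0, alpha > 0, True)
    res = sps.ttest_ind(x, y, equal_var=False)
    p = float(res.pvalue)
    return ShellComparison(0, float(res.statistic), float(res.df), p, p < alpha)


def compare(
    a: PopulationResult,
    b: PopulationResult,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[ShellComparison]:
    """Welch's two-tailed t-test per shell between two conditions.

    ``a`` is compared against reference ``b``; the result is also stored in
    ``a.comparisons[b.condition]``.  With ``bonferroni=True`` the per-shell
    significance level becomes ``alpha / n_shells``.

    Raises
    ------
    AggregationError
        If either cohort has fewer than 2 nuclei.
    """
    if not 0 < alpha < 1:
        raise AggregationError("alpha must be in (0, 1)")
    if a.n_nuclei < 2 or b.n_nuclei < 2:
        raise AggregationError("both cohorts need >= 2 nuclei for a comparison")
    if a.values.shape[1] != b.values.shape[1]:
        raise AggregationError("cohorts have different shell counts")
    level = alpha / a.values.shape[1] if bonferroni else alpha
    out = []
    for k in range(a.values.shape[1]):
        c = _welch_one_shell(a.values[:, k], b.values[:, k], level)
        out.append(
            ShellComparison(k + 1, c.t, c.df, c.p_value, c.significant, c.degenerate)
        )
    a.comparisons[b.condition] = out
    return out


def comparisons_frame(comparisons: list[ShellComparison]) -> pd.DataFrame:
    """Tabulate shell comparisons."""
    return pd.DataFrame(
        {
            "shell": [c.shell for c in comparisons],
            "t": [c.t for c in comparisons],
            "df": [c.df for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    )


def classify_position(
    result: PopulationResult | np.ndarray,
    peripheral_max: float = 2.4,
    interior_min: float = 3.6,
) -> str:
    """Label a mean shell profile as peripheral / intermediate / interior.

    Uses the shell center of mass c = Σ k·mean[k] / Σ mean[k] (shells
    numbered 1 at the periphery to 5 in the interior).  The thresholds are a
    package convention, not an established standard, and are configurable.

    Raises
    ------
    AggregationError
        On an all-zero profile.
    """
    mean = result.mean if isinstance(result, PopulationResult) else np.asarray(result, float)
    total = mean.sum()
    if total <= 0:
        raise AggregationError("cannot classify an all-zero mean profile")
    c = float(np.arange(1, len(mean) + 1) @ mean / total)
    if c <= peripheral_max:
        return "peripheral"
    if c >= interior_min:
        return "interior"
    return "intermediate"


def shell_center_of_mass(mean: np.ndarray) -> float:
    """Shell center of mass of a profile (1 = periphery, 5 = interior)."""
    mean = np.asarray(mean, dtype=float)
    return float(np.arange(1, len(mean) + 1) @ mean / mean.sum())


def plot_profile(result: PopulationResult, reference: str | None = None, ax=None):
    """Bar histogram of a condition's mean normalized profile.

    Shell 1 (periphery) is leftmost; error bars show SEM; shells
    significantly different from the reference condition (if a stored
    comparison exists) are marked with a filled square above the bar.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    shells = np.arange(1, len(result.mean) + 1)
    ax.bar(shells, result.mean, yerr=result.sem, capsize=3, color="0.6", edgecolor="k")
    comps = result.comparisons.get(reference) if reference else None
    if comps:
        for c in comps:
            if c.significant:
                y = result.mean[c.shell - 1] + result.sem[c.shell - 1]
                ax.plot(c.shell, y * 1.08 + 0.02, marker="s", color="k")
    ax.set_xlabel("shell (1 = periphery, 5 = interior)")
    ax.set_ylabel("mean normalized proportion")
    ax.set_title(f"{result.condition} (n={result.n_nuclei})")
    ax.set_xticks(shells)
    return ax
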