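"""Cohort-level statistics: Grubbs screening, two-way ANOVA with Tukey
post-hoc contrasts at three comparison levels, paired mixed-effects
comparisons with Sidak adjustment, power-based sample sizing, and report
arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "ComparisonResult",
    "grubbs_outliers",
    "group_subset_comparisons",
    "paired_mixed_comparisons",
    "required_sample_size",
    "percentage",
    "sidak_adjust",
]

#: Column contract for the long-format cohort table.
COHORT_COLUMNS = ("sample_id", "group", "subject_id", "subset", "parameter", "value")
CohortTable = pd.DataFrame  # alias documenting intent


@dataclass(frozen=True)
class ComparisonResult:
    """One adjusted pairwise contrast."""

    label: str
    estimate: float
    p_adjusted: float
    method: str  # "tukey" or "sidak"
    level: str  # groups-overall | groups-within-subset | subsets-within-group
    estimable: bool = True


# ---------------------------------------------------------------------------
# Grubbs outlier screening
# ---------------------------------------------------------------------------


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(values, alpha: float = 0.01, max_fraction: float = 0.2):
    """Indices of extreme outliers found by the iterative two-sided Grubbs test.

    At each step the point with the largest ``|x - mean| / sd`` is tested
    against the t-based critical value and removed if significant, repeating
    while significant; removals are capped at ``floor(n * max_fraction)`` of
    the original sample to guard small n.
    """
    x = np.asarray(values, dtype=float)
    n0 = len(x)
    if n0 < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    max_removals = int(n0 * max_fraction)
    active = np.arange(n0)
    flagged: list[int] = []

    while len(flagged) < max_removals and len(active) >= 3:
        sub = x[active]
        s = sub.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        g = dev[j] / s
        if g > _grubbs_critical(len(sub), alpha):
            flagged.append(int(active[j]))
            active = np.delete(active, j)
        else:
            break
    return sorted(flagged)


# ---------------------------------------------------------------------------
# Two-way ANOVA with Tukey post-hoc contrasts
# ---------------------------------------------------------------------------


def _cell_stats(df: pd.DataFrame):
    """Cell means/counts and the pooled within-cell mean square (full model)."""
    g = df.groupby(["group", "subset"], observed=True)["value"]
    means = g.mean()
    ns = g.size()
    ss_within = float(((df["value"] - g.transform("mean")) ** 2).sum())
    df_resid = int(len(df) - len(means))
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom in the group x subset design")
    mse = ss_within / df_resid
    return means, ns, mse, df_resid


def _tukey_p(diff: float, se: float, k: int, df: int) -> float:
    if se == 0:
        return 1.0 if diff == 0 else 0.0
    q = abs(diff) / (se / math.sqrt(2.0))
    return float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))


def group_subset_comparisons(
    table: CohortTable, parameter: str
) -> list[ComparisonResult]:
    """Tukey-adjusted pairwise contrasts from a two-way group x subset design.

    Contrasts are produced at three levels: (1) between group marginal means
    ignoring subsets, (2) between groups within each subset, and (3) between
    subsets within each group.  Marginal means are unweighted means of cell
    means, so unbalanced designs are handled in the Type-III spirit; the
    error term is the pooled within-cell mean square of the full interaction
    model.  Contrasts touching a cell with fewer than two observations are
    reported as not estimable.
    """
    df = table[table["parameter"] == parameter].dropna(subset=["value"])
    groups = sorted(df["group"].unique())
    subsets = sorted(df["subset"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    means, ns, mse, df_resid = _cell_stats(df)

    def cell(g, s):
        try:
            return float(means.loc[(g, s)]), int(ns.loc[(g, s)])
        except KeyError:
            return math.nan, 0

    results: list[ComparisonResult] = []

    # level 1: group marginal means over all subsets
    k = len(groups)
    for ga, gb in combinations(groups, 2):
        cells_a = [cell(ga, s) for s in subsets]
        cells_b = [cell(gb, s) for s in subsets]
        ok = all(n >= 2 for _, n in cells_a + cells_b)
        if ok:
            ma = np.mean([m for m, _ in cells_a])
            mb = np.mean([m for m, _ in cells_b])
            var = mse / len(subsets) ** 2 * (
                sum(1.0 / n for _, n in cells_a) + sum(1.0 / n for _, n in cells_b)
            )
            est = ma - mb
            p = _tukey_p(est, math.sqrt(var), k, df_resid)
        else:
            est, p = math.nan, math.nan
        results.append(
            ComparisonResult(
                label=f"{ga}-{gb}", estimate=est, p_adjusted=p,
                method="tukey", level="groups-overall", estimable=ok,
            )
        )

    # level 2: groups within each subset
    for s in subsets:
        for ga, gb in combinations(groups, 2):
            (ma, na), (mb, nb) = cell(ga, s), cell(gb, s)
            ok = na >= 2 and nb >= 2
            if ok:
                est = ma - mb
                se = math.sqrt(mse * (1.0 / na + 1.0 / nb))
                p = _tukey_p(est, se, k, df_resid)
            else:
                est, p = math.nan, math.nan
            results.append(
                ComparisonResult(
                    label=f"{ga}-{gb}|{s}", estimate=est, p_adjusted=p,
                    method="tukey", level="groups-within-subset", estimable=ok,
                )
            )

    # level 3: subsets within each group
    ks = len(subsets)
    for g in groups:
        for sa, sb in combinations(subsets, 2):
            (ma, na), (mb, nb) = cell(g, sa), cell(g, sb)
            ok = na >= 2 and nb >= 2
            if ok:
                est = ma - mb
                se = math.sqrt(mse * (1.0 / na + 1.0 / nb))
                p = _tukey_p(est, se, ks, df_resid) if ks >= 2 else math.nan
            else:
                est, p = math.nan, math.nan
            results.append(
                ComparisonResult(
                    label=f"{sa}-{sb}|{g}", estimate=est, p_adjusted=p,
                    method="tukey", level="subsets-within-group", estimable=ok,
                )
            )

    return results


# ---------------------------------------------------------------------------
# Paired mixed-effects comparisons
# ---------------------------------------------------------------------------


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: ``1 - (1 - p)^m``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def _mixed_treatment_effect(sub: pd.DataFrame, pre_group: str, post_group: str):
    """Random-intercept mixed model of value on treatment; returns (est, p)."""
    import statsmodels.api as sm

    y = sub["value"].to_numpy(dtype=float)
    post = (sub["group"] == post_group).to_numpy(dtype=float)
    exog = np.column_stack([np.ones_like(post), post])

    # degenerate designs: no residual variability after subject centering
    per_subj = sub.groupby("subject_id")["value"]
    centered = (sub["value"] - per_subj.transform("mean")).to_numpy(dtype=float)
    if len(centered) == 0 or float(np.max(np.abs(centered))) < 1e-12:
        est = float(y[post == 1].mean() - y[post == 0].mean()) if post.any() else 0.0
        return est, 1.0 if abs(est) < 1e-12 else 0.0

    last_error: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # boundary variance estimates can break individual optimizers
        for method in ("lbfgs", "powell", "nm", "bfgs"):
            try:
                model = sm.MixedLM(y, exog, groups=sub["subject_id"].to_numpy())
                fit = model.fit(reml=True, method=method)
                est = float(np.asarray(fit.fe_params)[1])
                p = float(np.asarray(fit.pvalues)[1])
            except Exception as exc:  # noqa: BLE001 - optimizer-specific failures
                last_error = exc
                continue
            if np.isfinite(p) and np.isfinite(est):
                return est, p
    raise RuntimeError(f"mixed model did not converge: {last_error}")


def paired_mixed_comparisons(
    table: CohortTable,
    pre_group: str,
    post_group: str,
    parameter: str,
) -> list[ComparisonResult]:
    """Per-subset treatment effects from a random-subject-intercept mixed model.

    Subjects with a missing pre or post visit still contribute to the fit.
    P-values are Sidak-adjusted across the subsets tested.
    """
    df = table[
        (table["parameter"] == parameter)
        & table["group"].isin([pre_group, post_group])
    ].dropna(subset=["value"])
    if df["subject_id"].nunique() < 3:
        raise ValueError("need at least 3 subjects for the mixed model")

    subsets = sorted(df["subset"].unique())
    m = len(subsets)
    results = []
    for s in subsets:
        sub = df[df["subset"] == s]
        has_pre = (sub["group"] == pre_group).any()
        has_post = (sub["group"] == post_group).any()
        if not (has_pre and has_post):
            results.append(
                ComparisonResult(
                    label=f"{post_group}-{pre_group}|{s}", estimate=math.nan,
                    p_adjusted=math.nan, method="sidak",
                    level="groups-within-subset", estimable=False,
                )
            )
            continue
        try:
            est, p = _mixed_treatment_effect(sub, pre_group, post_group)
        except Exception:
            results.append(
                ComparisonResult(
                    label=f"{post_group}-{pre_group}|{s}", estimate=math.nan,
                    p_adjusted=math.nan, method="sidak",
                    level="groups-within-subset", estimable=False,
                )
            )
            continue
        results.append(
            ComparisonResult(
                label=f"{post_group}-{pre_group}|{s}", estimate=est,
                p_adjusted=sidak_adjust(min(max(p, 0.0), 1.0), m),
                method="sidak", level="groups-within-subset",
            )
        )
    return results


# ---------------------------------------------------------------------------
# Power-based sample size
# ---------------------------------------------------------------------------


def _two_sample_t_power(d: float, n: int, alpha: float) -> float:
    dfree = 2 * n - 2
    nc = d * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dfree)
    return float(
        stats.nct.sf(tcrit, dfree, nc) + stats.nct.cdf(-tcrit, dfree, nc)
    )


def required_sample_size(
    pilot_mean_diff: float,
    pilot_sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    max_n: int = 100_000,
) -> int:
    """Smallest per-group n giving a two-sided two-sample t-test the target power.

    Effect size ``d = pilot_mean_diff / pilot_sd``; power is computed with the
    noncentral-t distribution and n is increased until it is reached.
    """
    if pilot_sd <= 0:
        raise ValueError("pilot_sd must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.0 < power < 1.0:
        raise ValueError("power must be in (0, 1)")
    d = abs(pilot_mean_diff) / pilot_sd
    if d == 0:
        raise ValueError("zero effect size: requested power is unreachable")
    for n in range(2, max_n + 1):
        if _two_sample_t_power(d, n, alpha) >= power:
            return n
    raise ValueError("required sample size exceeds max_n")


# ---------------------------------------------------------------------------
# Report arithmetic
# ---------------------------------------------------------------------------


def percentage(numerator: int, denominator: int) -> str:
    """Percentage of a count, formatted for reporting.

    Rounded to the nearest integer, except values with an exact one-decimal
    representation ending in .5, which keep that decimal (``37.5%``).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be between 0 and denominator")
    frac = Fraction(100 * numerator, denominator)
    tenths = frac * 10
    if tenths.denominator == 1 and tenths.numerator % 10 == 5:
        return f"{frac.numerator / frac.denominator:.1f}%"
    return f"{round(frac.numerator / frac.denominator)}%"
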