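"""Trial-level statistics: Mann-Whitney, ANOVA with Bonferroni post-hoc, and
the correct-trial subsampling control.

The comparisons mirror standard practice for trial-based electrophysiology:
nonparametric two-group contrasts (Mann-Whitney U, exact for small samples
without ties, normal approximation with tie correction otherwise), one- and
two-way fixed-effects ANOVA (Type II sums of squares for unbalanced designs)
with Bonferroni-adjusted pairwise post-hoc tests, and a per-subject
subsampling of the majority outcome group to rule out trial-count confounds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import TrialTable

__all__ = [
    "StatsResult",
    "mann_whitney",
    "anova",
    "bonferroni",
    "subsample_match",
    "movement_control",
]


@dataclass
class StatsResult:
    """Outcome of one statistical comparison."""

    test_name: str
    statistic: float
    p_value: float
    group_stats: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    post_hoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")

    def summary(self) -> str:
        lines = [f"{self.test_name}: statistic = {self.statistic:.6g}, p = {self.p_value:.4g}"]
        for name, (mean, sem, n) in self.group_stats.items():
            lines.append(f"  {name}: {mean:.6g} +/- {sem:.6g} (n = {n})")
        if self.post_hoc is not None:
            lines.append("  post-hoc (Bonferroni-adjusted):")
            lines.append("    " + self.post_hoc.to_string().replace("\n", "\n    "))
        return "\n".join(lines)


def _group_stats(groups: dict[str, np.ndarray]) -> dict[str, tuple[float, float, int]]:
    out = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
        out[name] = (float(vals.mean()), sem, int(vals.size))
    return out


def mann_whitney(group_a, group_b, exact_max_n: int = 20) -> StatsResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations and there are no ties across groups, and the
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= exact_max_n and b.size <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatsResult(
        test_name=f"Mann-Whitney U ({method})",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_stats=_group_stats({"A": a, "B": b}),
    )


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    """Bonferroni adjustment: min(1, p * m)."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return min(1.0, p_raw * n_comparisons)


def _posthoc_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    levels = sorted(pd.unique(labels))
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for la, lb in pairs:
        va, vb = values[labels == la], values[labels == lb]
        t, p = sps.ttest_ind(va, vb, equal_var=True)
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "t": float(t),
                "p_raw": float(p),
                "p_adj": bonferroni(float(p), len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def anova(
    values,
    factor1,
    factor2=None,
    post_hoc_factor: str | None = None,
) -> StatsResult:
    """One- or two-way fixed-effects ANOVA on trial-level values.

    With one factor, the classic one-way F test; with two factors, Type II
    sums of squares on the model with interaction.  The headline statistic
    and p-value are the factor1 main effect; the full table is in
    ``extra['anova_table']``.  ``post_hoc_factor`` ('factor1'/'factor2')
    requests Bonferroni-adjusted pairwise t tests across that factor's levels.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = np.asarray(values, dtype=float)
    f1 = np.asarray(factor1)
    df = pd.DataFrame({"value": y, "factor1": f1})
    for fac in ["factor1"] + (["factor2"] if factor2 is not None else []):
        if fac == "factor2":
            df["factor2"] = np.asarray(factor2)
        counts = df.groupby(fac, observed=True)["value"].count()
        if len(counts) < 2:
            raise ValueError(f"{fac} needs at least 2 levels")
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"{fac} levels with fewer than 2 observations: {bad}")

    if np.ptp(y) == 0:
        # degenerate all-equal input: no variance to explain
        return StatsResult(
            test_name="one-way ANOVA" if factor2 is None else "two-way ANOVA (Type II)",
            statistic=0.0,
            p_value=1.0,
            group_stats=_group_stats(
                {str(k): g["value"].to_numpy() for k, g in df.groupby("factor1", observed=True)}
            ),
        )

    formula = (
        "value ~ C(factor1)"
        if factor2 is None
        else "value ~ C(factor1) * C(factor2)"
    )
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=2)
    f_stat = float(table.loc["C(factor1)", "F"])
    p_val = float(table.loc["C(factor1)", "PR(>F)"])

    post_hoc = None
    if post_hoc_factor is not None:
        col = {"factor1": "factor1", "factor2": "factor2"}[post_hoc_factor]
        post_hoc = _posthoc_pairwise(df["value"].to_numpy(), df[col].to_numpy())

    return StatsResult(
        test_name="one-way ANOVA" if factor2 is None else "two-way ANOVA (Type II)",
        statistic=f_stat,
        p_value=p_val,
        group_stats=_group_stats(
            {str(k): g["value"].to_numpy() for k, g in df.groupby("factor1", observed=True)}
        ),
        post_hoc=post_hoc,
        extra={"anova_table": table},
    )


def subsample_match(
    trials: TrialTable,
    group_field: str = "outcome",
    seed: int = 0,
    groups: tuple[str, str] = ("correct", "incorrect"),
) -> TrialTable:
    """Per-subject subsampling of the majority group to the minority count.

    For each subject, draws a uniform random subset of that subject's
    majority-group trials of the same size as its minority group, leaving the
    minority group intact.  Subjects missing one group entirely are excluded
    with a warning.  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    df = trials.data
    kept_indices: list[int] = []
    for subject, sub in df.groupby("subject"):
        n_by_group = {g: int((sub[group_field] == g).sum()) for g in groups}
        if min(n_by_group.values()) == 0:
            warnings.warn(
                f"subject {subject} lacks one of {groups}; excluded from subsampling",
                stacklevel=2,
            )
            continue
        minority = min(groups, key=lambda g: n_by_group[g])
        majority = groups[1] if minority == groups[0] else groups[0]
        maj_idx = sub.index[sub[group_field] == majority].to_numpy()
        chosen = rng.choice(maj_idx, size=n_by_group[minority], replace=False)
        kept_indices.extend(sub.index[sub[group_field] == minority].tolist())
        kept_indices.extend(sorted(chosen.tolist()))
    out = df.loc[sorted(kept_indices)].reset_index(drop=True)
    return TrialTable(out)


def movement_control(trials: TrialTable, by: str = "outcome") -> dict[str, StatsResult]:
    """Mann-Whitney tests on running speed and duration between groups.

    ``by`` is 'outcome' (correct vs incorrect) or 'phase' (choice vs sample).
    Returns ``{'speed': ..., 'duration': ...}``.
    """
    df = trials.data
    if df.empty:
        raise ValueError("empty trial table")
    for col in ("speed", "duration"):
        if df[col].isna().any():
            raise ValueError(f"missing values in {col!r}")
    if by == "outcome":
        ga = df[df["outcome"] == "correct"]
        gb = df[df["outcome"] == "incorrect"]
        labels = ("correct", "incorrect")
    elif by == "phase":
        ga = df[df["phase"] == "choice"]
        gb = df[df["phase"] == "sample"]
        labels = ("choice", "sample")
    else:
        raise ValueError("by must be 'outcome' or 'phase'")
    if ga.empty or gb.empty:
        raise ValueError(f"one of the {by} groups is empty")
    out = {}
    for col in ("speed", "duration"):
        res = mann_whitney(ga[col].to_numpy(), gb[col].to_numpy())
        res.group_stats = _group_stats(
            {labels[0]: ga[col].to_numpy(), labels[1]: gb[col].to_numpy()}
        )
        out[col] = res
    return out
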