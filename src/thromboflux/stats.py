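"""Group comparisons for assay endpoints.

Endpoints (lag time, rapid-phase slope, maximum accumulation, bleeding
time, blood loss) are summarized as mean ± SE and compared between two
unpaired groups with Student's pooled-variance t-test.  The t-test is
available both from raw per-subject values and from printed summary
statistics (mean, SE, n) so that published comparisons can be
reconstructed.  Trace metrics observed repeatedly over time are compared
with a two-way mixed-design (repeated-measures) ANOVA: group is the
between-subject factor, time the within-subject factor, implemented
directly from the sums-of-squares decomposition with the group factor
tested against subjects-within-group and the time and group x time
factors against the time x subjects-within-group residual.  No
sphericity correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TTestResult",
    "EffectSummary",
    "AnovaResult",
    "summarize",
    "t_test_raw",
    "t_test_from_summary",
    "effect_summary",
    "repeated_measures_anova",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SE of one endpoint in one group."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a group summary needs n >= 2")
        if self.se < 0:
            raise ValueError("se must be nonnegative")

    @property
    def sd(self) -> float:
        """Sample standard deviation implied by the SE."""
        return self.se * math.sqrt(self.n)

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.se:.2f} (n={self.n})"


@dataclass(frozen=True)
class TTestResult:
    """Two-sample pooled-variance t-test outcome.

    ``degenerate`` flags the zero-pooled-variance corner: equal means
    give t = 0, p = 1; unequal means an infinite t with p = 0.
    """

    t_stat: float
    df: float
    p_two_sided: float
    degenerate: bool = False

    @property
    def significant_05(self) -> bool:
        return self.p_two_sided < 0.05


@dataclass(frozen=True)
class EffectSummary:
    """Difference and fold-ratio of two group means.

    Stored at full precision; ``difference_1dp``/``fold_ratio_1dp`` apply
    the one-decimal presentation rounding used in reports.
    """

    difference: float
    fold_ratio: float  # NaN when the reference mean is zero

    @property
    def difference_1dp(self) -> float:
        return round(self.difference, 1)

    @property
    def fold_ratio_1dp(self) -> float:
        return round(self.fold_ratio, 1)


@dataclass(frozen=True)
class AnovaFactor:
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """Mixed-design ANOVA table: group, time and group x time factors."""

    group: AnovaFactor
    time: AnovaFactor
    interaction: AnovaFactor

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("group", self.group),
            ("time", self.time),
            ("group_x_time", self.interaction),
        ]
        return pd.DataFrame(
            [(name, f.F, f.df_num, f.df_den, f.p) for name, f in rows],
            columns=["factor", "F", "df_num", "df_den", "p"],
        )


def summarize(values) -> GroupSummary:
    """Mean ± SE (sample SD with n-1 denominator over sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("summarize requires at least 2 values")
    return GroupSummary(
        mean=float(v.mean()),
        se=float(v.std(ddof=1) / math.sqrt(v.size)),
        n=int(v.size),
    )


def _pooled_t(mean_a, mean_b, sd_a, sd_b, n_a, n_b) -> TTestResult:
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    denom = math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    diff = mean_a - mean_b
    if denom == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0, degenerate=True)
    t = diff / denom
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t, df, p)


def t_test_raw(group_a, group_b) -> TTestResult:
    """Student's pooled-variance t-test from raw unpaired values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    return _pooled_t(a.mean(), b.mean(), a.std(ddof=1), b.std(ddof=1),
                     a.size, b.size)


def t_test_from_summary(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Pooled t reconstructed from printed means, SEs and group sizes.

    Uses the pooled-variance formula on the SDs implied by the SEs; at
    equal group sizes this reduces to
    ``t = (mean_a - mean_b) / sqrt(se_a**2 + se_b**2)``.
    """
    return _pooled_t(a.mean, b.mean, a.sd, b.sd, a.n, b.n)


def effect_summary(a: GroupSummary, b: GroupSummary) -> EffectSummary:
    """Difference ``a - b`` and fold-ratio ``a / b`` of the group means."""
    diff = a.mean - b.mean
    ratio = a.mean / b.mean if b.mean != 0.0 else math.nan
    return EffectSummary(difference=diff, fold_ratio=ratio)


def repeated_measures_anova(
    data: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    group: str = "group",
    time: str = "time",
) -> AnovaResult:
    """Two-way mixed-design ANOVA (between: group, within: time).

    Requires a balanced design in the repeated-measures sense: every
    subject observed exactly once at every timepoint (group sizes may
    differ).  The decomposition:

    * ``SS_group`` tested against ``SS_subjects-within-group``
      with df ``(g - 1, N - g)``;
    * ``SS_time`` and ``SS_group x time`` tested against
      ``SS_time x subjects-within-group`` with df ``(T - 1, (N-g)(T-1))``
      and ``((g-1)(T-1), (N-g)(T-1))``.

    Raises
    ------
    ValueError
        On unbalanced designs (imputation is out of scope) or with fewer
        than 2 subjects per group or 2 timepoints.
    """
    df = data[[subject, group, time, value]].copy()
    times = sorted(df[time].unique())
    groups = sorted(df[group].unique(), key=str)
    if len(times) < 2:
        raise ValueError("need at least 2 timepoints")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")

    # Balance check: every subject exactly once at every timepoint.
    counts = df.pivot_table(index=subject, columns=time, values=value,
                            aggfunc="count", fill_value=0)
    if counts.shape[1] != len(times) or not (counts.values == 1).all():
        raise ValueError(
            "unbalanced design: every subject must be observed exactly once "
            "at every timepoint (imputation is out of scope)")
    subj_group = df.groupby(subject)[group].nunique()
    if (subj_group > 1).any():
        raise ValueError("each subject must belong to exactly one group")
    sizes = df.drop_duplicates(subject).groupby(group)[subject].count()
    if (sizes < 2).any():
        raise ValueError("need at least 2 subjects per group")

    T = len(times)
    g = len(groups)
    N = df[subject].nunique()
    gm = df[value].mean()

    subj_means = df.groupby(subject)[value].mean()
    group_means = df.groupby(group)[value].mean()
    time_means = df.groupby(time)[value].mean()
    cell_means = df.groupby([group, time])[value].mean()
    n_per_group = df.drop_duplicates(subject).groupby(group)[subject].count()

    ss_between_subj = T * float(((subj_means - gm) ** 2).sum())
    ss_group = T * float((n_per_group * (group_means - gm) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group

    ss_total = float(((df[value] - gm) ** 2).sum())
    ss_within_subj = ss_total - ss_between_subj
    ss_time = N * float(((time_means - gm) ** 2).sum())
    ss_inter = 0.0
    for grp in groups:
        for tp in times:
            dev = (cell_means.loc[(grp, tp)] - group_means.loc[grp]
                   - time_means.loc[tp] + gm)
            ss_inter += float(n_per_group.loc[grp]) * dev * dev
    ss_err = ss_within_subj - ss_time - ss_inter

    df_group, df_subj = g - 1, N - g
    df_time = T - 1
    df_inter = (g - 1) * (T - 1)
    df_err = (N - g) * (T - 1)

    def factor(ss_num, df_num, ss_den, df_den) -> AnovaFactor:
        ms_num = ss_num / df_num
        ms_den = ss_den / df_den
        if ms_den <= 0.0:
            f_val = math.inf if ms_num > 0 else 0.0
            p = 0.0 if ms_num > 0 else 1.0
        else:
            f_val = ms_num / ms_den
            p = float(sps.f.sf(f_val, df_num, df_den))
        return AnovaFactor(F=max(f_val, 0.0), df_num=df_num, df_den=df_den, p=p)

    return AnovaResult(
        group=factor(ss_group, df_group, ss_subj_within, df_subj),
        time=factor(ss_time, df_time, ss_err, df_err),
        interaction=factor(ss_inter, df_inter, ss_err, df_err),
    )
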