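"""Statistical battery for transfer-time studies.

Covers the analysis plan of a two-group (concussion, control) by
two-session longitudinal design: robust outlier marking (1.5 x IQR from
the median), paired and independent t-tests with Cohen's d_z / d, 2x2
mixed ANOVAs with generalized eta squared, a Pearson correlation battery
at alpha = 0.01, and sensitivity analyses (minimal detectable effect at a
given power) on the noncentral t and F distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as ss

__all__ = [
    "StatResult",
    "cohens_dz_from_t",
    "cohens_d_from_t",
    "mark_outliers",
    "outlier_flags_by_session",
    "paired_t",
    "independent_t",
    "mixed_anova_2x2",
    "correlation_battery",
    "min_detectable_d",
    "min_detectable_f",
]


@dataclass
class StatResult:
    """One test's statistic, degrees of freedom, p, and effect size(s)."""

    label: str
    statistic: float
    df: float | tuple
    p: float
    effect_sizes: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isnan(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p={self.p} outside [0, 1]")


def cohens_dz_from_t(t: float, n: int) -> float:
    """Within-subject effect size for a paired t: d_z = t / sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return float(t / np.sqrt(n))


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Between-group effect size from a pooled-variance two-sample t:
    d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))


def mark_outliers(values, iqr_multiplier: float = 1.5) -> np.ndarray:
    """Flag values farther than ``iqr_multiplier`` x IQR from the median.

    Quartiles use the linear-interpolation convention (numpy default).
    The inequality is strict: a deviation of exactly 1.5 x IQR is kept.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("need a 1-D vector of >= 4 values")
    med = np.median(x)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return np.abs(x - med) > iqr_multiplier * (q3 - q1)


def outlier_flags_by_session(
    table: pd.DataFrame, measure: str, iqr_multiplier: float = 1.5
) -> pd.Series:
    """Participant-level outlier flags for one measure.

    A participant flagged at *either* session is excluded from that
    measure's analyses at both sessions. Returns a boolean Series indexed
    by participant.
    """
    flagged: set = set()
    for _, sub in table.dropna(subset=[measure]).groupby("session"):
        flags = mark_outliers(sub[measure].to_numpy(), iqr_multiplier)
        flagged |= set(sub.loc[flags, "participant"])
    participants = table["participant"].unique()
    return pd.Series([p in flagged for p in participants], index=participants)


def paired_t(x, y, label: str = "paired t") -> StatResult:
    """Paired-samples t-test with Cohen's d_z = t / sqrt(n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        if d[0] != 0:
            raise ValueError("zero-variance differences: statistic undefined")
        t, p = 0.0, 1.0  # x identical to y
    else:
        t, p = ss.ttest_rel(x, y)
    return StatResult(
        label=label, statistic=float(t), df=n - 1, p=float(p),
        effect_sizes={"d_z": cohens_dz_from_t(t, n)}, n={"pairs": n},
    )


def independent_t(
    a, b,
    welch_on_heterogeneity: bool = True,
    levene_alpha: float = 0.05,
    levene_center: str = "median",
    label: str = "independent t",
) -> StatResult:
    """Independent-samples t-test with Cohen's d.

    Pooled-variance t by default; if a Levene pre-test (median-centered,
    alpha = ``levene_alpha``) rejects variance homogeneity and
    ``welch_on_heterogeneity`` is set, the Welch t with Satterthwaite df
    is reported instead. Cohen's d always uses the pooled form
    d = t_pooled * sqrt(1/n_a + 1/n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    t_pooled, p_pooled = ss.ttest_ind(a, b, equal_var=True)
    d = cohens_d_from_t(float(t_pooled), na, nb)
    _, p_lev = ss.levene(a, b, center=levene_center)
    welch = welch_on_heterogeneity and p_lev < levene_alpha
    if welch:
        t, p = ss.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    else:
        t, p, df = t_pooled, p_pooled, na + nb - 2
    return StatResult(
        label=label, statistic=float(t), df=float(df), p=float(p),
        effect_sizes={"d": d}, n={"a": na, "b": nb},
        extra={"welch": bool(welch), "levene_p": float(p_lev)},
    )


def mixed_anova_2x2(
    table: pd.DataFrame,
    measure: str,
    group_col: str = "group",
    session_col: str = "session",
    id_col: str = "participant",
) -> dict[str, StatResult]:
    """2 (between: group) x 2 (within: session) mixed-design ANOVA.

    Complete cases only (participants with both sessions). The
    sum-of-squares decomposition is

        SS_total = SS_group + SS_subjects(group)
                 + SS_session + SS_group:session + SS_session:subjects

    with F_group = MS_group / MS_subjects(group) on (1, N-2) df and
    F_session, F_interaction against MS_session:subjects on (1, N-2) df.
    Generalized eta squared divides each effect SS by itself plus *all*
    subject-level error SS (SS_subjects(group) + SS_session:subjects),
    making effect sizes comparable across between- and within-subject
    effects.
    """
    cols = [id_col, group_col, session_col, measure]
    df = table[cols].dropna()
    wide = df.pivot_table(index=[id_col, group_col], columns=session_col,
                          values=measure)
    sessions = sorted(wide.columns)
    if len(sessions) != 2:
        raise ValueError("need exactly two sessions")
    wide = wide.dropna()
    groups = sorted(wide.index.get_level_values(group_col).unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    counts = wide.groupby(level=group_col).size()
    if (counts < 2).any() or counts.size < 2:
        raise ValueError("need >= 2 complete-case participants per group")

    y = wide.to_numpy()  # subjects x 2 sessions
    glab = wide.index.get_level_values(group_col).to_numpy()
    n_sub = y.shape[0]
    m = 2
    grand = y.mean()

    subj_mean = y.mean(axis=1)
    sess_mean = y.mean(axis=0)
    group_mean = {g: y[glab == g].mean() for g in groups}
    cell_mean = {(g, j): y[glab == g, j].mean() for g in groups for j in range(m)}
    ng = {g: int((glab == g).sum()) for g in groups}

    ss_group = sum(ng[g] * m * (group_mean[g] - grand) ** 2 for g in groups)
    ss_subj = m * sum(
        (subj_mean[i] - group_mean[glab[i]]) ** 2 for i in range(n_sub)
    )
    ss_session = n_sub * sum((sess_mean[j] - grand) ** 2 for j in range(m))
    ss_inter = sum(
        ng[g] * (cell_mean[(g, j)] - group_mean[g] - sess_mean[j] + grand) ** 2
        for g in groups for j in range(m)
    )
    resid = np.array([
        [y[i, j] - cell_mean[(glab[i], j)] - subj_mean[i] + group_mean[glab[i]]
         for j in range(m)]
        for i in range(n_sub)
    ])
    ss_err = float((resid**2).sum())

    df_between = n_sub - 2
    df_within = n_sub - 2
    ms_subj = ss_subj / df_between
    ms_err = ss_err / df_within if df_within > 0 else np.nan
    ss_error_all = ss_subj + ss_err

    def eta_g(ss_effect: float) -> float:
        denom = ss_effect + ss_error_all
        return float(ss_effect / denom) if denom > 0 else 0.0

    def result(name, ss_effect, ms_error, dfe) -> StatResult:
        if ms_error == 0:
            f, p = 0.0, 1.0
        else:
            f = ss_effect / ms_error
            p = float(ss.f.sf(f, 1, dfe))
        return StatResult(
            label=f"{measure}: {name}", statistic=float(f), df=(1, dfe), p=p,
            effect_sizes={"generalized_eta_squared": eta_g(ss_effect)},
            n={g: ng[g] for g in groups},
            extra={"ss": {
                "group": ss_group, "subjects_within_group": ss_subj,
                "session": ss_session, "interaction": ss_inter,
                "session_by_subjects": ss_err,
            }},
        )

    return {
        "group": result("group", ss_group, ms_subj, df_between),
        "session": result("session", ss_session, ms_err, df_within),
        "interaction": result("interaction", ss_inter, ms_err, df_within),
    }


def correlation_battery(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = 0.01,
    by_session: bool = True,
) -> list[StatResult]:
    """Pearson correlations for listed column pairs (pooled groups).

    A pair with fewer than 4 pairwise-complete observations or zero
    variance is reported with NaN statistics.
    """
    chunks = table.groupby("session") if by_session else [(None, table)]
    out: list[StatResult] = []
    for sess, sub in chunks:
        for x_col, y_col in pairs:
            d = sub[[x_col, y_col]].dropna()
            label = f"r({x_col}, {y_col})" + (f" s{sess}" if sess else "")
            if len(d) < 4 or d[x_col].std() == 0 or d[y_col].std() == 0:
                out.append(StatResult(label=label, statistic=np.nan,
                                      df=np.nan, p=np.nan,
                                      n={"pairs": len(d)},
                                      extra={"significant": None}))
                continue
            r, p = ss.pearsonr(d[x_col], d[y_col])
            out.append(StatResult(
                label=label, statistic=float(r), df=len(d) - 2, p=float(p),
                effect_sizes={"r": float(r)}, n={"pairs": len(d)},
                extra={"significant": bool(p < alpha), "alpha": alpha},
            ))
    return out


def _two_sample_power(d: float, n1: int, n2: int, alpha: float) -> float:
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = ss.t.isf(alpha / 2, df)
    power = ss.nct.sf(tcrit, df, ncp) + ss.nct.cdf(-tcrit, df, ncp)
    if np.isnan(power):  # extreme noncentrality: power saturates
        return 1.0 if ncp > tcrit else 0.0
    return float(power)


def min_detectable_d(
    n1: int, n2: int, alpha: float = 0.05, power: float = 0.80
) -> float:
    """Smallest Cohen's d a two-sided two-sample t-test detects at the
    requested power (noncentral-t sensitivity analysis)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if not (0 < alpha < 1) or not (alpha < power < 1):
        raise ValueError("require 0 < alpha < power < 1")
    f = lambda d: _two_sample_power(d, n1, n2, alpha) - power
    if f(10.0) < 0:
        raise ValueError("no detectable effect below d = 10")
    return float(optimize.brentq(f, 1e-6, 10.0, xtol=1e-8))


def _interaction_power(
    f_es: float, n_total: int, n_groups: int, m: int, rho: float, alpha: float
) -> float:
    lam = f_es**2 * n_total * m / (1.0 - rho)
    df1 = 1
    df2 = n_total - n_groups
    fcrit = ss.f.isf(alpha, df1, df2)
    return float(ss.ncf.sf(fcrit, df1, df2, lam))


def min_detectable_f(
    n_total: int,
    n_groups: int = 2,
    n_measurements: int = 2,
    rho: float = 0.3,
    alpha: float = 0.05,
    power: float = 0.80,
) -> float:
    """Smallest Cohen's f detectable for the within-between interaction of
    a repeated-measures design.

    Uses the noncentral-F formulation with noncentrality
    lambda = f^2 * N * m / (1 - rho), numerator df 1 and denominator df
    N - n_groups, where m is the number of repeated measurements and rho
    their correlation.
    """
    if n_total <= n_groups:
        raise ValueError("n_total must exceed n_groups")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if not (0 < alpha < 1) or not (alpha < power < 1):
        raise ValueError("require 0 < alpha < power < 1")
    g = lambda f_es: _interaction_power(
        f_es, n_total, n_groups, n_measurements, rho, alpha
    ) - power
    if g(10.0) < 0:
        raise ValueError("no detectable effect below f = 10")
    return float(optimize.brentq(g, 1e-6, 10.0, xtol=1e-8))
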