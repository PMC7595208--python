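"""Dual-luciferase reporter statistics.

A firefly reporter driven by a promoter construct is co-transfected with a
constitutive Renilla control; the firefly/Renilla ratio corrects for
transfection efficiency, and ratios are then scaled to the reference
construct (11 CTG repeats) measured in the same independent experiment, so
every analysis works on dimensionless relative activities with the
reference pinned at 1.

The repeat-length series is analysed as a one-way repeated-measures ANOVA
with the independent experiments as subjects, Greenhouse-Geisser corrected
for sphericity violations, followed by Dunnett's two-sided comparisons of
each repeat length against the 11-repeat control.  Dunnett adjusted
p-values use the equicorrelated multivariate-t distribution (correlation
1/2 for the equal per-condition n of a complete table) with the RM-ANOVA
error term, evaluated by Gauss-Hermite x Gauss-Legendre quadrature to
about 1e-6 absolute accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_reporter",
    "RmAnovaResult",
    "rm_anova_gg",
    "dunnett",
    "reporter_table",
]

_REQUIRED = ("promoter", "repeat_length", "experiment", "firefly", "renilla")


def normalize_reporter(measurements: pd.DataFrame, control: int = 11) -> pd.DataFrame:
    """Firefly/Renilla ratios scaled to the in-experiment control construct.

    ``measurements`` needs columns ``promoter, repeat_length, experiment,
    firefly, renilla`` (signals strictly positive).  Within each
    (promoter, experiment) stratum every ratio is divided by the stratum's
    ``control``-repeat ratio (mean, if measured more than once), so control
    rows come out exactly 1.  A stratum without a control measurement is an
    error naming the stratum.
    """
    missing = [c for c in _REQUIRED if c not in measurements.columns]
    if missing:
        raise ValueError(f"missing measurement columns: {missing}")
    df = measurements.copy()
    if (df["firefly"] <= 0).any() or (df["renilla"] <= 0).any():
        raise ValueError("firefly and renilla signals must be positive")
    df["ratio"] = df["firefly"] / df["renilla"]

    out = []
    for (promoter, experiment), grp in df.groupby(
        ["promoter", "experiment"], sort=False
    ):
        ref = grp.loc[grp["repeat_length"] == control, "ratio"]
        if ref.empty:
            raise ValueError(
                f"no {control}-repeat reference in stratum "
                f"(promoter={promoter!r}, experiment={experiment!r})"
            )
        scaled = grp["ratio"] / ref.mean()
        out.append(
            pd.DataFrame(
                {
                    "promoter": promoter,
                    "repeat_length": grp["repeat_length"].to_numpy(),
                    "experiment": experiment,
                    "value": scaled.to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def reporter_table(
    activities: pd.DataFrame, promoter: str
) -> pd.DataFrame:
    """Pivot relative activities to a subjects x conditions table for one
    promoter (experiments as rows, repeat lengths as columns)."""
    sub = activities[activities["promoter"] == promoter]
    table = sub.pivot_table(
        index="experiment", columns="repeat_length", values="value",
        aggfunc="mean",
    )
    return table


@dataclass(frozen=True)
class RmAnovaResult:
    F: float
    df_num: float
    df_den: float
    epsilon: float
    p_uncorrected: float
    p_gg: float
    ms_error: float
    df_error: int


def rm_anova_gg(table: pd.DataFrame) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``table`` is complete, subjects (independent experiments) x conditions
    (repeat lengths).  Epsilon comes from the double-centred sample
    covariance of the conditions; the corrected p evaluates F on
    ``(k-1)*eps, (n-1)*(k-1)*eps`` degrees of freedom.  With k = 2
    conditions sphericity is automatic and epsilon is exactly 1.
    """
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("incomplete subjects x conditions table (no imputation)")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")

    grand = X.mean()
    subj_means = X.mean(axis=1)
    cond_means = X.mean(axis=0)
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_error = max(ss_total - ss_cond - ss_subj, 0.0)

    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_error = ss_error / df2

    if ms_error == 0.0:
        F = 0.0 if ss_cond == 0.0 else float("inf")
    else:
        F = ms_cond / ms_error

    # Greenhouse-Geisser epsilon from the double-centred covariance matrix
    if k == 2:
        eps = 1.0
    else:
        S = np.cov(X, rowvar=False, ddof=1)
        C = np.eye(k) - np.full((k, k), 1.0 / k)
        Sc = C @ S @ C
        denom = (k - 1) * float((Sc * Sc).sum())
        eps = 1.0 if denom == 0.0 else float(np.trace(Sc)) ** 2 / denom
        eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    if np.isinf(F):
        p_unc = p_gg = 0.0
    else:
        p_unc = float(stats.f.sf(F, df1, df2))
        p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))
    return RmAnovaResult(
        F=float(F),
        df_num=df1 * eps,
        df_den=df2 * eps,
        epsilon=eps,
        p_uncorrected=p_unc,
        p_gg=p_gg,
        ms_error=ms_error,
        df_error=df2,
    )


def _prob_max_abs_lt(
    q: float, m: int, df: int, rho: float = 0.5, n_z: int = 64, n_s: int = 96
) -> float:
    """P(max_i |T_i| <= q) for m equicorrelated t variates sharing one
    chi-based denominator (Dunnett's two-sided probability)."""
    if q <= 0:
        return 0.0
    # shared-normal factor: Gauss-Hermite with z = sqrt(2) x
    xh, wh = np.polynomial.hermite.hermgauss(n_z)
    z = np.sqrt(2.0) * xh
    wz = wh / np.sqrt(np.pi)
    # chi factor: s = chi_df / sqrt(df) via probability transform
    xl, wl = np.polynomial.legendre.leggauss(n_s)
    u = 0.5 * (xl + 1.0)
    wu = 0.5 * wl
    s = np.sqrt(stats.chi2.ppf(u, df) / df)

    a = np.sqrt(rho)
    b = np.sqrt(1.0 - rho)
    qs = q * s[:, None]  # (n_s, 1)
    upper = (qs - a * z[None, :]) / b
    lower = (-qs - a * z[None, :]) / b
    inner = stats.norm.cdf(upper) - stats.norm.cdf(lower)
    inner = np.clip(inner, 0.0, 1.0) ** m
    return float(wu @ inner @ wz)


def dunnett(table: pd.DataFrame, control: int = 11) -> pd.DataFrame:
    """Two-sided Dunnett comparisons of each condition against the control.

    Uses the RM-ANOVA pooled error (``ms_error`` on ``(n-1)(k-1)`` df) of
    the complete subjects x conditions ``table``.  Returns one row per
    non-control condition with the mean difference, t statistic, unadjusted
    p and Dunnett-adjusted p.  With a single comparison the adjusted and
    unadjusted p coincide.
    """
    if control not in table.columns:
        raise ValueError(f"control condition {control!r} missing from table")
    an = rm_anova_gg(table)
    n = len(table)
    conditions = [c for c in table.columns if c != control]
    if not conditions:
        raise ValueError("need at least one non-control condition")
    m = len(conditions)

    ctrl_mean = float(table[control].mean())
    se = np.sqrt(2.0 * an.ms_error / n)
    rows = []
    for cond in conditions:
        diff = float(table[cond].mean()) - ctrl_mean
        if se == 0.0:
            t_stat = np.inf if diff != 0 else 0.0
            p_unadj = 0.0 if diff != 0 else 1.0
            p_adj = p_unadj
        else:
            t_stat = diff / se
            p_unadj = float(2.0 * stats.t.sf(abs(t_stat), an.df_error))
            if m == 1:  # a single comparison needs no adjustment
                p_adj = p_unadj
            else:
                p_adj = 1.0 - _prob_max_abs_lt(abs(t_stat), m, an.df_error)
                p_adj = float(np.clip(p_adj, p_unadj, 1.0))
        rows.append(
            {
                "condition": cond,
                "diff": diff,
                "t": float(t_stat),
                "p_unadjusted": p_unadj,
                "p_adjusted": p_adj,
            }
        )
    return pd.DataFrame(rows).set_index("condition")
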