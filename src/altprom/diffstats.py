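"""Two-tier differential usage statistics for a two-cohort, two-study design.

Tier one compares disease vs control within each study (experiment) with a
two-sided Mann-Whitney U test, Benjamini-Hochberg corrected across the
members of a test family (the rows plotted together in one figure panel).
Tier two pools both studies and fits, per row, a Gamma GLM on the shifted
normalized values

    y + 0.01 ~ Experiment + Disease + Experiment:Disease

and reports a Wald test of the Disease main effect (the disease contrast at
the reference experiment level, reference = alphabetically first), again
BH-corrected within the family.  The 0.01 shift keeps zeros inside the
Gamma support and is applied immediately before GLM fitting only; the
Mann-Whitney tier uses the unshifted values.

Wald p-values use the Student-t reference distribution with the model's
residual degrees of freedom and the Pearson-estimated dispersion, matching
the finite-sample behaviour of standard GLM summaries at these sample sizes
(6-9 per group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestFamily",
    "GammaGlmFit",
    "mann_whitney",
    "bh_fdr",
    "within_experiment",
    "gamma_glm_disease",
    "combined_analysis",
]

#: Largest per-group size at which the exact Mann-Whitney null distribution
#: is used (ties force the tie-corrected normal approximation).
EXACT_MWU_MAX_N = 8


@dataclass(frozen=True)
class TestFamily:
    """A set of rows corrected together (one multiple-testing family)."""

    family_id: str
    members: tuple[str, ...]

    def __init__(self, family_id: str, members: Sequence[str]):
        members = tuple(members)
        if len(set(members)) != len(members):
            raise ValueError(f"family {family_id!r} has duplicate members")
        object.__setattr__(self, "family_id", family_id)
        object.__setattr__(self, "members", members)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` with U computed for group ``x``.  The exact null
    distribution is used when ``min(n) <= 8`` and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact" if (min(x.size, y.size) <= EXACT_MWU_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_levels(meta: pd.DataFrame) -> tuple[str, str]:
    levels = sorted(meta["disease"].unique())
    if len(levels) != 2:
        raise ValueError(
            f"exactly two disease levels required, got {levels}"
        )
    return levels[0], levels[1]


def _direction(ctrl_values: np.ndarray, case_values: np.ndarray) -> str:
    mc = float(np.median(ctrl_values))
    mf = float(np.median(case_values))
    if mf > mc:
        return "up"
    if mf < mc:
        return "down"
    return "flat"


def _check_members(matrix: pd.DataFrame, family: TestFamily) -> None:
    missing = [m for m in family.members if m not in matrix.index]
    if missing:
        raise KeyError(
            f"family {family.family_id!r} member(s) missing from matrix: {missing}"
        )


def within_experiment(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    family: TestFamily,
) -> pd.DataFrame:
    """Per-experiment Mann-Whitney tests with family-wise BH correction.

    ``matrix`` is rows x samples of normalized values; ``meta`` is indexed by
    sample id with ``experiment`` and ``disease`` columns covering every
    matrix column.  Within each experiment, every family member is tested
    control vs disease and BH-corrected across the family's members.
    """
    _check_members(matrix, family)
    missing_meta = [s for s in matrix.columns if s not in meta.index]
    if missing_meta:
        raise ValueError(f"samples missing from metadata: {missing_meta}")
    meta = meta.loc[list(matrix.columns)]
    ctrl_level, case_level = _group_levels(meta)

    out_rows = []
    for exp in dict.fromkeys(meta["experiment"]):
        sub = meta[meta["experiment"] == exp]
        ctrl_ids = list(sub.index[sub["disease"] == ctrl_level])
        case_ids = list(sub.index[sub["disease"] == case_level])
        if not ctrl_ids or not case_ids:
            raise ValueError(
                f"experiment {exp!r} lacks one of the disease groups"
            )
        pvals = []
        for member in family.members:
            x = matrix.loc[member, ctrl_ids].to_numpy(dtype=float)
            y = matrix.loc[member, case_ids].to_numpy(dtype=float)
            u, p = mann_whitney(x, y)
            pvals.append(p)
            out_rows.append(
                {
                    "family": family.family_id,
                    "row_id": member,
                    "experiment": exp,
                    "n_ctrl": len(ctrl_ids),
                    "n_case": len(case_ids),
                    "U": u,
                    "p": p,
                    "direction": _direction(x, y),
                }
            )
        qvals = bh_fdr(pvals)
        for i in range(len(family.members)):
            out_rows[len(out_rows) - len(family.members) + i]["q"] = qvals[i]

    out = pd.DataFrame(out_rows)
    cols = [
        "family", "row_id", "experiment", "n_ctrl", "n_case",
        "U", "p", "q", "direction",
    ]
    return out[cols]


@dataclass(frozen=True)
class GammaGlmFit:
    """Disease-effect estimate from the pooled Gamma GLM."""

    disease_coef: float
    wald_p: float
    converged: bool
    df_resid: float = float("nan")


_LINKS = {
    "inverse": sm.families.links.InversePower,
    "log": sm.families.links.Log,
}


def gamma_glm_disease(
    values: pd.Series,
    meta: pd.DataFrame,
    link: str = "inverse",
    shift: float = 0.01,
    joint: bool = False,
) -> GammaGlmFit:
    """Gamma GLM disease test pooling both experiments.

    Fits ``values + shift ~ Experiment + Disease + Experiment:Disease``
    (treatment coding, alphabetically first levels as reference) with a
    Gamma family and the requested link, and returns the Disease main-effect
    coefficient with its two-sided Wald p (t reference, residual df).  With
    ``joint=True`` the Wald test covers the Disease main effect and all
    Disease interactions jointly (F test) and the returned coefficient is
    still the main effect.

    Non-convergence yields a flagged result with NaN p rather than an
    exception; a degenerate design (an empty experiment x disease cell, or a
    single experiment or disease level) raises ``ValueError``.
    """
    if link not in _LINKS:
        raise ValueError(f"unknown link {link!r}; expected one of {list(_LINKS)}")
    sub = meta.loc[list(values.index)]
    exps = sorted(sub["experiment"].unique())
    ctrl_level, case_level = _group_levels(sub)
    if len(exps) < 2:
        raise ValueError("combined model requires at least two experiments")
    cells = sub.groupby(["experiment", "disease"], observed=True).size()
    if len(cells) != 2 * len(exps):
        raise ValueError("degenerate design: empty experiment x disease cell")

    y = values.to_numpy(dtype=float) + shift
    if (y <= 0).any():
        raise ValueError(f"values must exceed -{shift} so shifted values are positive")

    # constant response: no information about any effect
    if np.allclose(y, y[0]):
        return GammaGlmFit(0.0, 1.0, True, float(len(y) - 2 * len(exps)))

    disease = (sub["disease"] == case_level).to_numpy(dtype=float)
    cols = {"const": np.ones(len(y))}
    for e in exps[1:]:
        cols[f"exp[{e}]"] = (sub["experiment"] == e).to_numpy(dtype=float)
    cols["disease"] = disease
    for e in exps[1:]:
        cols[f"exp[{e}]:disease"] = cols[f"exp[{e}]"] * disease
    X = pd.DataFrame(cols, index=values.index)

    family = sm.families.Gamma(link=_LINKS[link]())
    try:
        # statsmodels warns that the inverse link does not map onto the Gamma
        # domain; with a cell-saturated design the fitted means stay positive
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", sm.tools.sm_exceptions.DomainWarning)
            res = sm.GLM(y, X, family=family).fit()
        coef = float(res.params["disease"])
        if not np.isfinite(coef) or not np.isfinite(res.bse["disease"]):
            return GammaGlmFit(float("nan"), float("nan"), False)
        if joint:
            terms = ["disease"] + [f"exp[{e}]:disease" for e in exps[1:]]
            constraint = np.zeros((len(terms), X.shape[1]))
            for i, t in enumerate(terms):
                constraint[i, X.columns.get_loc(t)] = 1.0
            wt = res.wald_test(constraint, use_f=True, scalar=True)
            p = float(wt.pvalue)
        else:
            tstat = coef / float(res.bse["disease"])
            p = float(2.0 * stats.t.sf(abs(tstat), res.df_resid))
        return GammaGlmFit(coef, p, True, float(res.df_resid))
    except (np.linalg.LinAlgError, ValueError, sm.tools.sm_exceptions.PerfectSeparationError):
        return GammaGlmFit(float("nan"), float("nan"), False)


def combined_analysis(
    matrices: Mapping[str, pd.DataFrame],
    meta: pd.DataFrame,
    families: Sequence[TestFamily],
    link: str = "inverse",
    joint: bool = False,
) -> pd.DataFrame:
    """Full two-tier differential table over one or more test families.

    ``matrices`` maps experiment name -> rows x samples normalized matrix
    (disjoint sample sets; at least two experiments).  Per family member the
    within-experiment Mann-Whitney tier and the pooled Gamma GLM tier are
    computed; BH correction is applied per family, within experiment for the
    MWU p's and across members for the Wald p's.  The returned long table
    has one row per (member, experiment) with columns ``family, row_id,
    experiment, n_ctrl, n_case, U, p, q, glm_coef, wald_p, wald_q,
    direction`` where ``direction`` compares pooled group medians.
    """
    if len(matrices) < 2:
        raise ValueError("combined analysis requires at least two experiments")
    sample_lists = [list(m.columns) for m in matrices.values()]
    flat = [s for lst in sample_lists for s in lst]
    if len(set(flat)) != len(flat):
        raise ValueError("experiments must have disjoint sample sets")

    pooled = pd.concat(list(matrices.values()), axis=1, join="inner")
    missing_meta = [s for s in pooled.columns if s not in meta.index]
    if missing_meta:
        raise ValueError(f"samples missing from metadata: {missing_meta}")
    sub_meta = meta.loc[list(pooled.columns)]
    ctrl_level, case_level = _group_levels(sub_meta)
    ctrl_ids = list(sub_meta.index[sub_meta["disease"] == ctrl_level])
    case_ids = list(sub_meta.index[sub_meta["disease"] == case_level])

    pieces = []
    for family in families:
        _check_members(pooled, family)
        mwu = within_experiment(pooled, sub_meta, family)

        glm_rows = {}
        wald_ps = []
        for member in family.members:
            fit = gamma_glm_disease(
                pooled.loc[member], sub_meta, link=link, joint=joint
            )
            x = pooled.loc[member, ctrl_ids].to_numpy(dtype=float)
            y = pooled.loc[member, case_ids].to_numpy(dtype=float)
            glm_rows[member] = {
                "glm_coef": fit.disease_coef,
                "wald_p": fit.wald_p,
                "direction": _direction(x, y),
            }
            wald_ps.append(fit.wald_p)
        finite = np.isfinite(wald_ps)
        wald_q = np.full(len(wald_ps), np.nan)
        if finite.any():
            wald_q[finite] = bh_fdr(np.asarray(wald_ps)[finite])
        for i, member in enumerate(family.members):
            glm_rows[member]["wald_q"] = wald_q[i]

        glm = pd.DataFrame.from_dict(glm_rows, orient="index")
        glm.index.name = "row_id"
        merged = mwu.drop(columns=["direction"]).merge(
            glm.reset_index(), on="row_id", how="left"
        )
        pieces.append(merged)

    out = pd.concat(pieces, ignore_index=True)
    cols = [
        "family", "row_id", "experiment", "n_ctrl", "n_case",
        "U", "p", "q", "glm_coef", "wald_p", "wald_q", "direction",
    ]
    return out[cols]
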