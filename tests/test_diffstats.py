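from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from altprom.diffstats import (
    TestFamily as Family,
    bh_fdr,
    combined_analysis,
    gamma_glm_disease,
    mann_whitney,
    within_experiment,
)


def exact_mwu_p(x, y):
    """Brute-force two-sided Mann-Whitney p: enumerate every assignment of
    the pooled values to the two groups and count |U - n1 n2 / 2| at least
    as extreme as observed."""
    def ustat(a, b):
        return sum(
            (ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b
        )

    pooled = list(x) + list(y)
    n1 = len(x)
    center = n1 * len(y) / 2.0
    dev = abs(ustat(x, y) - center)
    total = extreme = 0
    for idx in combinations(range(len(pooled)), n1):
        chosen = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if abs(ustat(a, b) - center) >= dev - 1e-9:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_groups_no_evidence(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_swap_identity(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(5).tolist(), rng.random(7).tolist()
        u1, p1 = mann_whitney(x, y)
        u2, p2 = mann_whitney(y, x)
        assert u1 + u2 == pytest.approx(len(x) * len(y))
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (6, 6), (6, 8)])
    def test_exact_p_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            x = rng.random(n1).tolist()
            y = rng.random(n2).tolist()
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(exact_mwu_p(x, y), abs=1e-12)


class TestBhFdr:
    def test_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.random(25)
        perm = rng.permutation(25)
        q = bh_fdr(p)
        q_perm = bh_fdr(p[perm])
        assert np.allclose(q[perm], q_perm)


def _meta(n_ctrl_2019=6, n_case_2019=8, n_ctrl_2020=9, n_case_2020=6):
    rows = []
    for exp, n_ctrl, n_case in (
        ("2019", n_ctrl_2019, n_case_2019),
        ("2020", n_ctrl_2020, n_case_2020),
    ):
        rows += [(f"{exp}_C{i}", exp, "CTRL") for i in range(n_ctrl)]
        rows += [(f"{exp}_F{i}", exp, "FECD") for i in range(n_case)]
    return pd.DataFrame(
        rows, columns=["sample_id", "experiment", "disease"]
    ).set_index("sample_id")


def _matrix(meta, values_by_row):
    return pd.DataFrame(values_by_row, index=meta.index).T


class TestWithinExperiment:
    def test_family_of_one_q_equals_p(self):
        meta = _meta()
        rng = np.random.default_rng(3)
        matrix = _matrix(meta, {"e1": rng.random(len(meta))})
        res = within_experiment(matrix, meta, Family("f", ["e1"]))
        assert np.allclose(res["q"], res["p"])

    def test_identical_groups_flat_direction(self):
        meta = _meta()
        matrix = _matrix(meta, {"e1": np.ones(len(meta))})
        res = within_experiment(matrix, meta, Family("f", ["e1"]))
        assert (res["direction"] == "flat").all()

    def test_full_separation_exact_p(self):
        # all disease values below all control values at n = (6, 8)
        meta = _meta()
        values = np.where(meta["disease"] == "CTRL", 10.0, 1.0)
        values = values + np.arange(len(meta)) * 1e-6  # break ties
        matrix = _matrix(meta, {"e1": values})
        res = within_experiment(matrix, meta, Family("f", ["e1"]))
        row = res[res["experiment"] == "2019"].iloc[0]
        assert row["U"] == pytest.approx(6 * 8)  # U for the control group
        assert row["p"] == pytest.approx(2 / comb(14, 6))
        assert row["direction"] == "down"

    def test_missing_member_named(self):
        meta = _meta()
        matrix = _matrix(meta, {"e1": np.ones(len(meta))})
        with pytest.raises(KeyError, match="ghost"):
            within_experiment(matrix, meta, Family("f", ["e1", "ghost"]))


class TestGammaGlm:
    def test_constant_values_no_effect(self):
        meta = _meta()
        values = pd.Series(2.0, index=meta.index)
        fit = gamma_glm_disease(values, meta)
        assert fit.disease_coef == pytest.approx(0.0)
        assert fit.wald_p >= 0.99

    def test_order_preserving_relabel_invariance(self):
        meta = _meta()
        rng = np.random.default_rng(4)
        values = pd.Series(rng.gamma(5.0, 2.0, len(meta)), index=meta.index)
        fit = gamma_glm_disease(values, meta)
        renamed = meta.assign(
            experiment=meta["experiment"].map({"2019": "expA", "2020": "expB"})
        )
        fit2 = gamma_glm_disease(values, renamed)
        assert fit.disease_coef == pytest.approx(fit2.disease_coef)
        assert fit.wald_p == pytest.approx(fit2.wald_p)

    def test_joint_test_invariant_under_experiment_swap(self):
        # the joint Wald test of disease plus interactions does not depend
        # on which experiment is the reference level
        meta = _meta()
        rng = np.random.default_rng(5)
        values = pd.Series(rng.gamma(5.0, 2.0, len(meta)), index=meta.index)
        swapped = meta.assign(
            experiment=meta["experiment"].map({"2019": "2020", "2020": "2019"})
        )
        p1 = gamma_glm_disease(values, meta, joint=True).wald_p
        p2 = gamma_glm_disease(values, swapped, joint=True).wald_p
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_strong_effect_detected(self):
        meta = _meta()
        rng = np.random.default_rng(6)
        mean = np.where(meta["disease"] == "FECD", 40.0, 10.0)
        values = pd.Series(rng.gamma(10.0, mean / 10.0), index=meta.index)
        fit = gamma_glm_disease(values, meta)
        assert fit.converged
        assert fit.wald_p < 0.01

    def test_negative_shifted_values_rejected(self):
        meta = _meta()
        values = pd.Series(-1.0, index=meta.index)
        with pytest.raises(ValueError):
            gamma_glm_disease(values, meta)

    def test_single_experiment_rejected(self):
        meta = _meta()
        sub = meta[meta["experiment"] == "2019"]
        values = pd.Series(1.0, index=sub.index)
        with pytest.raises(ValueError):
            gamma_glm_disease(values, sub)

    def test_log_link_available(self):
        meta = _meta()
        rng = np.random.default_rng(7)
        values = pd.Series(rng.gamma(5.0, 2.0, len(meta)), index=meta.index)
        fit = gamma_glm_disease(values, meta, link="log")
        assert fit.converged
        assert 0.0 <= fit.wald_p <= 1.0


class TestCombinedAnalysis:
    def test_single_experiment_rejected(self):
        meta = _meta()
        matrix = _matrix(meta, {"e1": np.ones(len(meta))})
        sub = matrix[[c for c in matrix.columns if c.startswith("2019")]]
        with pytest.raises(ValueError, match="two experiments"):
            combined_analysis({"2019": sub}, meta, [Family("f", ["e1"])])

    def test_overlapping_samples_rejected(self):
        meta = _meta()
        matrix = _matrix(meta, {"e1": np.ones(len(meta))})
        with pytest.raises(ValueError, match="disjoint"):
            combined_analysis(
                {"a": matrix, "b": matrix}, meta, [Family("f", ["e1"])]
            )

    def test_output_shape_and_columns(self):
        meta = _meta()
        rng = np.random.default_rng(8)
        rows = {f"e{i}": rng.gamma(5.0, 2.0, len(meta)) for i in range(4)}
        matrix = _matrix(meta, rows)
        mats = {
            exp: matrix[[c for c in matrix.columns if c.startswith(exp)]]
            for exp in ("2019", "2020")
        }
        res = combined_analysis(
            mats, meta, [Family("f", list(rows))]
        )
        assert len(res) == 4 * 2  # member x experiment
        assert set(res.columns) >= {
            "row_id", "experiment", "n_ctrl", "n_case",
            "U", "p", "q", "glm_coef", "wald_p", "wald_q", "direction",
        }
        # GLM columns identical across experiments of one member
        g = res.groupby("row_id")["wald_p"].nunique()
        assert (g == 1).all()
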