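"""Histomorphometry, qPCR relative expression, paired tests, and AST logic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from osteoadapt.adaptation import (
    AdaptationOutcome,
    DynamicLabels,
    delta_ct,
    histomorphometry_indices,
    identify_ast,
    mann_whitney_u,
    outcomes_from_table,
    paired_t,
    synthetic_outcome_table,
    wilcoxon_signed_rank,
)
from osteoadapt.strainstats import summary_from_values


class TestHistomorphometry:
    def test_fully_double_labelled_surface(self):
        idx = histomorphometry_indices(DynamicLabels(sl_pm=0, dl_pm=100, bs=100, ir_l_wi=6))
        assert idx.ms_bs == 100.0

    def test_mar_from_six_day_interval(self):
        idx = histomorphometry_indices(DynamicLabels(sl_pm=0, dl_pm=50, bs=100, ir_l_wi=6.0))
        assert idx.mar == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        # dL.Pm 30, sL.Pm 20, BS 100 um, MAR 1.2 um/day -> MS/BS 40%, BFR 0.48
        labels = DynamicLabels(sl_pm=20, dl_pm=30, bs=100, ir_l_wi=1.2 * 6, label_interval=6)
        idx = histomorphometry_indices(labels)
        assert idx.ms_bs == pytest.approx(40.0)
        assert idx.mar == pytest.approx(1.2)
        assert idx.bfr_bs == pytest.approx(0.48)
        assert idx.bfr_bs == pytest.approx(idx.mar * idx.ms_bs / 100, rel=1e-9)

    def test_zero_surface_fails(self):
        with pytest.raises(ValueError):
            histomorphometry_indices(DynamicLabels(sl_pm=0, dl_pm=0, bs=0, ir_l_wi=1))

    def test_labelled_perimeter_cannot_exceed_surface(self):
        with pytest.raises(ValueError):
            DynamicLabels(sl_pm=80, dl_pm=30, bs=100, ir_l_wi=1)


class TestDeltaCt:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene", "ct"])

    def test_gene_equal_to_housekeeping_gives_unity(self):
        t = self._table([("s1", "Ager", 20.0), ("s1", "Sost", 20.0)])
        out = delta_ct(t)
        assert out["rel_expr"].iloc[0] == 1.0

    def test_powers_of_two(self):
        t = self._table([("s1", "Ager", 20.0), ("s1", "Sost", 21.0), ("s1", "Col1A1", 18.0)])
        out = delta_ct(t).set_index("gene")["rel_expr"]
        assert out["Sost"] == 0.5  # dCt = +1
        assert out["Col1A1"] == 4.0  # dCt = -2

    def test_fold_change_from_ddct(self):
        # ddCt = -1.585 between loaded and control -> fold change 3.0
        t = self._table([
            ("loaded", "Ager", 20.0), ("loaded", "Sost", 20.0),
            ("control", "Ager", 20.0), ("control", "Sost", 21.585),
        ])
        out = delta_ct(t).set_index("sample_id")["rel_expr"]
        assert out["loaded"] / out["control"] == pytest.approx(3.0, rel=1e-3)

    def test_missing_housekeeping_fails(self):
        t = self._table([("s1", "Sost", 20.0)])
        with pytest.raises(ValueError, match="housekeeping"):
            delta_ct(t)


class TestPairedT:
    def test_hand_computed_example(self):
        # differences (1, 2, 3, 4): t = 2.5 / (1.2910/2) = 3.873, p = 0.0305
        t, p = paired_t([1, 2, 3, 4], [0, 0, 0, 0])
        assert t == pytest.approx(3.873, abs=1e-3)
        assert p == pytest.approx(0.0305, abs=1e-4)

    def test_shift_invariance(self):
        x = np.array([1.0, 2.5, 3.0, 4.2, 5.1])
        y = np.array([0.5, 2.0, 3.5, 3.9, 4.0])
        _, p1 = paired_t(x, y)
        _, p2 = paired_t(x + 10, y + 10)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_difference_variance_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t([1, 2, 3], [0, 1, 2])


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        w, p = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6], [0] * 6)
        assert w == 21.0
        assert p == pytest.approx(2 / 64)

    def test_symmetric_under_swapping_limbs(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=7), rng.normal(size=7)
        _, p1 = wilcoxon_signed_rank(x, y)
        _, p2 = wilcoxon_signed_rank(y, x)
        assert p1 == pytest.approx(p2, rel=1e-12)

    @staticmethod
    def _brute_force_p(d):
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = np.array([
            ranks[np.array(signs) > 0].sum()
            for signs in itertools.product([1, -1], repeat=len(d))
        ])
        return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))

    @pytest.mark.parametrize("n", range(3, 11))
    def test_exact_p_equals_sign_enumeration_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        x = rng.normal(0.3, 1, n)
        y = rng.normal(0, 1, n)
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(self._brute_force_p(x - y), abs=1e-12)

    def test_matches_scipy_exact_for_tie_free_data(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0.5, 1, 12), rng.normal(0, 1, 12)
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(stats.wilcoxon(x, y, mode="exact").pvalue, abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(3, 9), st.integers(0, 10_000))
    def test_exact_enumeration_property(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        if np.all(x - y == 0):
            return
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(self._brute_force_p(x - y), abs=1e-12)


def test_mann_whitney_small_groups():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6, 7])
    oracle = stats.mannwhitneyu([1, 2, 3], [4, 5, 6, 7], alternative="two-sided")
    assert u == oracle.statistic and p == oracle.pvalue


class TestIdentifyAST:
    LOADS = (-3.5, -5.2, -7.0)

    @staticmethod
    def _summaries(voi, peaks):
        return [
            summary_from_values(voi, load, pt, pc, pt / 2, pc / 2)
            for load, (pc, pt) in zip(TestIdentifyAST.LOADS, peaks)
        ]

    @staticmethod
    def _outcomes(voi, responding, measure="Ct.Ar"):
        return [
            AdaptationOutcome(voi=voi, load=l, measure=measure,
                              p_value=0.01 if l in responding else 0.5)
            for l in TestIdentifyAST.LOADS
        ]

    def test_cortical_responds_at_all_loads(self):
        # low-load midshaft peaks (-1469, 1294) become the AST, upper-bound
        s = self._summaries("cort", [(-1469, 1294), (-2183, 1923), (-2939, 2588)])
        o = self._outcomes("cort", self.LOADS)
        rep = identify_ast(s, o, "cort", "Ct.Ar")
        assert rep.ast_compressive == -1469 and rep.ast_tensile == 1294
        assert rep.identified_at_load == -3.5
        assert rep.upper_bound and not rep.exceeds_max_tested

    def test_cancellous_responds_only_at_high_load(self):
        s = self._summaries("canc", [(-1322, 852), (-1964, 1266), (-2644, 1705)])
        o = self._outcomes("canc", (-7.0,), measure="BV/TV")
        rep = identify_ast(s, o, "canc", "BV/TV")
        assert rep.ast_compressive == -2644 and rep.ast_tensile == 1705
        assert rep.identified_at_load == -7.0

    def test_no_response_reports_bounds_only(self):
        s = self._summaries("canc", [(-100, 80), (-150, 120), (-200, 160)])
        o = self._outcomes("canc", ())
        rep = identify_ast(s, o, "canc", "Ct.Ar")
        assert rep.ast_compressive is None and rep.ast_tensile is None
        assert rep.exceeds_max_tested
        assert rep.per_load[-1][2:] == (-200, 160)  # highest load peaks as lower bound

    def test_non_monotone_pattern_flagged(self):
        s = self._summaries("v", [(-1, 1), (-2, 2), (-3, 3)])
        o = self._outcomes("v", (-3.5, -7.0))  # responds low and high, not medium
        rep = identify_ast(s, o, "v", "Ct.Ar")
        assert rep.non_monotone

    def test_mismatched_load_sets_fail(self):
        s = self._summaries("v", [(-1, 1), (-2, 2), (-3, 3)])[:2]
        o = self._outcomes("v", (-7.0,))
        with pytest.raises(ValueError, match="load sets"):
            identify_ast(s, o, "v", "Ct.Ar")

    def test_ast_strains_come_from_stored_summaries(self):
        s = self._summaries("v", [(-111, 99), (-222, 198), (-333, 297)])
        o = self._outcomes("v", (-5.2, -7.0))
        rep = identify_ast(s, o, "v", "Ct.Ar")
        stored = {(r[2], r[3]) for r in rep.per_load}
        assert (rep.ast_compressive, rep.ast_tensile) in stored


class TestOutcomesFromTable:
    def test_synthetic_table_reproduces_designated_responders(self):
        table = synthetic_outcome_table(
            responding={"midshaft_cortical": (-3.5, -5.2, -7.0),
                        "proximal_cancellous": (-7.0,)},
            measures={"midshaft_cortical": "Ct.Ar", "proximal_cancellous": "BV/TV"},
            seed=1,
        )
        outcomes = outcomes_from_table(table)
        by = {(o.voi, o.load): o.responded for o in outcomes}
        assert by[("midshaft_cortical", -3.5)]
        assert by[("midshaft_cortical", -7.0)]
        assert not by[("proximal_cancellous", -3.5)]
        assert not by[("proximal_cancellous", -5.2)]
        assert by[("proximal_cancellous", -7.0)]

    def test_responded_iff_p_below_alpha(self):
        o = AdaptationOutcome(voi="v", load=-3.5, measure="m", p_value=0.049)
        assert o.responded
        o2 = AdaptationOutcome(voi="v", load=-3.5, measure="m", p_value=0.051)
        assert not o2.responded
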