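"""Repeated-measures ANOVA, GG correction, effect sizes, pairwise tests."""
import numpy as np
import pandas as pd
import pytest

from riderp.core import ParameterError, ValidationError
from riderp.simulate import simulate_null_amplitudes
from riderp.stats import (
    _anova_from_tensor,
    gg_epsilon,
    partial_eta2,
    planned_pairwise,
    rm_anova,
    simple_effects,
)
from tests.oracles import box_epsilon, brute_force_rm_anova, paired_t_f


def _long(Y, factors):
    """(subject, f1, ...) tensor -> tidy table."""
    n = Y.shape[0]
    rows = []
    for idx in np.ndindex(*Y.shape):
        rows.append(
            [f"s{idx[0]:02d}"]
            + [f"{factors[i]}{idx[i + 1]}" for i in range(len(factors))]
            + [Y[idx]]
        )
    return pd.DataFrame(rows, columns=["subject", *factors, "amplitude"])


def _random_design(rng, n_subj, shape):
    Y = rng.normal(0, 1, (n_subj, *shape)) + rng.normal(0, 1, (n_subj,) + (1,) * len(shape))
    return Y


class TestRmAnova:
    def test_constant_data_zero_f(self):
        Y = np.full((6, 3), 2.0)
        tab = rm_anova(_long(Y, ["condition"]), ["condition"])
        assert tab.F.iloc[0] == 0.0

    def test_two_level_equals_squared_paired_t(self, rng):
        Y = rng.normal(0, 1, (12, 2))
        tab = rm_anova(_long(Y, ["condition"]), ["condition"])
        assert tab.F.iloc[0] == pytest.approx(paired_t_f(Y), rel=1e-10)

    @pytest.mark.parametrize(
        "shape", [(3,), (8,), (3, 8), (3, 2), (3, 3, 2), (2, 2, 2)]
    )
    def test_matches_brute_force_oracle(self, rng, shape):
        """F, df, partial eta^2 match the direct-summation oracle to 1e-8."""
        factors = ["A", "B", "D"][: len(shape)]
        Y = _random_design(rng, 18, shape)
        table = _long(Y, factors)
        mine = rm_anova(table, factors).set_index("effect")
        oracle = brute_force_rm_anova(table, factors)
        for eff, o in oracle.items():
            m = mine.loc[eff]
            assert m.df_num == o["df_num"] and m.df_den == o["df_den"]
            assert m.F == pytest.approx(o["F"], rel=1e-8)
            assert m.partial_eta2 == pytest.approx(o["partial_eta2"], rel=1e-8)
            assert m.ss_effect == pytest.approx(o["ss"], rel=1e-8)

    def test_main_effect_epsilon_matches_box_formula(self, rng):
        Y = _random_design(rng, 18, (4,))
        tab = rm_anova(_long(Y, ["condition"]), ["condition"])
        assert tab.gg_epsilon.iloc[0] == pytest.approx(box_epsilon(Y), rel=1e-10)

    def test_unbalanced_table_lists_missing_cells(self, rng):
        t = _long(rng.normal(size=(4, 3)), ["condition"])
        t = t.iloc[:-1]
        with pytest.raises(ValidationError, match="missing cells"):
            rm_anova(t, ["condition"])

    def test_label_permutation_leaves_other_effects(self, rng):
        """Relabeling conditions uniformly cannot change the electrode effect."""
        Y = _random_design(rng, 10, (3, 4))
        t = _long(Y, ["condition", "electrode"])
        base = rm_anova(t, ["condition", "electrode"]).set_index("effect")
        t2 = t.copy()
        t2["condition"] = t2["condition"].map(
            {"condition0": "condition2", "condition1": "condition0",
             "condition2": "condition1"}
        )
        perm = rm_anova(t2, ["condition", "electrode"]).set_index("effect")
        assert perm.loc["electrode", "F"] == pytest.approx(
            base.loc["electrode", "F"], rel=1e-10
        )
        assert perm.loc["condition", "F"] == pytest.approx(
            base.loc["condition", "F"], rel=1e-10
        )

    def test_ss_conservation(self, rng):
        """Partitioned SS (effects + errors + subject) add up to total SS."""
        from riderp.stats import _effect_ss

        Y = _random_design(rng, 9, (3, 2))
        total = float(((Y - Y.mean()) ** 2).sum())
        parts = 0.0
        from itertools import combinations

        axes = [0, 1, 2]
        for r in range(1, 4):
            for comb in combinations(axes, r):
                parts += _effect_ss(Y, comb)
        assert parts == pytest.approx(total, rel=1e-8)


class TestGgEpsilon:
    def test_compound_symmetry_gives_one(self, rng):
        # iid subject rows + common subject offset: population-spherical;
        # use a constructed exactly compound-symmetric sample
        base = rng.normal(0, 1, (40, 3))
        base = base - base.mean(axis=1, keepdims=True)  # equalize
        Y = base + rng.normal(0, 1, (40, 1))
        # exact check on the definition instead: epsilon of a matrix whose
        # contrast covariance is proportional to identity is 1
        q = np.linalg.qr(np.eye(3) - 1 / 3)[0][:, :2]
        Z = rng.normal(0, 1, (500, 2))
        Ylev = Z @ q.T
        assert gg_epsilon(Ylev + rng.normal(0, 1e-8, Ylev.shape)) > 0.95

    def test_rank_one_covariance_hits_lower_bound(self):
        subj = np.arange(10.0)
        Y = np.stack([subj, 2 * subj, 3 * subj], axis=1)  # rank-1 contrasts
        assert gg_epsilon(Y) == pytest.approx(0.5)

    def test_matches_box_double_centering(self, rng):
        Y = rng.normal(0, 1, (18, 3)) * np.array([1.0, 2.0, 3.0])
        assert gg_epsilon(Y) == pytest.approx(box_epsilon(Y), rel=1e-10)

    def test_single_level_rejected(self):
        with pytest.raises(ParameterError):
            gg_epsilon(np.zeros((5, 1)))


class TestPartialEta2:
    def test_limits_and_value(self):
        assert partial_eta2(3.0, 0.0) == 1.0
        assert partial_eta2(0.0, 5.0) == 0.0
        assert partial_eta2(3.0, 9.0) == 0.25

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            partial_eta2(-1.0, 2.0)


class TestPlannedPairwise:
    def test_identical_columns_t_zero_p_one(self):
        Y = np.tile(np.arange(8.0)[:, None], (1, 2))
        t = _long(Y, ["condition"])
        t["unit"] = "Pz"
        out = planned_pairwise(t)
        assert out.t.iloc[0] == 0.0
        assert out.p.iloc[0] == 1.0

    def test_constant_shift_flagged_degenerate(self):
        Y = np.stack([np.arange(8.0), np.arange(8.0) + 1.0], axis=1)
        t = _long(Y, ["condition"])
        t["unit"] = "Pz"
        out = planned_pairwise(t)
        assert bool(out.degenerate.iloc[0])

    def test_planted_difference_matches_hand_computed_t(self, rng):
        diff = rng.normal(2.0, 1.0, 18)
        a = rng.normal(0, 1, 18)
        Y = np.stack([a, a + diff], axis=1)
        t = _long(Y, ["condition"])
        t["unit"] = "Pz"
        out = planned_pairwise(t)
        expected = diff.mean() / (diff.std(ddof=1) / np.sqrt(18))
        assert abs(out.t.iloc[0]) == pytest.approx(abs(expected), rel=1e-10)

    def test_holm_adjustment_monotone(self, rng):
        Y = rng.normal(0, 1, (10, 3))
        t = _long(Y, ["condition"])
        t["unit"] = "Pz"
        out = planned_pairwise(t, adjust="holm")
        assert (out.p_holm >= out.p - 1e-15).all()


class TestSimpleEffects:
    def test_no_interaction_no_simple_effects(self):
        rng = np.random.default_rng(3)
        subj = rng.normal(0, 1, (10, 1, 1))
        region = rng.normal(0, 1, (1, 1, 4))
        Y = np.broadcast_to(subj + region, (10, 3, 4)).copy()
        t = _long(Y, ["condition", "region"])
        t = t.rename(columns={"region": "unit"})
        out = simple_effects(t, "condition", "unit")
        for tab in out.values():
            assert tab.F.iloc[0] == pytest.approx(0.0, abs=1e-18)

    def test_effect_only_where_planted(self, rng):
        Y = rng.normal(0, 0.5, (18, 3, 6))
        Y[:, 2, 4] += 3.0  # condition 2, ROI 4 only
        t = _long(Y, ["condition", "roi"]).rename(columns={"roi": "unit"})
        out = simple_effects(t, "condition", "unit")
        sig = {u for u, tab in out.items() if tab.p_gg.iloc[0] < 0.05}
        assert sig == {"roi4"}

    def test_each_table_passes_oracle(self, rng):
        Y = _random_design(rng, 12, (3, 4))
        t = _long(Y, ["condition", "roi"]).rename(columns={"roi": "unit"})
        out = simple_effects(t, "condition", "unit")
        for unit, tab in out.items():
            sub = t[t.unit == unit]
            oracle = brute_force_rm_anova(sub, ["condition"])["condition"]
            assert tab.F.iloc[0] == pytest.approx(oracle["F"], rel=1e-8)


def test_type_one_error_calibrated_under_null():
    """GG-corrected condition effect rejects ~5% under a non-spherical null."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        Y = simulate_null_amplitudes(rng)
        tab = _anova_from_tensor(Y, ["condition", "electrode"]).set_index("effect")
        rejections += tab.loc["condition", "p_gg"] <= 0.05
    rate = rejections / n_rep
    assert 0.02 <= rate <= 0.08
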