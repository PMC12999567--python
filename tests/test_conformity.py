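import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rhizoeval import (
    IndicatorTable,
    StudyDesign,
    anova_tukey_cld,
    composite_score,
    correlation_weights,
    evaluate_conformity,
    membership,
    percent_change,
)
from rhizoeval.conformity import membership_matrix
from rhizoeval.simulate import default_indicator_model, generate_indicators


def make_table(data: dict, directions: dict | None = None, reps=None) -> IndicatorTable:
    """Build an indicator table from {indicator: {treatment: [replicates]}}."""
    first = next(iter(data.values()))
    treatments = list(first)
    nrep = reps or len(first[treatments[0]])
    rows = {"treatment": [], "replicate": []}
    rows.update({ind: [] for ind in data})
    for t in treatments:
        for r in range(1, nrep + 1):
            rows["treatment"].append(t)
            rows["replicate"].append(r)
        for ind in data:
            rows[ind].extend(data[ind][t])
    dirs = directions or {ind: "benefit" for ind in data}
    return IndicatorTable(pd.DataFrame(rows), dirs)


class TestPercentChange:
    def test_no_change_is_exactly_zero(self):
        assert percent_change(3.7, 3.7) == 0.0

    def test_rounded_to_one_decimal(self):
        assert percent_change(1.123, 1.0) == 12.3

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)


class TestMembership:
    def test_extremes_map_to_zero_and_one(self):
        vals = pd.Series({"Ctrl": 2.0, "BA": 5.0, "FS": 3.0})
        u = membership(vals, "benefit")
        assert u["Ctrl"] == 0.0 and u["BA"] == 1.0

    def test_cost_direction_reverses(self):
        vals = pd.Series({"Ctrl": 2.0, "BA": 5.0})
        u = membership(vals, "cost")
        assert u["Ctrl"] == 1.0 and u["BA"] == 0.0

    def test_copper_means_hand_value(self):
        vals = pd.Series({"Ctrl": 0.81, "BA": 1.36, "FS": 1.48, "BA-FS": 1.60})
        u = membership(vals, "benefit")
        assert u["BA"] == pytest.approx((1.36 - 0.81) / (1.60 - 0.81), abs=1e-9)
        assert u["BA"] == pytest.approx(0.696, abs=5e-4)

    def test_constant_indicator_maps_to_half(self):
        u = membership(pd.Series({"a": 4.0, "b": 4.0}), "benefit")
        assert (u == 0.5).all()

    @given(st.floats(0.1, 50), st.floats(-20, 20))
    def test_invariant_to_affine_rescaling(self, scale, shift):
        vals = pd.Series({"a": 1.0, "b": 2.5, "c": 4.0})
        u1 = membership(vals, "benefit")
        u2 = membership(vals * scale + shift, "benefit")
        assert np.allclose(u1, u2, atol=1e-9)


class TestCorrelationWeights:
    def test_two_indicators_split_evenly(self):
        rng = np.random.default_rng(0)
        data = {
            "x": {t: rng.normal(5, 1, 3).tolist() for t in ("A", "B")},
            "y": {t: rng.normal(2, 1, 3).tolist() for t in ("A", "B")},
        }
        w = correlation_weights(make_table(data))
        assert w.tolist() == pytest.approx([0.5, 0.5])

    def test_duplicated_indicator_outweighs_noise(self):
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            base = {t: rng.normal(5, 1, 4).tolist() for t in ("A", "B")}
            noise = {t: rng.normal(5, 1, 4).tolist() for t in ("A", "B")}
            tbl = make_table({"x1": base, "x2": base, "z": noise})
            w = correlation_weights(tbl)
            if w["x1"] == pytest.approx(w["x2"]) and w["x1"] > w["z"]:
                wins += 1
        assert wins >= 18

    def test_matches_brute_force_mean_abs_r(self):
        rng = np.random.default_rng(3)
        data = {
            ind: {t: rng.normal(10, 2, 5).tolist() for t in ("A", "B")}
            for ind in ("i1", "i2", "i3")
        }
        tbl = make_table(data)
        w = correlation_weights(tbl)
        x = tbl.values[["i1", "i2", "i3"]].to_numpy().T
        raw = []
        for i in range(3):
            rs = [abs(np.corrcoef(x[i], x[j])[0, 1]) for j in range(3) if j != i]
            raw.append(np.mean(rs))
        expected = np.array(raw) / np.sum(raw)
        assert np.allclose(w.to_numpy(), expected, atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_indicator_named(self):
        data = {
            "flat": {"A": [1.0, 1.0], "B": [1.0, 1.0]},
            "ok": {"A": [1.0, 2.0], "B": [3.0, 4.0]},
        }
        with pytest.raises(ValueError, match="flat"):
            correlation_weights(make_table(data))


class TestCompositeScore:
    def test_equal_weights_average(self):
        u = pd.DataFrame({"i1": [0.0], "i2": [1.0]}, index=["t"])
        w = pd.Series({"i1": 0.5, "i2": 0.5})
        assert composite_score(u, w)["t"] == pytest.approx(0.5)

    def test_all_ones_scores_one_regardless_of_weights(self):
        u = pd.DataFrame({"i1": [1.0], "i2": [1.0], "i3": [1.0]}, index=["t"])
        w = pd.Series({"i1": 0.7, "i2": 0.2, "i3": 0.1})
        assert composite_score(u, w)["t"] == pytest.approx(1.0)

    @given(st.floats(0, 1), st.floats(0.0, 0.9))
    def test_monotone_in_membership(self, u0, bump):
        u = pd.DataFrame({"i1": [u0], "i2": [0.3]}, index=["t"])
        w = pd.Series({"i1": 0.6, "i2": 0.4})
        s0 = composite_score(u, w)["t"]
        u.loc["t", "i1"] = min(1.0, u0 + bump)
        assert composite_score(u, w)["t"] >= s0 - 1e-12

    def test_missing_value_rejected(self):
        u = pd.DataFrame({"i1": [np.nan], "i2": [1.0]}, index=["t"])
        w = pd.Series({"i1": 0.5, "i2": 0.5})
        with pytest.raises(ValueError, match="t"):
            composite_score(u, w)


class TestEvaluateConformity:
    def test_invariants_on_simulated_table(self):
        tbl = generate_indicators(StudyDesign(seed=6), default_indicator_model())
        res = evaluate_conformity(tbl)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert ((res.membership >= 0) & (res.membership <= 1)).all().all()
        assert ((res.scores >= 0) & (res.scores <= 1)).all()
        assert res.improvement_pct["Ctrl"] == 0.0
        # pH carries no direction and must not be scored
        assert "pH" not in res.membership.columns

    def test_best_treatment_scores_one_on_uniform_winner(self):
        data = {
            "i1": {"Ctrl": [1.0, 1.1], "BA-FS": [9.0, 9.1]},
            "i2": {"Ctrl": [2.0, 2.2], "BA-FS": [8.0, 8.2]},
        }
        res = evaluate_conformity(make_table(data))
        assert res.scores["BA-FS"] == pytest.approx(1.0)
        assert res.scores["Ctrl"] == pytest.approx(0.0)


class TestAnovaTukeyCld:
    def test_identical_groups_share_one_letter(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(10, 1, 5).tolist()
        tbl = make_table({"x": {t: vals for t in ("A", "B", "C")}})
        gc = anova_tukey_cld(tbl, "x")
        assert set(gc.letters.values()) == {"a"}

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(2)
        tbl = make_table({"x": {
            "lo": (rng.normal(0, 0.1, 5)).tolist(),
            "hi": (rng.normal(10, 0.1, 5)).tolist(),
        }})
        gc = anova_tukey_cld(tbl, "x")
        assert gc.letters["hi"] == "a" and gc.letters["lo"] == "b"
        assert gc.tukey_p.loc["hi", "lo"] < 0.05

    def test_zero_variance_unequal_means_flagged(self):
        tbl = make_table({"x": {"A": [1.0, 1.0], "B": [2.0, 2.0]}})
        gc = anova_tukey_cld(tbl, "x")
        assert gc.degenerate
        assert gc.letters["B"] == "a" and gc.letters["A"] == "b"

    def test_exchangeable_ca_letter_recovery(self):
        # Monte-Carlo under the configured means/SDs (n=5): at least three
        # distinct letters in the clear majority of seeds, and the lowest
        # treatment (Ctrl) never shares a letter with the highest (BA-FS).
        model = default_indicator_model(include_leaf=False)
        d = StudyDesign(seed=0)
        three_plus, separated = 0, 0
        for s in range(200):
            tbl = generate_indicators(d, model, seed=s)
            gc = anova_tukey_cld(tbl, "exchangeable_Ca")
            if len(set("".join(gc.letters.values()))) >= 3:
                three_plus += 1
            if not set(gc.letters["Ctrl"]) & set(gc.letters["BA-FS"]):
                separated += 1
        assert three_plus > 150
        assert separated == 200

    def test_letters_consistent_with_pairwise_tests(self):
        # significant pairs share no letter; non-significant pairs share one
        for s in range(25):
            rng = np.random.default_rng(s)
            tbl = make_table({"x": {
                t: rng.normal(rng.uniform(0, 4), 1.0, 5).tolist()
                for t in ("A", "B", "C", "D")
            }})
            gc = anova_tukey_cld(tbl, "x")
            overall_ns = gc.p >= gc.alpha
            for a, b in itertools.combinations(gc.letters, 2):
                shared = set(gc.letters[a]) & set(gc.letters[b])
                if overall_ns or gc.tukey_p.loc[a, b] >= gc.alpha:
                    assert shared, (s, a, b)
                else:
                    assert not shared, (s, a, b)
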