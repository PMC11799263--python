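"""Fold activation, one-way ANOVA and Dunnett's many-to-one comparison."""

import numpy as np
import pytest
from scipy import stats

from conftest import anova_oracle, pooled_t_oracle
from crisprascreen.plate_io import WellRecord, build_screen_dataset
from crisprascreen.screening import (
    dunnett_vs_control,
    fold_activation,
    one_way_anova,
    significance_tier,
    well_ratio,
)


# ---------------------------------------------------------------------------
# Well ratio and fold activation

def test_well_ratio_direct():
    assert well_ratio(WellRecord("p", "A01", "c", 100.0, 50.0)) == 2.0
    assert well_ratio(WellRecord("p", "A01", "c", 0.0, 7.0)) == 0.0


def test_well_ratio_guard():
    rec = WellRecord.__new__(WellRecord)  # bypass constructor validation
    object.__setattr__(rec, "plate_id", "p")
    object.__setattr__(rec, "well_id", "A01")
    object.__setattr__(rec, "condition", "c")
    object.__setattr__(rec, "tdtomato_au", 5.0)
    object.__setattr__(rec, "tagbfp_au", 0.0)
    with pytest.raises(ValueError):
        well_ratio(rec)


def _dataset_from_ratios(ratios: dict[str, list[float]]):
    wells, idx = [], 0
    for cond, rs in ratios.items():
        for r in rs:
            wells.append(WellRecord("p1", f"A{idx + 1:02d}", cond, 10.0 * r, 10.0))
            idx += 1
    return build_screen_dataset(wells, "Scr")

def test_fold_activation_hand_case():
    ds = _dataset_from_ratios({"Scr": [1, 1, 1], "g": [2, 2, 2]})
    acts = {a.condition: a for a in fold_activation(ds)}
    assert acts["g"].mean_fold == pytest.approx(2.0)
    assert acts["Scr"].mean_fold == pytest.approx(1.0)


def test_control_mean_fold_exactly_one(screen_dataset):
    acts = {a.condition: a for a in fold_activation(screen_dataset)}
    assert acts["Scr"].mean_fold == pytest.approx(1.0, abs=1e-14)


def test_folds_invariant_under_channel_rescaling(screen_dataset):
    scaled = build_screen_dataset(
        [
            WellRecord(w.plate_id, w.well_id, w.condition, 13.0 * w.tdtomato_au,
                       13.0 * w.tagbfp_au)
            for w in screen_dataset.wells
        ],
        "Scr",
    )
    ref = {a.condition: a.folds for a in fold_activation(screen_dataset)}
    new = {a.condition: a.folds for a in fold_activation(scaled)}
    for cond in ref:
        assert new[cond] == pytest.approx(ref[cond], rel=1e-12)


def test_guides_parsed_from_condition_labels(screen_dataset):
    acts = {a.condition: a for a in fold_activation(screen_dataset)}
    assert acts["Scr"].guides == frozenset()
    assert acts["5"].guides == frozenset({"5"})
    assert acts["1+5"].guides == frozenset({"1", "5"})


def test_sem_is_sample_sd_over_sqrt_n():
    ds = _dataset_from_ratios({"Scr": [1, 1, 1], "g": [1, 2, 3]})
    act = {a.condition: a for a in fold_activation(ds)}["g"]
    folds = np.array(act.folds)
    assert act.sem_fold == pytest.approx(folds.std(ddof=1) / np.sqrt(3), rel=1e-12)


# ---------------------------------------------------------------------------
# One-way ANOVA

def test_anova_hand_computed_small_design():
    res = one_way_anova({"a": [1, 2], "b": [3, 4]})
    assert res.f_stat == pytest.approx(8.0, rel=1e-12)
    assert (res.df_between, res.df_within) == (1, 2)


def test_anova_equal_group_means_give_zero_f():
    res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
    assert res.f_stat == pytest.approx(0.0, abs=1e-14)


def test_anova_29x3_degrees_of_freedom(screen_dataset):
    groups = {a.condition: list(a.folds) for a in fold_activation(screen_dataset)}
    res = one_way_anova(groups)
    assert (res.df_between, res.df_within) == (28, 58)


def test_anova_matches_independent_oracle_on_random_designs():
    rng = np.random.default_rng(42)
    for _ in range(50):
        k = rng.integers(2, 6)
        groups = {
            f"g{i}": rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(2, 5)).tolist()
            for i in range(k)
        }
        mine = one_way_anova(groups)
        f, dfb, dfw, p = anova_oracle(groups)
        assert mine.f_stat == pytest.approx(f, rel=1e-10)
        assert (mine.df_between, mine.df_within) == (dfb, dfw)
        assert mine.p_value == pytest.approx(p, rel=1e-10)


def test_anova_degenerate_inputs():
    with pytest.raises(ValueError):
        one_way_anova({"a": [1.0], "b": [1, 2]})
    with pytest.raises(ValueError):
        one_way_anova({"a": [2.0, 2.0], "b": [2.0, 2.0]})


# ---------------------------------------------------------------------------
# Dunnett

def test_dunnett_k1_reduces_to_pooled_t_test():
    rng = np.random.default_rng(7)
    for _ in range(20):
        ctrl = rng.normal(0, 1, int(rng.integers(3, 8))).tolist()
        trt = rng.normal(0.5, 1, len(ctrl)).tolist()
        (res,) = dunnett_vs_control({"c": ctrl, "t": trt}, "c")
        assert res.adjusted_p == pytest.approx(pooled_t_oracle(ctrl, trt), abs=1e-6)
        assert res.raw_p == pytest.approx(res.adjusted_p, abs=1e-6)


def test_dunnett_adjusted_p_at_least_raw(screen_dataset):
    groups = {a.condition: list(a.folds) for a in fold_activation(screen_dataset)}
    results = dunnett_vs_control(groups, "Scr")
    for r in results:
        assert r.adjusted_p >= r.raw_p - 1e-12
        assert 0.0 <= r.adjusted_p <= 1.0


def test_dunnett_agrees_with_scipy_reference():
    rng = np.random.default_rng(11)
    groups = {f"g{i}": rng.normal(0.3 * i, 1, 4).tolist() for i in range(6)}
    groups["ctrl"] = rng.normal(0, 1, 4).tolist()
    mine = {r.condition: r.adjusted_p for r in dunnett_vs_control(groups, "ctrl")}
    names = [g for g in groups if g != "ctrl"]
    ref = stats.dunnett(*[groups[g] for g in names], control=groups["ctrl"])
    for name, p in zip(names, ref.pvalue):
        assert mine[name] == pytest.approx(p, abs=2e-3)


def test_dunnett_monotone_in_group_mean():
    rng = np.random.default_rng(3)
    base = {f"g{i}": rng.normal(0, 1, 3).tolist() for i in range(5)}
    base["c"] = rng.normal(0, 1, 3).tolist()
    previous = None
    for shift in (0.0, 0.5, 1.0, 2.0):
        groups = {k: list(v) for k, v in base.items()}
        groups["g0"] = [x + shift for x in groups["g0"]]
        res = {r.condition: r for r in dunnett_vs_control(groups, "c")}
        p = res["g0"].adjusted_p
        if previous is not None:
            assert p < previous
        previous = p


def test_dunnett_unequal_n_requires_seed_then_runs():
    groups = {"c": [0.1, 0.2, 0.0], "t1": [1.0, 1.2, 0.9, 1.1], "t2": [0.2, 0.1, 0.3]}
    with pytest.raises(ValueError, match="seed"):
        dunnett_vs_control(groups, "c")
    res = dunnett_vs_control(groups, "c", seed=5)
    again = dunnett_vs_control(groups, "c", seed=5)
    assert [r.adjusted_p for r in res] == [r.adjusted_p for r in again]
    for r in res:
        assert r.adjusted_p >= r.raw_p


def test_dunnett_missing_control_errors():
    with pytest.raises(ValueError, match="control"):
        dunnett_vs_control({"a": [1, 2], "b": [2, 3]}, "Scr")


def test_significance_tiers():
    assert significance_tier(0.3) == "ns"
    assert significance_tier(0.04) == "*"
    assert significance_tier(0.009) == "**"
    assert significance_tier(0.0009) == "***"
    assert significance_tier(5e-5) == "****"
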