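import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mammodensity import validation_stats as vs


# ---------------------------------------------------------------------------
# weighted percentiles and grouping


def test_weighted_percentiles_reduce_to_unweighted_midranks():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=200)
    got = vs.weighted_percentiles(vals)
    expected = 100.0 * (stats.rankdata(vals) - 0.5) / vals.size
    assert np.allclose(got, expected)


def test_weighted_percentiles_two_value_midrank():
    """{10 w=1, 20 w=3}: W(<10)=0, W(=10)=1 -> 12.5; W(<20)=1, W(=20)=3 -> 62.5."""
    got = vs.weighted_percentiles([10.0, 20.0], [1.0, 3.0])
    assert got.tolist() == [12.5, 62.5]


def test_weight_two_equals_duplicated_record():
    vals = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
    w = np.array([2.0, 1.0, 1.0, 1.0, 1.0])
    dup_vals = np.concatenate([[3.0], vals])
    dup = vs.weighted_percentiles(dup_vals)
    assert np.allclose(vs.weighted_percentiles(vals, w), dup[1:])
    assert vs.weighted_percentiles(vals, w)[0] == dup[0]


def test_weighted_percentiles_contract_errors():
    with pytest.raises(ValueError):
        vs.weighted_percentiles([])
    with pytest.raises(ValueError):
        vs.weighted_percentiles([1.0, 2.0], [0.0, 0.0])


def test_assign_group_boundaries():
    assert vs.assign_group(10) == "Q1"
    assert vs.assign_group(20) == "Q2"  # left-closed boundary
    assert vs.assign_group(85) == "D9"
    assert vs.assign_group(95) == "D10"
    assert vs.assign_group(100) == "D10"
    with pytest.raises(ValueError):
        vs.assign_group(101)


def test_group_shares_on_large_weighted_cohort():
    """Uniform percentiles yield 20/20/20/20/10/10 group shares within 1%."""
    rng = np.random.default_rng(1)
    vals = rng.lognormal(10, 0.9, size=40_000)
    w = rng.choice([1.0, 64.5], size=vals.size)
    pct = vs.weighted_percentiles(vals, w)
    groups = vs.assign_group(pct)
    shares = {
        g: np.sum(w[groups == g]) / w.sum() * 100 for g in vs.GROUP_LABELS
    }
    for g, target in zip(vs.GROUP_LABELS, (20, 20, 20, 20, 10, 10)):
        assert abs(shares[g] - target) <= 1.0


# ---------------------------------------------------------------------------
# tumour classification


@pytest.mark.parametrize(
    "size, expected",
    [
        ("microinvasive", ("small", 0.1)),
        (15.0, ("small", 15.0)),
        (15.1, ("large", 15.1)),
        (0.1, ("small", 0.1)),
    ],
)
def test_classify_tumour(size, expected):
    assert vs.classify_tumour(size) == expected


def test_classify_tumour_rejects_nonpositive():
    with pytest.raises(ValueError):
        vs.classify_tumour(0.0)


# ---------------------------------------------------------------------------
# logistic models


def _records_2x2(a, b, c, d):
    """D10: a cases / b controls; Q1: c cases / d controls."""
    rows = []
    for group, outcome, count in [
        ("D10", "interval", a),
        ("D10", "control", b),
        ("Q1", "interval", c),
        ("Q1", "control", d),
    ]:
        rows += [{"density_group": group, "outcome": outcome}] * count
    return pd.DataFrame(rows)


def test_logistic_or_matches_contingency_closed_form():
    """With one binary exposure and no covariates the ML logistic OR is
    ad/bc and its Wald CI the Woolf interval, to 6 significant figures."""
    a, b, c, d = 30, 20, 15, 40
    records = _records_2x2(a, b, c, d)
    tab = vs.fit_outcome_model(records, case_outcomes=("interval",), covariates=())
    or_hat = tab.odds_ratio("D10")
    lo, hi = tab.ci("D10")
    woolf_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    expected = a * d / (b * c)
    assert or_hat == pytest.approx(expected, rel=1e-6)
    assert lo == pytest.approx(expected * math.exp(-z * woolf_se), rel=1e-6)
    assert hi == pytest.approx(expected * math.exp(z * woolf_se), rel=1e-6)


def test_identical_case_control_split_gives_unit_ors():
    rows = []
    for g in vs.GROUP_LABELS:
        rows += [{"density_group": g, "outcome": "interval"}] * 10
        rows += [{"density_group": g, "outcome": "control"}] * 10
    tab = vs.fit_outcome_model(pd.DataFrame(rows), ("interval",), covariates=())
    assert np.allclose(tab.table["odds_ratio"], 1.0, rtol=1e-6)


def test_complete_separation_names_the_empty_cell():
    records = _records_2x2(30, 0, 15, 40)
    with pytest.raises(ValueError, match="D10"):
        vs.fit_outcome_model(records, case_outcomes=("interval",), covariates=())


def test_round_by_density_interaction_term_is_supported():
    rng = np.random.default_rng(2)
    n = 2000
    records = pd.DataFrame(
        {
            "density_group": rng.choice(["Q1", "Q4", "D10"], size=n),
            "screening_round": rng.choice(["first", "subsequent"], size=n),
            "outcome": rng.choice(["interval", "control"], size=n, p=[0.3, 0.7]),
        }
    )
    tab = vs.fit_outcome_model(
        records, ("interval",), covariates=("screening_round",),
        interaction_round=True,
    )
    assert any(":" in p for p in tab.fit.params.index)


# ---------------------------------------------------------------------------
# programme sensitivity


def test_sensitivity_transform_identities():
    assert vs.sensitivity_from_odds(0.25) == pytest.approx(80.0)
    assert vs.sensitivity_from_odds(0.0) == 100.0


def test_sensitivity_is_pure_transform_of_model_odds():
    """predict_sensitivity shares the logistic core: its estimate equals
    100/(1+odds) with odds from the interval-vs-screen-detected fit."""
    rng = np.random.default_rng(3)
    n = 1500
    groups = rng.choice(list(vs.GROUP_LABELS), size=n)
    p_interval = np.where(np.isin(groups, ["D9", "D10"]), 0.45, 0.25)
    outcome = np.where(
        rng.random(n) < p_interval, "interval", "small_screen_detected"
    )
    records = pd.DataFrame({"density_group": groups, "outcome": outcome})
    tab = vs.fit_outcome_model(
        records, case_outcomes=("interval",),
        control_outcomes=("small_screen_detected",), covariates=(),
    )
    intercept = tab.fit.params["const"]
    est = vs.predict_sensitivity(records, {"density_group": "Q1"}, covariates=())
    assert est.sensitivity == pytest.approx(
        vs.sensitivity_from_odds(math.exp(intercept)), abs=1e-10
    )
    assert est.ci_low <= est.sensitivity <= est.ci_high


# ---------------------------------------------------------------------------
# ROC / AUC


def test_roc_auc_trivial_cases():
    auc, _ = vs.roc_auc([10, 11, 12], [1, 2, 3])
    assert auc == 1.0
    auc, _ = vs.roc_auc([5, 5, 5], [5, 5, 5])
    assert auc == 0.5


def test_roc_auc_listed_small_sample():
    """cases {3,5,5} vs controls {1,2,5}: wins 2 + 2.5 + 2.5 of 9 pairs
    (ties count one half) -> 7/9."""
    auc, curve = vs.roc_auc([3, 5, 5], [1, 2, 5])
    assert auc == pytest.approx(7 / 9)
    assert curve["fpr"].iloc[0] == 0.0 and curve["tpr"].iloc[-1] == 1.0
    assert (curve["fpr"].diff().dropna() >= 0).all()


def test_roc_auc_equals_bruteforce_pair_counting():
    rng = np.random.default_rng(4)
    for _ in range(20):
        cases = rng.integers(0, 8, size=rng.integers(2, 12))
        controls = rng.integers(0, 8, size=rng.integers(2, 12))
        auc, _ = vs.roc_auc(cases, controls)
        wins = sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x in cases for y in controls
        )
        assert auc == pytest.approx(wins / (len(cases) * len(controls)))


# ---------------------------------------------------------------------------
# trend and rank tests


def test_trend_tests_on_identical_values():
    out = vs.trend_and_rank_tests([5.0] * 9, ["a", "b", "c"] * 3, ["a", "b", "c"])
    assert out["cuzick_z"] == 0.0
    assert out["kw_h"] == 0.0
    assert out["cuzick_p"] == 1.0


def test_cuzick_matches_hand_computation_on_3x3_toy():
    """Values strictly increasing with group: T=108, E=90, Var=45,
    z = 18/sqrt(45)."""
    values = np.arange(1, 10, dtype=float)
    labels = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
    out = vs.trend_and_rank_tests(values, labels, ["g1", "g2", "g3"])
    assert out["cuzick_z"] == pytest.approx(18 / math.sqrt(45))
    assert out["cuzick_z"] > 0


def test_two_group_kruskal_wallis_equals_squared_ranksum_z():
    rng = np.random.default_rng(5)
    x = rng.integers(0, 10, size=25).astype(float)
    y = rng.integers(2, 12, size=30).astype(float)
    values = np.concatenate([x, y])
    labels = ["x"] * 25 + ["y"] * 30
    out = vs.trend_and_rank_tests(values, labels, ["x", "y"])
    n, m = 25, 30
    ranks = stats.rankdata(values)
    w = ranks[:n].sum()
    e_w = n * (n + m + 1) / 2.0
    _, ties = np.unique(values, return_counts=True)
    tie_corr = 1.0 - np.sum(ties**3 - ties) / ((n + m) ** 3 - (n + m))
    var_w = n * m * (n + m + 1) / 12.0 * tie_corr
    z = (w - e_w) / math.sqrt(var_w)
    assert out["kw_h"] == pytest.approx(z**2)


def test_trend_tests_reject_empty_group():
    with pytest.raises(ValueError, match="zero members"):
        vs.trend_and_rank_tests([1.0, 2.0], ["a", "a"], ["a", "b"])


# ---------------------------------------------------------------------------
# agreement


def test_compare_measures_identical_inputs():
    rng = np.random.default_rng(6)
    a = rng.lognormal(10, 0.9, 500)
    rep = vs.compare_measures(a, a.copy())
    assert rep.pearson_r == pytest.approx(1.0)
    assert rep.ba_mean_diff == 0.0
    assert rep.perfect_agreement_pct == pytest.approx(100.0)
    assert rep.within_one_pct == pytest.approx(100.0)


def test_compare_measures_independent_null_agreement():
    """Independent measures: r ~ 0 and perfect agreement ~ sum of squared
    group shares = 4*0.2^2 + 2*0.1^2 = 18%."""
    rng = np.random.default_rng(7)
    n = 20_000
    a = rng.lognormal(10, 0.9, n)
    b = rng.lognormal(10, 0.9, n)
    rep = vs.compare_measures(a, b)
    assert abs(rep.pearson_r) < 0.03
    assert rep.perfect_agreement_pct == pytest.approx(18.0, abs=1.5)


def test_within_one_category_agreement_matches_cell_scan():
    rng = np.random.default_rng(8)
    n = 3000
    a = rng.lognormal(10, 0.9, n)
    b = np.exp(0.8 * np.log(a) + 0.2 * rng.normal(10, 0.9, n))
    rep = vs.compare_measures(a, b)
    tab = rep.crosstab_pct.to_numpy()
    brute = sum(
        tab[i, j] for i in range(6) for j in range(6) if abs(i - j) <= 1
    )
    assert rep.within_one_pct == pytest.approx(brute)
    assert rep.crosstab_pct.to_numpy().sum() == pytest.approx(100.0)
    assert rep.perfect_agreement_pct == pytest.approx(np.trace(tab))


def test_compare_measures_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        vs.compare_measures([5.0] * 10, [5.0] * 10)
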