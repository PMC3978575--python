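"""Screening-outcome validation statistics for breast-density measures.

Reproduces the analysis design used to validate an automated density
measure against screening outcomes on a case-control sample drawn from a
population screening programme:

* whole-screened-population percentiles of dense area, weighting sampled
  controls by their inverse sampling fractions;
* quintile-decile density groups (four lowest quintiles Q1-Q4 plus the
  two upper deciles D9, D10);
* unconditional logistic regression odds ratios per density group
  (reference Q1), adjusted for age group, hormone-therapy use, family
  history, symptoms and screening round;
* programme sensitivity — the proportion of cancers that are
  screen-detected — predicted from a case-only model of interval versus
  screen-detected cancers;
* ROC/AUC discrimination, non-parametric trend (Cuzick) and rank
  (Kruskal-Wallis) tests, and between-measure agreement (correlation,
  Bland-Altman on the log scale, quintile-decile cross-classification).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GROUP_LABELS",
    "AGE_GROUPS",
    "OUTCOMES",
    "COHORT_COLUMNS",
    "ORTable",
    "SensitivityEstimate",
    "AgreementReport",
    "weighted_percentiles",
    "assign_group",
    "add_density_groups",
    "classify_tumour",
    "fit_outcome_model",
    "predict_sensitivity",
    "sensitivity_from_odds",
    "sensitivity_table",
    "roc_auc",
    "trend_and_rank_tests",
    "compare_measures",
]

#: Quintile-decile group labels in density order.
GROUP_LABELS = ("Q1", "Q2", "Q3", "Q4", "D9", "D10")
#: Population-percentile boundaries between consecutive groups.
GROUP_CUTS = (20.0, 40.0, 60.0, 80.0, 90.0)

AGE_GROUPS = ("40-49", "50-54", "55-59", "60-64", "65-69", "70-79")
OUTCOMES = ("small_screen_detected", "large_screen_detected", "interval", "control")
SCREEN_DETECTED = ("small_screen_detected", "large_screen_detected")

#: Cohort CSV schema consumed by this module.
COHORT_COLUMNS = (
    "woman_id", "age_group", "ht_use", "family_history", "symptoms",
    "screening_round", "outcome", "tumour_size_mm",
    "dense_area_px_a", "dense_area_px_b", "weight",
)

#: Default adjustment set of every regression model.
DEFAULT_COVARIATES = (
    "age_group", "ht_use", "family_history", "symptoms", "screening_round",
)

MICROINVASIVE = "microinvasive"
MICROINVASIVE_SIZE_MM = 0.1
SMALL_TUMOUR_MAX_MM = 15.0

_Z975 = float(stats.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# percentiles and grouping


def weighted_percentiles(
    values: Sequence[float], weights: Sequence[float] | None = None
) -> np.ndarray:
    """Percentile score of each value in the weighted empirical distribution.

    Mid-rank convention: pct(v) = 100 * (W(<v) + W(=v)/2) / W_total, so
    tied values share one percentile and a record of weight 2 behaves
    exactly like two unit-weight copies.  Weighting controls by inverse
    sampling fractions turns sample percentiles into whole-screened-
    population percentiles.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty input")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != values.shape:
        raise ValueError("values and weights must have the same length")
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("weights must be non-negative and not all zero")

    order = np.argsort(values, kind="mergesort")
    v_sorted = values[order]
    cw = np.concatenate([[0.0], np.cumsum(weights[order])])
    left = np.searchsorted(v_sorted, values, side="left")
    right = np.searchsorted(v_sorted, values, side="right")
    below = cw[left]
    equal = cw[right] - cw[left]
    return 100.0 * (below + 0.5 * equal) / cw[-1]


def assign_group(percentile):
    """Quintile-decile group for a percentile score in [0, 100].

    Boundaries are left-closed: [0,20) Q1, [20,40) Q2, [40,60) Q3,
    [60,80) Q4, [80,90) D9, [90,100] D10.
    """
    arr = np.asarray(percentile, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("percentile outside [0, 100]")
    idx = np.digitize(arr, GROUP_CUTS, right=False)
    labels = np.asarray(GROUP_LABELS, dtype=object)[idx]
    if np.isscalar(percentile) or arr.ndim == 0:
        return str(labels if arr.ndim == 0 else labels[()])
    return labels


def add_density_groups(
    records: pd.DataFrame,
    measure: str = "dense_area_px_a",
    group_col: str = "density_group",
) -> pd.DataFrame:
    """Attach weighted population percentiles and quintile-decile groups.

    Returns a copy with ``<group_col>`` and ``<group_col>_percentile``
    columns computed from ``measure`` using the ``weight`` column.
    """
    out = records.copy()
    pct = weighted_percentiles(out[measure].to_numpy(), out["weight"].to_numpy())
    out[group_col + "_percentile"] = pct
    out[group_col] = assign_group(pct)
    return out


# ---------------------------------------------------------------------------
# tumour classification


def classify_tumour(size) -> tuple[str, float]:
    """Classify one tumour record into (small|large, numeric size in mm).

    Microinvasive tumours are assigned a nominal size of 0.1 mm (and are
    therefore small); otherwise sizes of at most 15 mm are small and
    larger ones large.  Non-positive sizes are invalid.
    """
    if isinstance(size, str):
        if size.strip().lower() == MICROINVASIVE:
            return "small", MICROINVASIVE_SIZE_MM
        size = float(size)
    size = float(size)
    if not size > 0:
        raise ValueError(f"tumour size must be positive, got {size}")
    return ("small" if size <= SMALL_TUMOUR_MAX_MM else "large"), size


# ---------------------------------------------------------------------------
# logistic fitting core


def _design_matrix(
    records: pd.DataFrame,
    covariates: Sequence[str],
    group_col: str = "density_group",
    interaction_round: bool = False,
) -> pd.DataFrame:
    """Dummy-coded design: intercept, density groups (Q1 reference) and
    categorical covariates (first level of each as reference)."""
    present_groups = set(records[group_col].unique())
    cols: dict[str, np.ndarray] = {"const": np.ones(len(records))}
    for g in GROUP_LABELS[1:]:
        if g in present_groups:
            cols[f"density[{g}]"] = (records[group_col] == g).astype(float).to_numpy()
    for cov in covariates:
        if cov == "age_group":
            present_ages = set(records["age_group"].unique())
            for a in AGE_GROUPS[1:]:
                if a in present_ages:
                    cols[f"age[{a}]"] = (records["age_group"] == a).astype(float).to_numpy()
        elif cov == "ht_use":
            cols["ht_use"] = (records["ht_use"] == "yes").astype(float).to_numpy()
        elif cov == "family_history":
            cols["family_history"] = (
                records["family_history"] == "yes"
            ).astype(float).to_numpy()
        elif cov == "symptoms":
            cols["symptoms"] = (
                records["symptoms"] != "none"
            ).astype(float).to_numpy()
        elif cov == "screening_round":
            cols["subsequent_round"] = (
                records["screening_round"] == "subsequent"
            ).astype(float).to_numpy()
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    if interaction_round:
        rnd = (records["screening_round"] == "subsequent").astype(float).to_numpy()
        for g in GROUP_LABELS[1:]:
            if f"density[{g}]" in cols:
                cols[f"density[{g}]:subsequent"] = cols[f"density[{g}]"] * rnd
    return pd.DataFrame(cols, index=records.index)


def _fit_logit(y: np.ndarray, X: pd.DataFrame, records: pd.DataFrame,
               group_col: str = "density_group"):
    """Maximum-likelihood logistic fit shared by every model here."""
    _check_separation(y, records, group_col)
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=100)
    except Exception as exc:  # pragma: no cover - defensive
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge")
    return res


def _check_separation(y: np.ndarray, records: pd.DataFrame, group_col: str) -> None:
    """Fail early, naming the empty cell, when a density group carries
    only one outcome class (complete separation on the exposure)."""
    tab = pd.crosstab(records[group_col], y)
    for g in tab.index:
        row = tab.loc[g]
        if (row == 0).any():
            missing = "cases" if row.get(1, 0) == 0 else "controls"
            raise ValueError(
                f"complete separation: density group {g} has no {missing}"
            )


@dataclass
class ORTable:
    """Fitted odds ratios per quintile-decile group, reference Q1."""

    table: pd.DataFrame  # columns: group, odds_ratio, ci_low, ci_high
    covariates: tuple[str, ...]
    n_cases: int
    n_controls: int
    fit: object = field(repr=False, default=None)

    def odds_ratio(self, group: str) -> float:
        return float(self.table.set_index("group").loc[group, "odds_ratio"])

    def ci(self, group: str) -> tuple[float, float]:
        row = self.table.set_index("group").loc[group]
        return float(row["ci_low"]), float(row["ci_high"])


def fit_outcome_model(
    records: pd.DataFrame,
    case_outcomes: Sequence[str],
    control_outcomes: Sequence[str] = ("control",),
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_col: str = "density_group",
    measure: str = "dense_area_px_a",
    interaction_round: bool = False,
) -> ORTable:
    """Unconditional logistic regression of outcome on density group.

    Density group (Q1 reference) enters as a categorical exposure together
    with the categorical adjustment covariates; Wald 95% CIs are reported
    on the OR scale.  If ``group_col`` is absent it is derived from
    ``measure`` with weighted population percentiles first.
    """
    if group_col not in records.columns:
        records = add_density_groups(records, measure=measure, group_col=group_col)
    sub = records[records["outcome"].isin(tuple(case_outcomes) + tuple(control_outcomes))]
    y = sub["outcome"].isin(case_outcomes).astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both cases and controls to fit the model")
    X = _design_matrix(sub, covariates, group_col, interaction_round)
    res = _fit_logit(y, X, sub, group_col)

    rows = [{"group": "Q1", "odds_ratio": 1.0, "ci_low": 1.0, "ci_high": 1.0}]
    for g in GROUP_LABELS[1:]:
        name = f"density[{g}]"
        if name not in res.params.index:
            continue
        b = res.params[name]
        se = res.bse[name]
        rows.append(
            {
                "group": g,
                "odds_ratio": float(np.exp(b)),
                "ci_low": float(np.exp(b - _Z975 * se)),
                "ci_high": float(np.exp(b + _Z975 * se)),
            }
        )
    return ORTable(
        table=pd.DataFrame(rows),
        covariates=tuple(covariates),
        n_cases=int(y.sum()),
        n_controls=int(len(y) - y.sum()),
        fit=res,
    )


# ---------------------------------------------------------------------------
# programme sensitivity


def sensitivity_from_odds(odds: float) -> float:
    """Programme sensitivity (%) from the odds of interval versus
    screen-detected cancer: 100 / (1 + odds)."""
    return 100.0 / (1.0 + odds)


def _profile_vector(
    columns: Iterable[str], profile: dict, group_col: str
) -> np.ndarray:
    """Design-row for one covariate profile, aligned to fitted columns."""
    x = []
    for col in columns:
        if col == "const":
            x.append(1.0)
        elif col.startswith("density["):
            x.append(float(profile.get(group_col) == col[8:-1]))
        elif col.startswith("age["):
            x.append(float(profile.get("age_group") == col[4:-1]))
        elif col == "ht_use":
            x.append(float(profile.get("ht_use") == "yes"))
        elif col == "family_history":
            x.append(float(profile.get("family_history") == "yes"))
        elif col == "symptoms":
            x.append(float(profile.get("symptoms", "none") != "none"))
        elif col == "subsequent_round":
            x.append(float(profile.get("screening_round") == "subsequent"))
        else:
            raise ValueError(f"cannot evaluate profile for design column {col!r}")
    return np.asarray(x)


@dataclass
class SensitivityEstimate:
    """Predicted programme sensitivity (%) for one covariate profile."""

    sensitivity: float
    ci_low: float
    ci_high: float
    profile: dict


def predict_sensitivity(
    records: pd.DataFrame,
    profile: Mapping[str, str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_col: str = "density_group",
    measure: str = "dense_area_px_a",
) -> SensitivityEstimate:
    """Programme sensitivity from the case-only interval-cancer model.

    Fits interval versus screen-detected among cancers (same logistic
    core as the OR models), evaluates the linear predictor at ``profile``
    (a mapping with ``density_group`` plus one level per covariate), and
    transforms its Wald CI through 100/(1+odds).  The transform is
    monotone decreasing, so the CI bounds swap.
    """
    if group_col not in records.columns:
        records = add_density_groups(records, measure=measure, group_col=group_col)
    cases = records[records["outcome"] != "control"]
    if cases.empty:
        raise ValueError("no cancer cases in the records")
    y = (cases["outcome"] == "interval").astype(int).to_numpy()
    X = _design_matrix(cases, covariates, group_col)
    res = _fit_logit(y, X, cases, group_col)

    x = _profile_vector(X.columns, dict(profile), group_col)
    eta = float(x @ res.params.to_numpy())
    se = float(np.sqrt(x @ res.cov_params().to_numpy() @ x))
    return SensitivityEstimate(
        sensitivity=sensitivity_from_odds(np.exp(eta)),
        ci_low=sensitivity_from_odds(np.exp(eta + _Z975 * se)),
        ci_high=sensitivity_from_odds(np.exp(eta - _Z975 * se)),
        profile=dict(profile),
    )


def sensitivity_table(
    records: pd.DataFrame,
    base_profile: Mapping[str, str] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_col: str = "density_group",
    measure: str = "dense_area_px_a",
) -> pd.DataFrame:
    """Predicted sensitivity per screening round and density group for a
    reference woman (defaults: aged 50-54, no symptoms, no hormone
    therapy, no family history)."""
    base = {
        "age_group": "50-54",
        "ht_use": "no",
        "family_history": "no",
        "symptoms": "none",
    }
    if base_profile:
        base.update(base_profile)
    rows = []
    for rnd in ("first", "subsequent"):
        for g in GROUP_LABELS:
            profile = dict(base, screening_round=rnd, **{group_col: g})
            est = predict_sensitivity(
                records, profile, covariates, group_col, measure
            )
            rows.append(
                {
                    "screening_round": rnd,
                    "group": g,
                    "sensitivity": est.sensitivity,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# discrimination and non-parametric tests


def roc_auc(
    case_values: Sequence[float], control_values: Sequence[float]
) -> tuple[float, pd.DataFrame]:
    """ROC curve and AUC for separating cases from controls by a value.

    The AUC is the Mann-Whitney probability that a random case exceeds a
    random control, ties counted one half; the curve has one point per
    distinct threshold (classification rule: value >= threshold is
    called a case).
    """
    cases = np.asarray(case_values, dtype=np.float64)
    controls = np.asarray(control_values, dtype=np.float64)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([cases, controls])
    ranks = stats.rankdata(combined)
    r_cases = ranks[: cases.size].sum()
    auc = (r_cases - cases.size * (cases.size + 1) / 2.0) / (cases.size * controls.size)

    thresholds = np.unique(combined)[::-1]
    tpr = [(cases >= t).mean() for t in thresholds]
    fpr = [(controls >= t).mean() for t in thresholds]
    curve = pd.DataFrame(
        {
            "threshold": np.concatenate([[np.inf], thresholds]),
            "fpr": np.concatenate([[0.0], fpr]),
            "tpr": np.concatenate([[0.0], tpr]),
        }
    )
    return float(auc), curve


def trend_and_rank_tests(
    values: Sequence[float],
    group_labels: Sequence,
    ordered_groups: Sequence | None = None,
    scores: Sequence[float] | None = None,
) -> dict:
    """Cuzick trend test across ordered groups and Kruskal-Wallis H.

    The Cuzick statistic is a Wilcoxon-type rank test for trend: with
    group scores l_i and rank sums R_i (mid-ranks for ties),
    T = sum l_i R_i is standardised by its permutation mean and variance
    (tie-corrected).  Groups listed in ``ordered_groups`` must all be
    present.  Returns ``cuzick_z``, ``cuzick_p``, ``kw_h``, ``kw_p``.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(group_labels, dtype=object)
    if ordered_groups is None:
        ordered_groups = sorted(set(labels.tolist()))
    ordered_groups = list(ordered_groups)
    if len(ordered_groups) < 2:
        raise ValueError("need at least two groups")
    group_vals = [values[labels == g] for g in ordered_groups]
    for g, gv in zip(ordered_groups, group_vals):
        if gv.size == 0:
            raise ValueError(f"group {g!r} has zero members")
    if scores is None:
        scores = np.arange(1, len(ordered_groups) + 1, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)

    n = values.size
    ranks = stats.rankdata(values)
    n_i = np.array([gv.size for gv in group_vals], dtype=np.float64)
    r_i = np.array(
        [ranks[labels == g].sum() for g in ordered_groups], dtype=np.float64
    )
    t_stat = float(np.sum(scores * r_i))
    l_bar = float(np.sum(scores * n_i))
    e_t = (n + 1) / 2.0 * l_bar
    var_t = (n + 1) / 12.0 * (n * float(np.sum(scores**2 * n_i)) - l_bar**2)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_corr = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n) if n > 1 else 0.0
    var_t *= tie_corr
    if var_t <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (t_stat - e_t) / np.sqrt(var_t)
        p = 2.0 * stats.norm.sf(abs(z))

    if np.unique(values).size == 1:
        kw_h, kw_p = 0.0, 1.0
    else:
        kw_h, kw_p = stats.kruskal(*group_vals)
    return {
        "cuzick_z": float(z),
        "cuzick_p": float(p),
        "kw_h": float(kw_h),
        "kw_p": float(kw_p),
    }


# ---------------------------------------------------------------------------
# between-measure agreement


@dataclass
class AgreementReport:
    """Agreement between two dense-area measures on the same images."""

    pearson_r: float
    pearson_p: float
    ba_mean_diff: float  # mean difference of log dense areas
    ba_lo: float  # lower limit of agreement (log scale)
    ba_hi: float
    crosstab_pct: pd.DataFrame  # 6x6, rows measure A, columns measure B, %
    perfect_agreement_pct: float
    within_one_pct: float


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    cov = np.average((x - xm) * (y - ym), weights=w)
    vx = np.average((x - xm) ** 2, weights=w)
    vy = np.average((y - ym) ** 2, weights=w)
    if vx == 0 or vy == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(cov / np.sqrt(vx * vy))


def compare_measures(
    measure_a: Sequence[float],
    measure_b: Sequence[float],
    weights: Sequence[float] | None = None,
) -> AgreementReport:
    """Agreement analysis between two paired dense-area measures.

    Pearson correlation of the (weighted) population percentile scores,
    Bland-Altman mean difference and 95% limits of agreement on the log
    dense-area scale, and the weighted 6x6 cross-classification of
    quintile-decile groups with perfect and within-one-category agreement
    percentages.
    """
    a = np.asarray(measure_a, dtype=np.float64)
    b = np.asarray(measure_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("measures must be paired 1-D sequences")
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=np.float64)

    pct_a = weighted_percentiles(a, w)
    pct_b = weighted_percentiles(b, w)
    r = _weighted_pearson(pct_a, pct_b, w)
    n = a.size
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r) * np.sqrt(n - 3)
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 0.0 if abs(r) == 1 else 1.0

    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("dense areas must be positive for log Bland-Altman")
    diff = np.log(a) - np.log(b)
    mean_diff = float(np.average(diff, weights=w))
    sd_diff = float(np.sqrt(np.average((diff - mean_diff) ** 2, weights=w)))
    lo = mean_diff - 1.96 * sd_diff
    hi = mean_diff + 1.96 * sd_diff

    ga = assign_group(pct_a)
    gb = assign_group(pct_b)
    tab = np.zeros((6, 6))
    gidx = {g: i for i, g in enumerate(GROUP_LABELS)}
    for i, j, wi in zip(ga, gb, w):
        tab[gidx[i], gidx[j]] += wi
    tab_pct = 100.0 * tab / tab.sum()
    perfect = float(np.trace(tab_pct))
    ii, jj = np.indices(tab.shape)
    within_one = float(tab_pct[np.abs(ii - jj) <= 1].sum())

    return AgreementReport(
        pearson_r=r,
        pearson_p=p,
        ba_mean_diff=mean_diff,
        ba_lo=float(lo),
        ba_hi=float(hi),
        crosstab_pct=pd.DataFrame(
            tab_pct, index=list(GROUP_LABELS), columns=list(GROUP_LABELS)
        ),
        perfect_agreement_pct=perfect,
        within_one_pct=within_one,
    )
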