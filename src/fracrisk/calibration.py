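"""Quantile calibration tables and predicted-risk ratios.

Calibration is assessed by grouping subjects into quantiles of predicted
risk (quintiles for any-osteoporotic fracture, quartiles for hip) and
comparing each group's mean predicted probability against the observed
cumulative incidence at the prediction horizon.  The observed risk is the
Kaplan-Meier complement by default — administrative censoring typically
ends follow-up before a 10-year horizon, so a crude event proportion would
be biased low — with a crude-proportion option for fully observed data.

The predicted-risk ratio contrasts the geometric mean predicted risk of
subjects who fractured with that of subjects who did not:
``exp(mean log p | event) - (mean log p | no event))``, with a Welch-type
normal interval on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import (
    DegenerateGroupingError,
    DegenerateOutcomeError,
    DomainError,
    PairingError,
)


@dataclass(frozen=True)
class CalibrationGroup:
    group: int             # 1-based, lowest predicted risk first
    n: int
    mean_predicted: float
    observed_risk: float   # cumulative incidence at the horizon
    observed_ci_low: float
    observed_ci_high: float


@dataclass(frozen=True)
class CalibrationTable:
    n_groups: int
    horizon: float
    cutoffs: tuple[float, ...]   # probability thresholds between groups
    groups: tuple[CalibrationGroup, ...]
    observed_estimator: str


@dataclass(frozen=True)
class RiskRatioResult:
    ratio: float
    ci_low: float
    ci_high: float
    n_fracture: int
    n_nonfracture: int


def quantile_groups(predicted, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign quantile-group labels (0-based) with ties to the lower group.

    Returns ``(labels, cutoffs)`` where cutoffs are the n_groups-1 interior
    empirical quantiles of the predictions.
    """
    predicted = np.asarray(predicted, dtype=float)
    if n_groups < 2:
        raise DomainError("n_groups must be >= 2")
    if predicted.size <= n_groups:
        raise DomainError("cohort must be larger than the number of groups")
    if np.unique(predicted).size < n_groups:
        raise DegenerateGroupingError(
            f"only {np.unique(predicted).size} distinct predicted values for "
            f"{n_groups} groups; reduce n_groups or perturb the predictions"
        )
    cutoffs = np.quantile(predicted, np.arange(1, n_groups) / n_groups)
    # ties at a cutoff fall into the lower group
    labels = np.searchsorted(cutoffs, predicted, side="left")
    if np.unique(labels).size < n_groups:
        raise DegenerateGroupingError(
            "tied predictions collapse at least one quantile group; "
            "reduce n_groups or perturb the predictions"
        )
    return labels, cutoffs


def _km_risk(followup_years, events, horizon: float, alpha: float = 0.05):
    """Kaplan-Meier cumulative incidence at `horizon` with Greenwood CI."""
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(followup_years, event_observed=events)
    risk = float(kmf.cumulative_density_at_times(horizon).iloc[0])
    ci = kmf.confidence_interval_survival_function_
    idx = ci.index.values
    pos = np.searchsorted(idx, horizon, side="right") - 1
    pos = max(pos, 0)
    s_low, s_high = ci.iloc[pos, 0], ci.iloc[pos, 1]
    return risk, float(1.0 - s_high), float(1.0 - s_low)


def _crude_risk(followup_years, events, horizon: float, alpha: float = 0.05):
    """Event proportion within the horizon with a Wilson interval."""
    followup_years = np.asarray(followup_years, dtype=float)
    events = np.asarray(events, dtype=int)
    k = int(((events == 1) & (followup_years <= horizon)).sum())
    n = events.size
    res = stats.binomtest(k, n).proportion_ci(confidence_level=1 - alpha, method="wilson")
    return k / n, float(res.low), float(res.high)


def calibration_table(
    predicted,
    followup_years,
    events,
    n_groups: int = 5,
    horizon: float = 10.0,
    observed: str = "km",
) -> CalibrationTable:
    """Observed vs mean predicted risk across quantile groups of prediction.

    ``observed="km"`` (default) estimates each group's observed risk as the
    Kaplan-Meier cumulative incidence at `horizon` (death and end of
    registration treated as censoring); ``"crude"`` uses the raw event
    proportion within the horizon.
    """
    predicted = np.asarray(predicted, dtype=float)
    followup_years = np.asarray(followup_years, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (predicted.shape == followup_years.shape == events.shape):
        raise PairingError("predicted, followup_years and events must align")
    labels, cutoffs = quantile_groups(predicted, n_groups)
    estimator = {"km": _km_risk, "crude": _crude_risk}.get(observed)
    if estimator is None:
        raise DomainError(f"unknown observed-risk estimator {observed!r}")
    groups = []
    for g in range(n_groups):
        mask = labels == g
        obs, lo, hi = estimator(followup_years[mask], events[mask], horizon)
        groups.append(
            CalibrationGroup(
                group=g + 1,
                n=int(mask.sum()),
                mean_predicted=float(predicted[mask].mean()),
                observed_risk=obs,
                observed_ci_low=lo,
                observed_ci_high=hi,
            )
        )
    return CalibrationTable(
        n_groups=n_groups,
        horizon=float(horizon),
        cutoffs=tuple(float(c) for c in cutoffs),
        groups=tuple(groups),
        observed_estimator=observed,
    )


def predicted_risk_band(predicted_group, alpha: float = 0.05) -> tuple[float, float]:
    """Monte-Carlo band for a group's observed risk under perfect calibration.

    If every subject's true risk equals their prediction, the observed
    event fraction in a group is a sum of independent Bernoulli draws; the
    band is the normal interval around the mean prediction with the
    heterogeneous-Bernoulli standard error.
    """
    p = np.asarray(predicted_group, dtype=float)
    if p.size == 0:
        raise DomainError("empty group")
    z = stats.norm.ppf(1 - alpha / 2)
    se = float(np.sqrt(np.sum(p * (1 - p))) / p.size)
    mean = float(p.mean())
    return mean - z * se, mean + z * se


def predicted_risk_ratio(predicted, events, alpha: float = 0.05) -> RiskRatioResult:
    """Geometric-mean ratio of predicted risk, fracture vs non-fracture.

    The ratio is the back-transformed difference in mean log predicted risk
    between subjects with and without the outcome; the CI back-transforms a
    Welch two-sample interval on the log scale.
    """
    predicted = np.asarray(predicted, dtype=float)
    events = np.asarray(events, dtype=int)
    if predicted.shape != events.shape:
        raise PairingError("predicted and events must align")
    if np.any(predicted <= 0.0):
        raise DomainError("all predictions must be strictly positive")
    log_p = np.log(predicted)
    g1 = log_p[events == 1]
    g0 = log_p[events == 0]
    if g1.size == 0 or g0.size == 0:
        raise DegenerateOutcomeError("both fracture and non-fracture groups must be non-empty")
    diff = float(g1.mean() - g0.mean())
    if g1.size > 1 and g0.size > 1:
        v1, v0 = g1.var(ddof=1) / g1.size, g0.var(ddof=1) / g0.size
        se = float(np.sqrt(v1 + v0))
        if se > 0:
            df = (v1 + v0) ** 2 / (
                v1**2 / (g1.size - 1) + v0**2 / (g0.size - 1)
            )
            t = stats.t.ppf(1 - alpha / 2, df)
        else:
            t = 0.0
    else:
        se, t = 0.0, 0.0
    return RiskRatioResult(
        ratio=float(np.exp(diff)),
        ci_low=float(np.exp(diff - t * se)),
        ci_high=float(np.exp(diff + t * se)),
        n_fracture=int(g1.size),
        n_nonfracture=int(g0.size),
    )
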