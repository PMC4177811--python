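"""ROC discrimination: AUC with DeLong variance and paired AUC comparison.

The AUC here is the Mann-Whitney probability that a randomly chosen subject
who fractured is assigned a higher predicted risk than a randomly chosen
subject who did not, with tied predictions counted 1/2.  Standard errors
use the DeLong placement-value estimator; paired model comparisons use the
DeLong covariance of the two AUCs and a two-sided normal p-value.

By default the outcome is the binary "suffered a first fracture during
follow-up" indicator.  :func:`horizon_restricted_outcome` offers the
alternative framing for horizon-specific predictions: events within the
horizon count as events, subjects censored event-free before the horizon
are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateOutcomeError, DomainError, PairingError


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_events: int
    n_nonevents: int


@dataclass(frozen=True)
class AUCComparison:
    auc_a: float
    auc_b: float
    delta: float      # auc_a - auc_b
    se_delta: float
    z: float
    p_value: float


def _check_inputs(predicted, events):
    predicted = np.asarray(predicted, dtype=float)
    events = np.asarray(events)
    if predicted.shape != events.shape or predicted.ndim != 1:
        raise PairingError("predicted and events must be equal-length 1-D vectors")
    if not np.all(np.isin(events, (0, 1))):
        raise DomainError("events must be coded 0/1")
    events = events.astype(int)
    if events.sum() == 0 or events.sum() == events.size:
        raise DegenerateOutcomeError(
            "AUC needs at least one event and one non-event subject"
        )
    return predicted, events


def _placements(predicted: np.ndarray, events: np.ndarray):
    """DeLong placement values (V10 for events, V01 for non-events) and AUC."""
    pos = predicted[events == 1]
    neg = predicted[events == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    # midrank identity: placement of each event among non-events, ties = 1/2
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc_value = v10.mean()
    return auc_value, v10, v01


def auc(
    predicted,
    events,
    alpha: float = 0.05,
    ci_scale: str = "linear",
) -> ROCResult:
    """Mann-Whitney AUC with DeLong standard error.

    ``ci_scale="linear"`` gives a normal CI truncated to [0, 1];
    ``"logit"`` forms the interval on the log-odds scale.
    """
    predicted, events = _check_inputs(predicted, events)
    auc_value, v10, v01 = _placements(predicted, events)
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    if ci_scale == "linear":
        lo, hi = max(0.0, auc_value - z * se), min(1.0, auc_value + z * se)
    elif ci_scale == "logit":
        if not 0.0 < auc_value < 1.0 or se == 0.0:
            lo = hi = auc_value
        else:
            logit = np.log(auc_value / (1 - auc_value))
            se_logit = se / (auc_value * (1 - auc_value))
            lo = 1 / (1 + np.exp(-(logit - z * se_logit)))
            hi = 1 / (1 + np.exp(-(logit + z * se_logit)))
    else:
        raise DomainError(f"unknown ci_scale {ci_scale!r}")
    return ROCResult(
        auc=float(auc_value),
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
        n_events=m,
        n_nonevents=n,
    )


def compare_auc(predicted_a, predicted_b, events) -> AUCComparison:
    """Paired DeLong comparison of two models' AUCs on the same subjects."""
    predicted_a = np.asarray(predicted_a, dtype=float)
    predicted_b = np.asarray(predicted_b, dtype=float)
    if predicted_a.shape != predicted_b.shape:
        raise PairingError("the two prediction vectors must cover the same subjects")
    predicted_a, events = _check_inputs(predicted_a, events)
    auc_a, v10_a, v01_a = _placements(predicted_a, events)
    auc_b, v10_b, v01_b = _placements(predicted_b, events)
    m, n = v10_a.size, v01_a.size

    def _cov(x, y, size):
        return float(np.cov(x, y, ddof=1)[0, 1]) / size if size > 1 else 0.0

    var_delta = (
        _cov(v10_a, v10_a, m) + _cov(v10_b, v10_b, m) - 2 * _cov(v10_a, v10_b, m)
        + _cov(v01_a, v01_a, n) + _cov(v01_b, v01_b, n) - 2 * _cov(v01_a, v01_b, n)
    )
    se_delta = float(np.sqrt(max(var_delta, 0.0)))
    delta = float(auc_a - auc_b)
    if se_delta == 0.0:
        z = 0.0 if delta == 0.0 else np.inf * np.sign(delta)
    else:
        z = delta / se_delta
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return AUCComparison(
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        delta=delta,
        se_delta=se_delta,
        z=float(z),
        p_value=p,
    )


def horizon_restricted_outcome(followup_years, events, horizon: float):
    """Binary outcome restricted to a prediction horizon.

    Returns ``(mask, outcome)``: subjects kept (event within the horizon, or
    followed event-free past it) and their 0/1 outcome.  Subjects censored
    event-free before the horizon carry no information about horizon-
    restricted status and are dropped.
    """
    followup_years = np.asarray(followup_years, dtype=float)
    events = np.asarray(events, dtype=int)
    event_in_horizon = (events == 1) & (followup_years <= horizon)
    survived_horizon = followup_years >= horizon
    mask = event_in_horizon | survived_horizon
    return mask, event_in_horizon[mask].astype(int)


def roc_curve_table(predicted, events) -> "np.ndarray":
    """(threshold, FPR, TPR) coordinate table, one row per distinct cutoff."""
    predicted, events = _check_inputs(predicted, events)
    order = np.argsort(-predicted, kind="mergesort")
    p_sorted = predicted[order]
    e_sorted = events[order]
    distinct = np.r_[np.nonzero(np.diff(p_sorted))[0], p_sorted.size - 1]
    tp = np.cumsum(e_sorted)[distinct]
    fp = np.cumsum(1 - e_sorted)[distinct]
    tpr = tp / e_sorted.sum()
    fpr = fp / (1 - e_sorted).sum()
    return np.column_stack([p_sorted[distinct], fpr, tpr])
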