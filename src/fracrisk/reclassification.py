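"""Net reclassification improvement between two risk models.

Subjects are assigned to ordered risk categories under a reference model
and a comparison model; the categorical NRI summarizes how often the
comparison model moves subjects in the "correct" direction:

    NRI_event     = P(up | event)   - P(down | event)
    NRI_non-event = P(down | non-event) - P(up | non-event)
    NRI_overall   = NRI_event + NRI_non-event

Standard errors use Pencina's asymptotic formulas for the categorical NRI
with two-sided normal p-values.  The sign convention is fixed — positive
values mean the comparison model classifies better — and is carried in
every result so tabulated output cannot be misread.

Category thresholds default to each model's own predicted-risk quartiles
(``threshold_mode="per_model"``); a shared mode using the pooled quartiles
of both models' predictions, and fully explicit thresholds, are also
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateOutcomeError,
    DomainError,
    PairingError,
    ThresholdError,
)

SIGN_CONVENTION = "positive = comparison model classifies better than reference"


@dataclass(frozen=True)
class ReclassificationTable:
    """Cross-tab of risk categories (reference rows x comparison columns)."""

    thresholds_reference: tuple[float, ...]
    thresholds_comparison: tuple[float, ...]
    event_table: np.ndarray      # shape (k, k)
    nonevent_table: np.ndarray   # shape (k, k)

    @property
    def n_events(self) -> int:
        return int(self.event_table.sum())

    @property
    def n_nonevents(self) -> int:
        return int(self.nonevent_table.sum())


@dataclass(frozen=True)
class NRIResult:
    nri_event: float
    nri_nonevent: float
    nri_overall: float
    se_event: float
    se_nonevent: float
    se_overall: float
    p_event: float
    p_nonevent: float
    p_overall: float
    direction_convention: str = SIGN_CONVENTION


def _as_thresholds(thresholds) -> tuple[float, ...]:
    t = tuple(float(x) for x in thresholds)
    if len(t) == 0:
        raise ThresholdError("at least one threshold is required")
    if any(b <= a for a, b in zip(t, t[1:])):
        raise ThresholdError(f"thresholds must be strictly increasing, got {t}")
    return t


def assign_categories(predicted, thresholds) -> np.ndarray:
    """0-based ordered risk category for each prediction.

    A prediction equal to a threshold falls in the lower category,
    consistent with the quantile-grouping tie rule used elsewhere.
    """
    thresholds = _as_thresholds(thresholds)
    return np.searchsorted(np.asarray(thresholds), np.asarray(predicted, float), side="left")


def model_quartiles(predicted) -> tuple[float, ...]:
    """The three interior quartile cut-offs of a model's predicted risks."""
    q = np.quantile(np.asarray(predicted, dtype=float), [0.25, 0.5, 0.75])
    if np.unique(q).size < 3:
        raise ThresholdError("predicted risks too discrete for distinct quartiles")
    return tuple(float(x) for x in q)


def _resolve_thresholds(pred_reference, pred_comparison, thresholds, threshold_mode):
    if thresholds is not None:
        t = _as_thresholds(thresholds)
        return t, t
    if threshold_mode == "per_model":
        return model_quartiles(pred_reference), model_quartiles(pred_comparison)
    if threshold_mode == "shared":
        pooled = np.concatenate([pred_reference, pred_comparison])
        t = model_quartiles(pooled)
        return t, t
    raise DomainError(f"unknown threshold_mode {threshold_mode!r}")


def _paired(pred_reference, pred_comparison, events):
    a = np.asarray(pred_reference, dtype=float)
    b = np.asarray(pred_comparison, dtype=float)
    e = np.asarray(events)
    if not (a.shape == b.shape == e.shape) or a.ndim != 1:
        raise PairingError("prediction vectors and events must be equal-length 1-D vectors")
    if not np.all(np.isin(e, (0, 1))):
        raise DomainError("events must be coded 0/1")
    return a, b, e.astype(int)


def reclassification_table(
    pred_reference,
    pred_comparison,
    events,
    thresholds=None,
    threshold_mode: str = "per_model",
) -> ReclassificationTable:
    """Cross-tabulate risk categories under the two models by event status."""
    a, b, e = _paired(pred_reference, pred_comparison, events)
    t_ref, t_cmp = _resolve_thresholds(a, b, thresholds, threshold_mode)
    k = max(len(t_ref), len(t_cmp)) + 1
    cat_ref = assign_categories(a, t_ref)
    cat_cmp = assign_categories(b, t_cmp)
    tables = []
    for status in (1, 0):
        mask = e == status
        table = np.zeros((k, k), dtype=int)
        np.add.at(table, (cat_ref[mask], cat_cmp[mask]), 1)
        tables.append(table)
    return ReclassificationTable(
        thresholds_reference=t_ref,
        thresholds_comparison=t_cmp,
        event_table=tables[0],
        nonevent_table=tables[1],
    )


def _component(n_up: int, n_down: int, n: int) -> tuple[float, float, float]:
    """Net proportion moved, Pencina asymptotic SE and two-sided p."""
    p_up, p_down = n_up / n, n_down / n
    index = p_up - p_down
    se = float(np.sqrt(max(p_up + p_down - (p_up - p_down) ** 2, 0.0) / n))
    if se == 0.0:
        p = 1.0 if index == 0.0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(index) / se))
    return index, se, p


def nri_from_table(table: ReclassificationTable, event_direction: int = +1) -> NRIResult:
    """Categorical NRI from a reclassification cross-tab.

    ``event_direction=+1`` keeps the standard convention (upward moves are
    correct for events); it exists so the swap-antisymmetry of the index can
    be exercised directly.
    """
    iu = np.triu_indices_from(table.event_table, k=1)
    il = np.tril_indices_from(table.event_table, k=-1)
    n_e = table.n_events
    n_ne = table.n_nonevents
    if n_e == 0 or n_ne == 0:
        raise DegenerateOutcomeError("NRI needs at least one event and one non-event")
    up_e, down_e = int(table.event_table[iu].sum()), int(table.event_table[il].sum())
    up_ne, down_ne = int(table.nonevent_table[iu].sum()), int(table.nonevent_table[il].sum())
    if event_direction == -1:
        up_e, down_e = down_e, up_e
        up_ne, down_ne = down_ne, up_ne
    nri_e, se_e, p_e = _component(up_e, down_e, n_e)
    nri_ne, se_ne, p_ne = _component(down_ne, up_ne, n_ne)
    nri_all = nri_e + nri_ne
    se_all = float(np.sqrt(se_e**2 + se_ne**2))
    p_all = 1.0 if se_all == 0.0 and nri_all == 0.0 else (
        0.0 if se_all == 0.0 else float(2 * stats.norm.sf(abs(nri_all) / se_all))
    )
    return NRIResult(
        nri_event=nri_e,
        nri_nonevent=nri_ne,
        nri_overall=nri_all,
        se_event=se_e,
        se_nonevent=se_ne,
        se_overall=se_all,
        p_event=p_e,
        p_nonevent=p_ne,
        p_overall=p_all,
    )


def nri(
    pred_reference,
    pred_comparison,
    events,
    thresholds=None,
    threshold_mode: str = "per_model",
) -> NRIResult:
    """Categorical net reclassification improvement of comparison vs reference."""
    table = reclassification_table(
        pred_reference, pred_comparison, events, thresholds, threshold_mode
    )
    return nri_from_table(table)
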