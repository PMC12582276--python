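"""Type A/B/C classification of chromatin-state periodicity responses.

Each chromatin state contributes a paired (control, treated) periodicity
profile. The response of its nucleosome-repeat signal to linker-histone
overexpression falls into three categories:

* **A** — no repeat signal in either condition (open chromatin stays open),
* **B** — a weak repeat signal that does not weaken on treatment, typically
  with a small (~4 bp) NRL increase,
* **C** — no repeat signal in control but a strong ladder after treatment
  (de novo nucleosome ordering).

Thresholds on the bounded repeat-strength score operationalize the
qualitative labels; the defaults were calibrated once on the package's
synthetic generator (see docs/methods.md).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError
from .nrl import PeriodicityProfile


@dataclass(frozen=True)
class TypingThresholds:
    """Strength cut points for the no/weak/strong repeat-signal labels."""

    s_none: float = 0.05
    s_weak: float = 0.10
    s_strong: float = 0.30
    min_delta_nrl_bp: float = 0.0
    strict_b: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.s_none <= self.s_weak <= self.s_strong <= 1.0):
            raise ParameterError(
                "require 0 <= s_none <= s_weak <= s_strong <= 1")


@dataclass
class StateTypeCall:
    """Classification of one chromatin state's periodicity response."""

    state_label: str
    call: str  # "A" | "B" | "C" | "unclassified"
    wt_strength: float | None = None
    tx_strength: float | None = None
    delta_nrl_bp: float | None = None
    reason: str | None = None


def classify_state(wt: PeriodicityProfile,
                   tx: PeriodicityProfile,
                   thresholds: TypingThresholds = TypingThresholds(),
                   state_label: str | None = None) -> StateTypeCall:
    """Classify one state from its paired control/treated profiles.

    A: both strengths below ``s_none``. C: control below ``s_none`` and
    treated at/above ``s_strong``. B: control in ``[s_none, s_strong)``
    and treated strength not lower than control. Anything else is
    unclassified. The treated-minus-control NRL difference is reported
    whenever both NRLs are defined; with ``strict_b``, B additionally
    requires ``delta_nrl_bp >= min_delta_nrl_bp``.
    """
    thresholds.validate()
    label = state_label or (wt.stratum[0] if wt.stratum else "?")
    ws, ts = wt.strength, tx.strength
    delta = None
    if not (math.isnan(wt.nrl_bp) or math.isnan(tx.nrl_bp)):
        delta = tx.nrl_bp - wt.nrl_bp

    if ws < thresholds.s_none and ts < thresholds.s_none:
        call, reason = "A", None
    elif ws < thresholds.s_none and ts >= thresholds.s_strong:
        call, reason = "C", None
    elif thresholds.s_none <= ws < thresholds.s_strong and ts >= ws:
        call, reason = "B", None
        if thresholds.strict_b and (
                delta is None or delta < thresholds.min_delta_nrl_bp):
            call, reason = "unclassified", "delta_nrl below strict-B minimum"
    else:
        call, reason = "unclassified", "strength pattern matches no category"
    return StateTypeCall(label, call, ws, ts, delta, reason)


def classify_all(profiles: dict[tuple[str, str], PeriodicityProfile],
                 thresholds: TypingThresholds = TypingThresholds(),
                 conditions: tuple[str, str] = ("WT", "iH1.0"),
                 ) -> tuple[list[StateTypeCall], pd.DataFrame]:
    """Classify every state with a paired profile; summarize counts by type.

    `profiles` maps ``(state_label, condition)`` to a profile. States
    missing either condition are reported unclassified with a reason.
    Output preserves first-appearance state order.
    """
    order: dict[str, None] = {}
    for state, _cond in profiles:
        order.setdefault(state, None)
    calls = []
    for state in order:
        wt = profiles.get((state, conditions[0]))
        tx = profiles.get((state, conditions[1]))
        if wt is None or tx is None:
            missing = conditions[0] if wt is None else conditions[1]
            calls.append(StateTypeCall(
                state, "unclassified",
                wt.strength if wt else None, tx.strength if tx else None,
                None, f"missing {missing} profile"))
            continue
        calls.append(classify_state(wt, tx, thresholds, state_label=state))
    counts = pd.Series([c.call for c in calls]).value_counts()
    summary = pd.DataFrame({
        "type": ["A", "B", "C", "unclassified"],
        "n_states": [int(counts.get(t, 0))
                     for t in ("A", "B", "C", "unclassified")],
    })
    return calls, summary


def calls_to_frame(calls: list[StateTypeCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "state": c.state_label, "call": c.call,
        "wt_strength": c.wt_strength, "tx_strength": c.tx_strength,
        "delta_nrl_bp": c.delta_nrl_bp, "reason": c.reason,
    } for c in calls])
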