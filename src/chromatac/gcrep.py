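"""GC content per chromatin state and the representation-vs-GC regression.

Quantifies whether reads from GC-poor states are under-represented in one
condition relative to another: each fragment is assigned to the state
containing its midpoint, per-state read percentages are computed per
condition, and the log2 treated/control representation ratio is regressed
on state GC content by ordinary least squares.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import FragmentRecord, GenomicInterval
from .errors import (AnnotationConflictError, BoundsError,
                     InsufficientDataError, UndefinedValueError)

log = logging.getLogger(__name__)

_GC = frozenset("GC")
_AT = frozenset("AT")


def gc_content(genome: Mapping[str, str],
               intervals: Sequence[GenomicInterval]) -> float:
    """Pooled (G+C)/(A+C+G+T) over intervals; ambiguity codes excluded.

    Case-insensitive (soft-masked lowercase counts like uppercase).
    """
    gc = at = 0
    for iv in intervals:
        seq = genome.get(iv.chrom)
        if seq is None:
            raise BoundsError(f"chromosome {iv.chrom!r} not in genome")
        if iv.end > len(seq):
            raise BoundsError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond sequence "
                f"end ({len(seq)})")
        sub = seq[iv.start:iv.end].upper()
        gc += sub.count("G") + sub.count("C")
        at += sub.count("A") + sub.count("T")
    if gc + at == 0:
        raise UndefinedValueError("no unambiguous bases in intervals")
    return gc / (gc + at)


class StateIndex:
    """Midpoint lookup over non-overlapping labeled state intervals."""

    def __init__(self, states: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        per_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in states:
            per_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in per_chrom.items():
            ivs = sorted(ivs, key=lambda x: x.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise AnnotationConflictError(
                        f"overlapping state intervals on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}")
            starts = np.array([iv.start for iv in ivs])
            ends = np.array([iv.end for iv in ivs])
            labels = [iv.label if iv.label is not None else "." for iv in ivs]
            self._by_chrom[chrom] = (starts, ends, labels)

    def assign(self, chrom: str, pos: int) -> str | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, labels = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return labels[i]
        return None

    def assign_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized midpoint assignment; unassigned positions get None."""
        out = np.full(len(positions), None, dtype=object)
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return out
        starts, ends, labels = entry
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        lab_arr = np.asarray(labels, dtype=object)
        out[ok] = lab_arr[idx[ok]]
        return out


def state_read_fractions(fragments_by_condition: Mapping[str, Sequence[FragmentRecord]],
                         states: Sequence[GenomicInterval],
                         ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-state read percentages per condition (midpoint assignment).

    Fragments falling in no state go to an "unannotated" bucket that is
    excluded from the 100% normalization; per-condition percentages over
    annotated states sum to 100.
    """
    index = StateIndex(states)
    state_order: dict[str, None] = {}
    for iv in states:
        state_order.setdefault(iv.label if iv.label is not None else ".", None)
    pct: dict[str, pd.Series] = {}
    unannotated: dict[str, int] = {}
    for cond, frags in fragments_by_condition.items():
        counts = dict.fromkeys(state_order, 0)
        n_un = 0
        by_chrom: dict[str, list[int]] = {}
        for f in frags:
            by_chrom.setdefault(f.interval.chrom, []).append(f.interval.midpoint)
        for chrom, mids in by_chrom.items():
            labels = index.assign_many(chrom, np.asarray(mids))
            tallied = Counter(labels)
            n_un += tallied.pop(None, 0)
            for lab, n in tallied.items():
                counts[lab] += n
        total = sum(counts.values())
        if total == 0:
            raise InsufficientDataError(
                f"no fragments assigned to any state for {cond!r}", count=0)
        pct[cond] = pd.Series({s: 100.0 * c / total for s, c in counts.items()})
        unannotated[cond] = n_un
    return pd.DataFrame(pct), unannotated


@dataclass
class StateRepresentation:
    """GC content and paired-condition read representation of one state."""

    state_label: str
    gc_fraction: float
    wt_read_pct: float
    tx_read_pct: float
    log2_ratio: float


@dataclass
class RegressionFit:
    """OLS fit of log2 representation ratio on GC content."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


def build_state_representations(genome: Mapping[str, str],
                                states: Sequence[GenomicInterval],
                                fragments_by_condition: Mapping[str, Sequence[FragmentRecord]],
                                conditions: tuple[str, str] = ("WT", "iH1.0"),
                                ) -> list[StateRepresentation]:
    """Assemble per-state GC + representation records for the regression."""
    pct, _ = state_read_fractions(fragments_by_condition, states)
    by_label: dict[str, list[GenomicInterval]] = {}
    for iv in states:
        by_label.setdefault(iv.label if iv.label is not None else ".", []).append(iv)
    out = []
    for label, ivs in by_label.items():
        gc = gc_content(genome, ivs)
        wt = float(pct.loc[label, conditions[0]])
        tx = float(pct.loc[label, conditions[1]])
        if wt == 0 or tx == 0:
            log.warning("state %r has zero reads in a condition; "
                        "dropped from regression", label)
            ratio = float("nan")
        else:
            ratio = math.log2(tx / wt)
        out.append(StateRepresentation(label, gc, wt, tx, ratio))
    return out


def representation_regression(reps: Sequence[StateRepresentation]) -> RegressionFit:
    """OLS of log2(treated/control representation) on state GC content."""
    pts = [(r.gc_fraction, r.log2_ratio) for r in reps
           if math.isfinite(r.log2_ratio)]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need >= 3 states with finite log2 ratio, got {len(pts)}",
            count=len(pts))
    x, y = map(np.asarray, zip(*pts))
    fit = stats.linregress(x, y)
    return RegressionFit(float(fit.slope), float(fit.intercept),
                         float(fit.rvalue**2), float(fit.pvalue), len(pts))


def representations_to_frame(reps: Sequence[StateRepresentation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "state": r.state_label, "gc_fraction": r.gc_fraction,
        "wt_read_pct": r.wt_read_pct, "tx_read_pct": r.tx_read_pct,
        "log2_ratio": r.log2_ratio,
    } for r in reps])
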