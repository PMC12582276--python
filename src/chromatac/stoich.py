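"""Histone stoichiometry and lineage-output metrics.

Small, exactly specified arithmetic on protein-abundance and flow-
cytometry summaries: linker-histone subtype share of the total H1 pool,
H1-per-nucleosome ratios anchored to core-histone abundances (two copies
of each of H2A/H2B/H3/H4 per octamer), the lymphoid/myeloid output ratio
(%B + %T over %myeloid), and plain fold changes. Abundances are assumed
already normalized for instrument response.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import IncompleteDataError, ParameterError, UndefinedValueError

log = logging.getLogger(__name__)

CORE_HISTONES = ("H2A", "H2B", "H3", "H4")
CORE_COPIES_PER_NUCLEOSOME = 2.0
CORE_DIVERGENCE_WARN = 0.2


@dataclass
class ProteinAbundanceTable:
    """Protein abundances (rows) by sample (columns) with role designations."""

    abundance: pd.DataFrame
    h1_subtypes: frozenset[str]
    core_histones: frozenset[str] = frozenset(CORE_HISTONES)

    def __post_init__(self):
        self.h1_subtypes = frozenset(self.h1_subtypes)
        self.core_histones = frozenset(self.core_histones)
        if self.h1_subtypes & self.core_histones:
            raise ParameterError("h1_subtypes and core_histones must be disjoint")
        if (self.abundance.to_numpy() < 0).any():
            raise ParameterError("abundances must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def _col(self, sample: str | None) -> pd.Series:
        if sample is None:
            if len(self.abundance.columns) != 1:
                raise ParameterError("sample must be named for multi-sample tables")
            return self.abundance.iloc[:, 0]
        return self.abundance[sample]


def percent_of_total_h1(table: ProteinAbundanceTable,
                        subtype: str,
                        sample: str | None = None) -> float:
    """Subtype abundance as a percentage of the summed H1 pool."""
    if subtype not in table.h1_subtypes:
        raise ParameterError(f"{subtype!r} is not a designated H1 subtype")
    col = table._col(sample)
    present = [s for s in table.h1_subtypes if s in col.index]
    total = float(col.loc[present].sum())
    if total <= 0:
        raise UndefinedValueError("total H1 abundance is zero")
    value = float(col.get(subtype, 0.0))
    return 100.0 * value / total


def h1_per_nucleosome(table: ProteinAbundanceTable,
                      subtype: str = "total",
                      sample: str | None = None) -> float:
    """H1 (one subtype or the whole pool) per nucleosome.

    The nucleosome count is the mean core-histone abundance divided by
    the two copies each core histone contributes per octamer; averaging
    the four cores damps per-protein quantification noise. Cores
    diverging by more than 20% trigger a logged warning.
    """
    col = table._col(sample)
    missing = [c for c in sorted(table.core_histones) if c not in col.index]
    if missing:
        raise IncompleteDataError(f"missing core histones: {missing}")
    cores = col.loc[sorted(table.core_histones)].astype(float)
    if (cores <= 0).any():
        raise IncompleteDataError("all core histones need abundance > 0")
    if cores.max() / cores.min() - 1.0 > CORE_DIVERGENCE_WARN:
        log.warning("core-histone abundances diverge by >20%% "
                    "(min %.3g, max %.3g)", cores.min(), cores.max())
    nucleosomes = cores.mean() / CORE_COPIES_PER_NUCLEOSOME
    if subtype == "total":
        h1 = float(col.loc[[s for s in table.h1_subtypes
                            if s in col.index]].sum())
    else:
        if subtype not in table.h1_subtypes:
            raise ParameterError(f"{subtype!r} is not a designated H1 subtype")
        h1 = float(col.get(subtype, 0.0))
    return h1 / float(nucleosomes)


@dataclass(frozen=True)
class LineageFractions:
    """Percent B, T and myeloid cells among donor-derived cells."""

    pct_b: float
    pct_t: float
    pct_myeloid: float

    def __post_init__(self):
        for name in ("pct_b", "pct_t", "pct_myeloid"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ParameterError(f"{name} must be in [0, 100], got {v}")


def lymphoid_myeloid_ratio(f: LineageFractions) -> float:
    """(%B + %T) / %myeloid."""
    if f.pct_myeloid == 0:
        raise UndefinedValueError("myeloid percentage is zero")
    return (f.pct_b + f.pct_t) / f.pct_myeloid


def fold_change(a: float, b: float) -> float:
    """Plain ratio a / b (e.g. colony counts between conditions)."""
    if b == 0:
        raise UndefinedValueError("denominator is zero")
    return a / b


def stoichiometry_summary(table: ProteinAbundanceTable) -> pd.DataFrame:
    """Per-sample percent-of-total-H1 and per-nucleosome ratios."""
    rows = []
    for sample in table.samples:
        for sub in sorted(table.h1_subtypes):
            if sub not in table.abundance.index:
                continue
            rows.append({
                "sample": sample, "subtype": sub,
                "pct_of_total_h1": percent_of_total_h1(table, sub, sample),
                "per_nucleosome": h1_per_nucleosome(table, sub, sample),
            })
        rows.append({
            "sample": sample, "subtype": "total",
            "pct_of_total_h1": 100.0,
            "per_nucleosome": h1_per_nucleosome(table, "total", sample),
        })
    return pd.DataFrame(rows)
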