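"""Tiered differential accessibility between two conditions.

Counts are normalized with median-of-ratios size factors, log2-transformed
with a pseudo-count, and tested per peak with a moderated two-sample t
statistic: per-peak pooled variances are shrunk toward a scaled
inverse-chi-square prior fitted across all peaks by the method of moments
on log variances (empirical-Bayes variance moderation in the limma
tradition), which stabilizes inference at 2-3 replicates per condition.
A plain per-peak Welch t is available as ``method="welch"``.

Calls are tiered with raw-P/fold-change cutoffs (relaxed: P < 0.01 and
fold > 2; stringent: P < 0.001 and fold > 4), ranked by significance then
effect size, and annotated with the genomic feature category of the peak
midpoint (promoter > 5'UTR > 3'UTR > exon > intron > distal).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import GenomicInterval, PeakCountTable
from .errors import FormatError, ParameterError, UndefinedValueError

log = logging.getLogger(__name__)

PSEUDO_COUNT = 0.5
PROMOTER_WINDOW_BP = 2000

RELAXED_P, RELAXED_FC = 0.01, 2.0
STRINGENT_P, STRINGENT_FC = 0.001, 4.0

FEATURE_PRECEDENCE = ("promoter", "5'UTR", "3'UTR", "exon", "intron", "distal")


# ---------------------------------------------------------------------------
# Normalization

def normalize_counts(table: PeakCountTable) -> tuple[np.ndarray, np.ndarray]:
    """Median-of-ratios size factors (geometric-mean reference).

    Falls back to total-count scaling (factors proportional to library
    size, mean 1) with a logged warning when no peak has all-positive
    counts.
    """
    counts = table.counts.astype(float)
    if np.any(counts.sum(axis=0) <= 0):
        raise ParameterError("every sample needs total count > 0")
    all_pos = np.all(counts > 0, axis=1)
    if not all_pos.any():
        log.warning("no peak with all-positive counts; "
                    "falling back to total-count size factors")
        totals = counts.sum(axis=0)
        factors = totals / totals.mean()
    else:
        sub = counts[all_pos]
        ref = np.exp(np.log(sub).mean(axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    return counts / factors, factors


# ---------------------------------------------------------------------------
# Testing

@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse-chi-square prior on per-peak log-scale variances."""

    d0: float      # prior degrees of freedom (inf = complete pooling)
    s0_sq: float   # prior variance
    df_residual: float
    # Total df available across all pooled peaks; the moderated t never
    # uses more df than this, even when d0 is infinite.
    df_pooled: float = float("inf")

    @property
    def df_total(self) -> float:
        return min(self.d0 + self.df_residual, self.df_pooled)


def fit_variance_prior(s_sq: np.ndarray, df: int) -> VariancePrior:
    """Method-of-moments fit on log variances (digamma/trigamma matching).

    Peaks with zero sample variance are excluded from the fit. When the
    spread of log variances is no larger than expected from chi-square
    sampling alone, the prior df is infinite (complete pooling).
    """
    s = s_sq[s_sq > 0]
    if len(s) < 2:
        return VariancePrior(float("inf"), float(np.mean(s_sq)) or 1e-8, df,
                             df * len(s_sq))
    e = np.log(s) - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(e.mean())
    rhs = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if rhs <= 0:
        # Infinite prior df: the pooled mean variance is the MLE of the scale.
        return VariancePrior(float("inf"), float(s.mean()), df, df * len(s_sq))
    half_d0 = optimize.brentq(
        lambda x: special.polygamma(1, x) - rhs, 1e-8, 1e8)
    s0_sq = float(np.exp(ebar + special.digamma(half_d0) - np.log(half_d0)))
    return VariancePrior(2.0 * half_d0, s0_sq, df, df * len(s_sq))


def moderate_variances(s_sq: np.ndarray, prior: VariancePrior) -> np.ndarray:
    """Posterior (shrunken) variances under the fitted prior."""
    if np.isinf(prior.d0):
        return np.full_like(s_sq, prior.s0_sq)
    return ((prior.d0 * prior.s0_sq + prior.df_residual * s_sq)
            / (prior.d0 + prior.df_residual))


def _log_matrix(normalized: np.ndarray, pseudo: float) -> np.ndarray:
    return np.log2(normalized + pseudo)


def test_peak(normalized_row: np.ndarray,
              tx_idx: np.ndarray,
              wt_idx: np.ndarray,
              pseudo: float = PSEUDO_COUNT,
              prior: VariancePrior | None = None) -> tuple[float, float]:
    """(log2 fold change, p value) for one peak.

    log2FC compares mean normalized counts (treated vs control) with a
    pseudo-count. With a fitted :class:`VariancePrior` the p value comes
    from the moderated t; without one, from a plain Welch t on the log2
    replicate values. An all-zero peak returns (0, 1).
    """
    row = np.asarray(normalized_row, dtype=float)
    tx, wt = row[tx_idx], row[wt_idx]
    if np.all(row == 0):
        return 0.0, 1.0
    l2fc = float(np.log2(tx.mean() + pseudo) - np.log2(wt.mean() + pseudo))
    ltx, lwt = np.log2(tx + pseudo), np.log2(wt + pseudo)
    n1, n2 = len(ltx), len(lwt)
    if prior is not None:
        df = n1 + n2 - 2
        s_sq = ((n1 - 1) * ltx.var(ddof=1) + (n2 - 1) * lwt.var(ddof=1)) / df
        s_post = moderate_variances(np.array([s_sq]), prior)[0]
        se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
        diff = ltx.mean() - lwt.mean()
        if se == 0:
            return l2fc, (1.0 if diff == 0 else 0.0)
        t = diff / se
        df_total = prior.df_total
        p = (2.0 * stats.norm.sf(abs(t)) if np.isinf(df_total)
             else 2.0 * stats.t.sf(abs(t), df_total))
        return l2fc, float(p)
    vtx, vwt = ltx.var(ddof=1), lwt.var(ddof=1)
    if vtx == 0 and vwt == 0:
        return l2fc, (1.0 if ltx.mean() == lwt.mean() else 0.0)
    res = stats.ttest_ind(ltx, lwt, equal_var=False)
    return l2fc, float(res.pvalue)


def test_all_peaks(table: PeakCountTable,
                   conditions: tuple[str, str] = ("WT", "iH1.0"),
                   pseudo: float = PSEUDO_COUNT,
                   method: str = "moderated") -> pd.DataFrame:
    """Normalize and test every peak; vectorized over the whole table.

    Returns a DataFrame with ``log2_fc``, ``p_value`` and ``p_adj``
    (Benjamini-Hochberg) indexed in peak order.
    """
    if method not in ("moderated", "welch"):
        raise ParameterError("method must be 'moderated' or 'welch'")
    wt_idx = table.sample_indices(conditions[0])
    tx_idx = table.sample_indices(conditions[1])
    if len(wt_idx) < 2 or len(tx_idx) < 2:
        raise ParameterError("need >= 2 replicates per condition")
    normalized, _ = normalize_counts(table)
    lmat = _log_matrix(normalized, pseudo)
    ltx, lwt = lmat[:, tx_idx], lmat[:, wt_idx]
    n1, n2 = ltx.shape[1], lwt.shape[1]
    l2fc = (np.log2(normalized[:, tx_idx].mean(axis=1) + pseudo)
            - np.log2(normalized[:, wt_idx].mean(axis=1) + pseudo))
    diff = ltx.mean(axis=1) - lwt.mean(axis=1)
    if method == "moderated":
        df = n1 + n2 - 2
        s_sq = ((n1 - 1) * ltx.var(axis=1, ddof=1)
                + (n2 - 1) * lwt.var(axis=1, ddof=1)) / df
        prior = fit_variance_prior(s_sq, df)
        s_post = moderate_variances(s_sq, prior)
        se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        df_total = prior.df_total
        p = (2.0 * stats.norm.sf(np.abs(t)) if np.isinf(df_total)
             else 2.0 * stats.t.sf(np.abs(t), df_total))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(ltx, lwt, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), np.where(diff == 0, 1.0, 0.0), p)
    all_zero = np.all(table.counts == 0, axis=1)
    p[all_zero] = 1.0
    l2fc[all_zero] = 0.0
    p_adj = _bh_adjust(p)
    return pd.DataFrame({"log2_fc": l2fc, "p_value": p, "p_adj": p_adj})


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Tiering / ranking

def apply_tiers(results: pd.DataFrame,
                relaxed=(RELAXED_P, RELAXED_FC),
                stringent=(STRINGENT_P, STRINGENT_FC)) -> pd.DataFrame:
    """Add ``tier`` (none/relaxed/stringent) and ``direction`` columns.

    A tier requires p below its cutoff AND linear fold change above its
    cutoff (fold > 2 means |log2FC| > 1). Stringent calls are a subset of
    relaxed by construction. Direction is open/closed by the sign of the
    treated-vs-control log2FC, ``none`` for untiered peaks.
    """
    out = results.copy()
    abs_l2 = out["log2_fc"].abs()
    rel = (out["p_value"] < relaxed[0]) & (abs_l2 > np.log2(relaxed[1]))
    stri = (out["p_value"] < stringent[0]) & (abs_l2 > np.log2(stringent[1]))
    stri &= rel  # guarantee set inclusion even with unusual custom cutoffs
    out["tier"] = np.where(stri, "stringent", np.where(rel, "relaxed", "none"))
    direction = np.where(out["log2_fc"] > 0, "open",
                         np.where(out["log2_fc"] < 0, "closed", "none"))
    out["direction"] = np.where(out["tier"] == "none", "none", direction)
    return out


def rank_results(results: pd.DataFrame,
                 peaks: list[GenomicInterval] | None = None) -> pd.DataFrame:
    """Rank peaks: ascending p, then descending |log2FC|, then genomic order.

    Rank 1 is the strongest call. Adds a ``rank`` column; row order is
    unchanged.
    """
    out = results.copy()
    abs_l2 = out["log2_fc"].abs().to_numpy()
    if peaks is not None:
        chroms = np.array([p.chrom for p in peaks])
        starts = np.array([p.start for p in peaks])
    else:
        chroms = np.zeros(len(out))
        starts = np.arange(len(out))
    order = np.lexsort((starts, chroms, -abs_l2, out["p_value"].to_numpy()))
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return out


# ---------------------------------------------------------------------------
# Feature annotation

@dataclass(frozen=True)
class Transcript:
    """A gene model entry: exon blocks plus CDS bounds, stranded."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


def _categorize_in_transcript(pos: int, t: Transcript,
                              promoter_bp: int) -> str | None:
    """Feature category of a position w.r.t. one transcript, or None."""
    if abs(pos - t.tss) <= promoter_bp:
        return "promoter"
    if not (t.start <= pos < t.end):
        return None
    in_exon = any(s <= pos < e for s, e in t.exons)
    if not in_exon:
        return "intron"
    if t.cds_start >= t.cds_end:  # non-coding transcript: plain exon
        return "exon"
    if pos < t.cds_start:
        return "5'UTR" if t.strand == "+" else "3'UTR"
    if pos >= t.cds_end:
        return "3'UTR" if t.strand == "+" else "5'UTR"
    return "exon"


def annotate_feature(peak: GenomicInterval,
                     transcripts: list[Transcript],
                     promoter_bp: int = PROMOTER_WINDOW_BP) -> str:
    """Feature category of the peak midpoint against a gene model.

    Precedence: promoter > 5'UTR > 3'UTR > exon > intron > distal, with
    the promoter a strand-aware ``TSS +/- promoter_bp`` window.
    """
    pos = peak.midpoint
    best = len(FEATURE_PRECEDENCE) - 1  # distal
    for t in transcripts:
        if t.chrom != peak.chrom:
            continue
        cat = _categorize_in_transcript(pos, t, promoter_bp)
        if cat is not None:
            best = min(best, FEATURE_PRECEDENCE.index(cat))
    return FEATURE_PRECEDENCE[best]


def normalize_to_reference(region_signal: float,
                           reference_signal: float) -> float:
    """Accessibility of a region relative to a reference region."""
    if reference_signal <= 0:
        raise UndefinedValueError("reference signal must be > 0")
    return region_signal / reference_signal


# ---------------------------------------------------------------------------
# Full pipeline

def run_da(table: PeakCountTable,
           conditions: tuple[str, str] = ("WT", "iH1.0"),
           gene_model: list[Transcript] | None = None,
           method: str = "moderated",
           pseudo: float = PSEUDO_COUNT,
           promoter_bp: int = PROMOTER_WINDOW_BP) -> pd.DataFrame:
    """Normalize, test, tier, rank and annotate every peak.

    Returns one row per peak: coordinates, log2_fc, p_value, p_adj, tier,
    direction, rank and feature (``distal`` when no gene model given).
    """
    res = test_all_peaks(table, conditions, pseudo, method)
    res = apply_tiers(res)
    res = rank_results(res, table.peaks)
    res.insert(0, "peak_id", [p.label if p.label is not None else f"peak_{i}"
                              for i, p in enumerate(table.peaks)])
    res.insert(1, "chrom", [p.chrom for p in table.peaks])
    res.insert(2, "start", [p.start for p in table.peaks])
    res.insert(3, "end", [p.end for p in table.peaks])
    if gene_model is not None:
        res["feature"] = [annotate_feature(p, gene_model, promoter_bp)
                          for p in table.peaks]
    else:
        res["feature"] = "distal"
    return res


def tier_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Counts by tier x direction (stringent counted inside relaxed too)."""
    rows = []
    for tier, pcut, fcut in (("relaxed", RELAXED_P, RELAXED_FC),
                             ("stringent", STRINGENT_P, STRINGENT_FC)):
        in_tier = ((results["p_value"] < pcut)
                   & (results["log2_fc"].abs() > np.log2(fcut)))
        for direction, sign in (("open", 1), ("closed", -1)):
            n = int((in_tier & (np.sign(results["log2_fc"]) == sign)).sum())
            rows.append({"tier": tier, "direction": direction, "n_peaks": n})
    return pd.DataFrame(rows)
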