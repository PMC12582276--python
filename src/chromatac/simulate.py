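"""Synthetic-data generator with known ground truth.

Emulates the structure of a chromatin-state-stratified ATAC experiment:

* fragment-length mixtures with a nucleosome ladder (mono/di/tri peaks at
  ``core_bp + (k-1)*period_bp``) over a sub-nucleosomal exponential
  background,
* a genome tiled by chromatin-state blocks with controlled per-state GC,
* GC-dependent read-representation bias between conditions,
* negative-binomially dispersed peak-count tables with planted
  differential accessibility, and
* protein-abundance tables anchored to core-histone stoichiometry
  (two copies each of H2A/H2B/H3/H4 per nucleosome).

All randomness flows through explicit integer seeds; identical seeds give
bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import FragmentRecord, GenomicInterval, PeakCountTable
from .errors import ParameterError

DEFAULT_CONDITIONS = ("WT", "iH1.0")


@dataclass(frozen=True)
class FragmentSimParams:
    """Parameters of the fragment-length mixture for one stratum.

    The periodic component is a mixture of Gaussians centred at
    ``core_bp + (k-1)*period_bp`` for ladder orders ``k = 1..n_orders``
    with geometric weights ``order_decay**(k-1)``; the remaining
    ``1 - periodic_fraction`` of fragments come from an exponential
    background truncated below at 1 bp.
    """

    period_bp: float = 190.0
    core_bp: float = 147.0
    n_orders: int = 3
    peak_sd_bp: float = 15.0
    order_decay: float = 0.5
    periodic_fraction: float = 0.6
    background_scale_bp: float = 60.0
    n_fragments: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if self.period_bp < self.core_bp:
            raise ParameterError("period_bp must be >= core_bp")
        if not (0.0 <= self.periodic_fraction <= 1.0):
            raise ParameterError("periodic_fraction must be in [0, 1]")
        if self.n_orders < 1:
            raise ParameterError("n_orders must be >= 1")
        if not (0.0 < self.order_decay < 1.0):
            raise ParameterError("order_decay must be in (0, 1)")
        if self.peak_sd_bp < 0:
            raise ParameterError("peak_sd_bp must be >= 0")
        if self.background_scale_bp <= 0:
            raise ParameterError("background_scale_bp must be > 0")
        if self.n_fragments < 0:
            raise ParameterError("n_fragments must be >= 0")


@dataclass(frozen=True)
class StateSimSpec:
    """One simulated chromatin state: fragment model per condition + GC."""

    state_label: str
    wt_params: FragmentSimParams
    tx_params: FragmentSimParams
    gc_fraction: float = 0.45
    genome_share: float = 1.0

    def validate(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ParameterError("gc_fraction must be in [0, 1]")
        if self.genome_share <= 0:
            raise ParameterError("genome_share must be > 0")
        self.wt_params.validate()
        self.tx_params.validate()


@dataclass(frozen=True)
class CountSimParams:
    """Negative-binomial peak-count simulation with planted effects.

    ``planted`` holds ``(peak_index, true_fold_change, direction)`` where
    direction ``"open"`` multiplies the treated-condition mean by the fold
    and ``"closed"`` divides it. ``dispersion`` is the NB dispersion alpha
    (variance = mean + alpha * mean**2); alpha = 0 gives Poisson counts.
    """

    n_peaks: int = 32_000
    n_reps_per_condition: int = 3
    mean_depth: float = 100.0
    dispersion: float = 0.05
    planted: tuple[tuple[int, float, str], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_peaks < len(self.planted):
            raise ParameterError("n_peaks must be >= number of planted peaks")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be > 0")
        if self.n_reps_per_condition < 1:
            raise ParameterError("n_reps_per_condition must be >= 1")
        for idx, fold, direction in self.planted:
            if not (0 <= idx < self.n_peaks):
                raise ParameterError(f"planted index {idx} out of range")
            if fold <= 0:
                raise ParameterError("planted fold change must be > 0")
            if direction not in ("open", "closed"):
                raise ParameterError("direction must be 'open' or 'closed'")


def simulate_fragment_lengths(params: FragmentSimParams) -> np.ndarray:
    """Draw fragment lengths (bp, continuous, all >= 1) from the mixture."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_fragments
    n_periodic = rng.binomial(n, params.periodic_fraction)
    weights = params.order_decay ** np.arange(params.n_orders)
    weights = weights / weights.sum()
    orders = rng.choice(params.n_orders, size=n_periodic, p=weights)
    centers = params.core_bp + orders * params.period_bp
    ladder = rng.normal(centers, params.peak_sd_bp)
    # background: exponential truncated below at 1 bp (inverse-CDF sample)
    u = rng.random(n - n_periodic)
    background = 1.0 - params.background_scale_bp * np.log1p(-u)
    lengths = np.concatenate([ladder, background])
    return np.clip(lengths, 1.0, None)


def apply_gc_bias(state_fractions: dict[str, float],
                  gc_by_state: dict[str, float],
                  slope: float) -> dict[str, float]:
    """Reweight state read fractions by an exponential GC bias.

    New fraction is proportional to ``old * exp(slope * (gc - mean_gc))``,
    renormalized to sum to 1. Positive slope over-represents GC-rich states.
    """
    if not state_fractions:
        raise ParameterError("state_fractions must be nonempty")
    if set(state_fractions) - set(gc_by_state):
        raise ParameterError("every state needs a GC value")
    total = sum(state_fractions.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ParameterError("state fractions must sum to 1")
    gcs = {s: gc_by_state[s] for s in state_fractions}
    for s, g in gcs.items():
        if not (0.0 <= g <= 1.0):
            raise ParameterError(f"gc for state {s!r} not in [0, 1]")
    mean_gc = np.mean(list(gcs.values()))
    raw = {s: f * np.exp(slope * (gcs[s] - mean_gc))
           for s, f in state_fractions.items()}
    z = sum(raw.values())
    return {s: v / z for s, v in raw.items()}


def _random_sequence(length: int, gc_fraction: float,
                     rng: np.random.Generator) -> str:
    """Sequence with an exact G+C count of round(gc_fraction * length)."""
    n_gc = int(round(gc_fraction * length))
    n_at = length - n_gc
    letters = np.empty(length, dtype="U1")
    letters[: n_gc // 2] = "G"
    letters[n_gc // 2: n_gc] = "C"
    letters[n_gc: n_gc + n_at // 2] = "A"
    letters[n_gc + n_at // 2:] = "T"
    rng.shuffle(letters)
    return "".join(letters)


@dataclass
class SimulatedStateDataset:
    """Bundle of all per-state simulation outputs plus generating truth."""

    genome: dict[str, str]
    states: list[GenomicInterval]
    fragments: dict[str, list[FragmentRecord]]
    specs: list[StateSimSpec] = field(default_factory=list)


def simulate_state_dataset(specs: list[StateSimSpec],
                           chrom_length: int,
                           seed: int,
                           n_fragments_per_condition: int = 100_000,
                           conditions: tuple[str, str] = DEFAULT_CONDITIONS,
                           gc_bias_slope: dict[str, float] | None = None,
                           chrom: str = "chrSim") -> SimulatedStateDataset:
    """Simulate genome, state annotation and per-condition fragment sets.

    States tile the chromosome contiguously in proportion to their
    ``genome_share``; each block's sequence hits the state's target GC
    exactly (to rounding). Fragments are allocated to states by share,
    optionally reweighted per condition by :func:`apply_gc_bias`, placed
    uniformly within state blocks.
    """
    if not specs:
        raise ParameterError("specs must be nonempty")
    for sp in specs:
        sp.validate()
    shares = np.array([sp.genome_share for sp in specs], dtype=float)
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ParameterError(f"genome shares sum to {shares.sum()}, not 1")
    bounds = np.round(np.concatenate([[0.0], np.cumsum(shares)]) * chrom_length)
    bounds = bounds.astype(int)
    bounds[-1] = chrom_length
    if np.any(np.diff(bounds) < 1000):
        raise ParameterError("chrom_length too small: every state needs >= 1 kb")

    ss = np.random.SeedSequence(seed)
    seq_rng = np.random.default_rng(ss.spawn(1)[0])
    blocks, states = [], []
    for sp, s0, s1 in zip(specs, bounds[:-1], bounds[1:]):
        blocks.append(_random_sequence(s1 - s0, sp.gc_fraction, seq_rng))
        states.append(GenomicInterval(chrom, int(s0), int(s1), sp.state_label))
    genome = {chrom: "".join(blocks)}

    gc_by_state = {sp.state_label: sp.gc_fraction for sp in specs}
    base_fracs = {sp.state_label: float(sh) for sp, sh in zip(specs, shares)}
    slopes = gc_bias_slope or {}

    fragments: dict[str, list[FragmentRecord]] = {}
    for ci, cond in enumerate(conditions):
        cond_rng = np.random.default_rng(ss.spawn(1)[0])
        fracs = apply_gc_bias(base_fracs, gc_by_state, slopes.get(cond, 0.0))
        alloc = cond_rng.multinomial(
            n_fragments_per_condition,
            [fracs[sp.state_label] for sp in specs])
        recs: list[FragmentRecord] = []
        for sp, n_st, s0, s1 in zip(specs, alloc, bounds[:-1], bounds[1:]):
            params = sp.tx_params if ci == 1 else sp.wt_params
            child = int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31))
            lens = simulate_fragment_lengths(
                replace(params, n_fragments=int(n_st), seed=child))
            ilens = np.maximum(np.round(lens).astype(int), 1)
            ilens = np.minimum(ilens, s1 - s0)  # fragment must fit its block
            starts = s0 + np.floor(
                cond_rng.random(len(ilens)) * (s1 - s0 - ilens + 1)).astype(int)
            sample = f"{cond}_1"
            recs.extend(
                FragmentRecord(GenomicInterval(chrom, int(a), int(a + l)),
                               sample, cond)
                for a, l in zip(starts, ilens))
        fragments[cond] = recs
    return SimulatedStateDataset(genome, states, fragments, list(specs))


def simulate_peak_counts(params: CountSimParams,
                         conditions: tuple[str, str] = DEFAULT_CONDITIONS,
                         peak_width: int = 500,
                         peak_spacing: int = 1000,
                         chrom: str = "chrPeaks",
                         ) -> tuple[PeakCountTable, pd.DataFrame]:
    """Simulate an NB-dispersed peak-count table with planted effects.

    Returns the count table and a truth table (one row per planted peak:
    ``peak_index, true_fold, direction``).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_reps = params.n_reps_per_condition
    wt_mean = np.full(params.n_peaks, params.mean_depth)
    tx_mean = wt_mean.copy()
    for idx, fold, direction in params.planted:
        tx_mean[idx] = (params.mean_depth * fold if direction == "open"
                        else params.mean_depth / fold)

    def draw(mean_vec: np.ndarray) -> np.ndarray:
        m = np.repeat(mean_vec[:, None], n_reps, axis=1)
        if params.dispersion == 0:
            return rng.poisson(m)
        r = 1.0 / params.dispersion
        p = r / (r + m)
        return rng.negative_binomial(r, p)

    counts = np.hstack([draw(wt_mean), draw(tx_mean)])
    samples = [f"{conditions[0]}_{i + 1}" for i in range(n_reps)] + \
              [f"{conditions[1]}_{i + 1}" for i in range(n_reps)]
    condition_of = {s: (conditions[0] if i < n_reps else conditions[1])
                    for i, s in enumerate(samples)}
    peaks = [GenomicInterval(chrom, i * peak_spacing,
                             i * peak_spacing + peak_width, f"peak_{i}")
             for i in range(params.n_peaks)]
    truth = pd.DataFrame(
        [(idx, fold, direction) for idx, fold, direction in params.planted],
        columns=["peak_index", "true_fold", "direction"])
    return PeakCountTable(peaks, counts, samples, condition_of), truth


def simulate_abundance_table(subtype_fractions: dict[str, float],
                             h1_per_nucleosome: float,
                             noise_cv: float,
                             seed: int,
                             sample: str = "S1",
                             core_histones: tuple[str, ...] = ("H2A", "H2B", "H3", "H4"),
                             ) -> "ProteinAbundanceTable":
    """Simulate an LC-MS-style protein-abundance table for one sample.

    Core histones sit at 2 units per nucleosome each; total H1 at
    ``h1_per_nucleosome`` units per nucleosome, split across subtypes by
    ``subtype_fractions``. Multiplicative lognormal noise with coefficient
    of variation ``noise_cv`` (mean-1) is applied to every abundance.
    """
    from .stoich import ProteinAbundanceTable

    fracs = dict(subtype_fractions)
    if not fracs:
        raise ParameterError("subtype_fractions must be nonempty")
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ParameterError("subtype fractions must sum to 1")
    if h1_per_nucleosome < 0:
        raise ParameterError("h1_per_nucleosome must be >= 0")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    values = {h: 2.0 for h in core_histones}
    values.update({sub: h1_per_nucleosome * f for sub, f in fracs.items()})
    names = list(values)
    arr = np.array([values[n] for n in names], dtype=float)
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        noise = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), len(arr))
        arr = arr * noise
    df = pd.DataFrame({sample: arr}, index=pd.Index(names, name="protein"))
    return ProteinAbundanceTable(df, frozenset(fracs), frozenset(core_histones))
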