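# chromatac

Chromatin-state-stratified analysis of accessibility fragment data under
linker-histone perturbation, with a fully synthetic data generator for
desk-scale validation.

## Scientific problem

Linker histone H1 binds nucleosomes at the DNA dyad and compacts
chromatin. Overexpressing an H1 isoform in stem and progenitor cells is
expected to reorganize chromatin genome-wide: nucleosome arrays become
more regular, their repeat length changes, and many regulatory regions
lose accessibility. Three questions recur when analyzing such an
experiment from accessibility (ATAC-style) sequencing:

1. **Nucleosome spacing.** The fragment-length distribution carries a
   mono/di/tri-nucleosomal ladder; the spacing of its peaks estimates the
   nucleosome repeat length (NRL). How does the NRL, and the strength of
   the ladder, change per chromatin state when H1 is overexpressed?
2. **Differential accessibility.** Which regions gain or lose reads, at
   defensible error rates, with only 2–3 replicates per condition?
3. **Stoichiometry.** How much of the total linker-histone pool does the
   induced isoform reach, per nucleosome?

Real answers require large sequencing datasets. This package instead
implements the full analysis stack *plus* a parametric generator of
synthetic genomes, fragments, counts and abundance tables, so every
method can be validated against planted ground truth on a laptop.

## Core model

- **Fragment lengths** in one (state, condition) stratum are a mixture:
  a periodic component of Gaussians centered at
  `core + (k−1)·period` for ladder orders `k = 1..3` with geometric
  weights, and an exponential sub-nucleosomal background.
- **NRL** is the ordinary-least-squares slope of detected ladder-peak
  center on ladder order — invariant to a constant offset of all peaks
  and exact when the ladder is exact.
- **Repeat strength** is a bounded spectral score: the fraction of
  structured spectral power falling in the nucleosomal period band
  (150–250 bp), computed over the nucleosomal length region.
- **State typing** classifies each state's (control, treated) strength
  pair as Type A (no signal in either), Type B (weak signal that does
  not weaken, typically with a ~4 bp NRL increase) or Type C (de novo
  strong ladder).
- **Differential accessibility** uses median-of-ratios normalization,
  log2 counts with a pseudo-count, and an empirical-Bayes moderated t
  statistic (per-peak variances shrunk toward a fitted scaled
  inverse-chi-square prior), tiered at relaxed (P < 0.01, fold > 2) and
  stringent (P < 0.001, fold > 4) cutoffs.
- **Stoichiometry** reads a protein-abundance table: percent of total
  H1 per subtype, and H1 per nucleosome as subtype abundance over the
  mean of the four core histones divided by two.

See `docs/methods.md` for assumptions, calibrations and limitations.

## Worked example

Simulate a strongly ordered stratum and recover its repeat length:

```python
from chromatac.simulate import FragmentSimParams, simulate_fragment_lengths
from chromatac.nrl import profile_stratum

lengths = simulate_fragment_lengths(FragmentSimParams(
    period_bp=190.0, periodic_fraction=0.6, n_fragments=200_000, seed=1))
prof = profile_stratum(lengths)
print(prof.nrl_bp, round(prof.strength, 3))
```

prints

```
190.5 0.328
```

The full narrative analysis lives in `analysis/` and runs in order:

```bash
python analysis/01_simulate_dataset.py
python analysis/02_nrl_profiles.py
python analysis/03_type_states.py
python analysis/04_gc_representation.py
python analysis/05_differential_accessibility.py
python analysis/06_stoichiometry.py
```

On the shipped configuration (seed 20) this produces, among others:

- `02` — the weak-ladder state's NRL rises from 186.0 bp (control) to
  190.0 bp (treated); the de-novo-ordered state has no detectable ladder
  in control and a 190.0 bp ladder with strength 0.360 after treatment.
- `03` — the three simulated states classify as exactly one Type A, one
  Type B (ΔNRL = 4.0 bp) and one Type C.
- `04` — the planted treated-condition GC bias is recovered as a
  positive representation slope (2.198 per GC unit, r² = 1.000 on
  3 states).
- `05` — all 320 planted effects are recovered at the stringent tier:
  242 closed and 78 open, with no false stringent calls.
- `06` — the induced subtype rises from 1.30% to 18.00% of total H1
  (13.8-fold), with total H1 per nucleosome 0.50 → 0.58.

The same pipeline is exposed as a CLI
(`chromatac simulate | nrl | type-states | gc-rep | da | stoich`);
run `chromatac --help` for the flags.

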