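"""Generate the synthetic study dataset.

Writes genome, chromatin-state annotation, per-condition fragment sets, a
peak-count table with planted accessibility effects, and a linker-histone
abundance table under ``results/data/``.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import study_config as cfg  # noqa: E402

from chromatac import io as cio  # noqa: E402
from chromatac.io import write_abundance_tsv  # noqa: E402
from chromatac.simulate import (CountSimParams, simulate_abundance_table,  # noqa: E402
                                simulate_peak_counts, simulate_state_dataset)


def main() -> None:
    out = cfg.DATA_DIR
    out.mkdir(parents=True, exist_ok=True)

    ds = simulate_state_dataset(
        cfg.STATE_SPECS, chrom_length=cfg.CHROM_LENGTH, seed=cfg.SEED,
        n_fragments_per_condition=cfg.N_FRAGMENTS_PER_CONDITION,
        conditions=cfg.CONDITIONS, gc_bias_slope=cfg.GC_BIAS_SLOPE)
    cio.write_fasta(out / "genome.fa", ds.genome)
    cio.write_bed(out / "states.bed", ds.states)
    for cond, frags in ds.fragments.items():
        cio.write_fragments(out / f"fragments_{cond}.bed", frags)
    print(f"genome: {sum(len(s) for s in ds.genome.values()):,} bp, "
          f"{len(ds.states)} state blocks")
    for cond, frags in ds.fragments.items():
        print(f"fragments [{cond}]: {len(frags):,}")

    planted = tuple((i, cfg.PLANTED_FOLD, "closed")
                    for i in range(cfg.N_PLANTED_CLOSED)) + \
        tuple((i, cfg.PLANTED_FOLD, "open")
              for i in range(cfg.N_PLANTED_CLOSED,
                             cfg.N_PLANTED_CLOSED + cfg.N_PLANTED_OPEN))
    table, truth = simulate_peak_counts(CountSimParams(
        n_peaks=cfg.N_PEAKS, n_reps_per_condition=3,
        mean_depth=cfg.MEAN_DEPTH, dispersion=cfg.DISPERSION,
        planted=planted, seed=cfg.SEED), conditions=cfg.CONDITIONS)
    cio.write_count_table(out / "peak_counts.tsv", table)
    truth.to_csv(out / "planted_truth.tsv", sep="\t", index=False)
    print(f"peak counts: {cfg.N_PEAKS:,} peaks x {len(table.samples)} "
          f"samples, {len(planted)} planted effects")

    frames = []
    for i, (cond, (fracs, per_nuc)) in enumerate(
            cfg.ABUNDANCE_SCENARIO.items()):
        t = simulate_abundance_table(fracs, per_nuc, noise_cv=0.0,
                                     seed=cfg.SEED + i, sample=cond)
        frames.append(t.abundance)
    abundance = frames[0].join(frames[1:])
    write_abundance_tsv(out / "abundance.tsv", abundance)
    print(f"abundance table: {abundance.shape[0]} proteins x "
          f"{abundance.shape[1]} samples")


if __name__ == "__main__":
    main()
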