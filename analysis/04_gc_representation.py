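"""Per-state GC content vs read-representation shift.

Reads genome, states and fragments from 01; writes the per-state
representation table and the GC-vs-log2-ratio regression.
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import study_config as cfg  # noqa: E402

from chromatac import io as cio  # noqa: E402
from chromatac.gcrep import (build_state_representations,  # noqa: E402
                             representation_regression,
                             representations_to_frame)


def main() -> None:
    genome = cio.read_fasta(cfg.DATA_DIR / "genome.fa")
    states = cio.read_bed(cfg.DATA_DIR / "states.bed", expected_columns=4)
    frags = {
        cond: cio.read_fragments(cfg.DATA_DIR / f"fragments_{cond}.bed",
                                 sample=f"{cond}_1", condition=cond)
        for cond in cfg.CONDITIONS}
    reps = build_state_representations(genome, states, frags, cfg.CONDITIONS)
    frame = representations_to_frame(reps)
    frame.to_csv(cfg.RESULTS_DIR / "state_representation.tsv",
                 sep="\t", index=False)
    fit = representation_regression(reps)
    pd.DataFrame([{
        "slope": fit.slope, "intercept": fit.intercept,
        "r_squared": fit.r_squared, "p_value": fit.p_value,
        "n_points": fit.n_points,
    }]).to_csv(cfg.RESULTS_DIR / "gc_regression.tsv", sep="\t", index=False)
    print(frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"\nregression: slope={fit.slope:.3f} "
          f"r2={fit.r_squared:.3f} p={fit.p_value:.3g} n={fit.n_points}")


if __name__ == "__main__":
    main()
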