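"""Per-(state, condition) NRL and repeat-strength profiles.

Reads the fragment sets and state annotation from 01, assigns fragments to
states by midpoint, and writes ``results/nrl_profiles.tsv``.
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import study_config as cfg  # noqa: E402

from chromatac import io as cio  # noqa: E402
from chromatac.gcrep import StateIndex  # noqa: E402
from chromatac.nrl import profile_stratum  # noqa: E402


def main() -> None:
    states = cio.read_bed(cfg.DATA_DIR / "states.bed", expected_columns=4)
    index = StateIndex(states)
    rows = []
    for cond in cfg.CONDITIONS:
        frags = cio.read_fragments(cfg.DATA_DIR / f"fragments_{cond}.bed",
                                   sample=f"{cond}_1", condition=cond)
        by_state: dict[str, list] = {}
        for f in frags:
            label = index.assign(f.interval.chrom, f.interval.midpoint)
            if label is not None:
                by_state.setdefault(label, []).append(f)
        for state, sub in sorted(by_state.items()):
            prof = profile_stratum(sub, state, cond)
            rows.append({
                "state": state, "condition": cond,
                "n_fragments": prof.n_fragments,
                "nrl_bp": prof.nrl_bp,
                "nrl_stderr_bp": prof.nrl_stderr_bp,
                "strength": prof.strength,
            })
    df = pd.DataFrame(rows)
    out = cfg.RESULTS_DIR / "nrl_profiles.tsv"
    df.to_csv(out, sep="\t", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
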