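"""Type A/B/C classification of the state periodicity responses.

Reads ``results/nrl_profiles.tsv`` from 02 and writes the per-state calls
and the type summary.
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import study_config as cfg  # noqa: E402

from chromatac.nrl import PeriodicityProfile  # noqa: E402
from chromatac.state_types import (TypingThresholds, calls_to_frame,  # noqa: E402
                                   classify_all)


def main() -> None:
    df = pd.read_csv(cfg.RESULTS_DIR / "nrl_profiles.tsv", sep="\t")
    profiles = {}
    for r in df.itertuples():
        profiles[(r.state, r.condition)] = PeriodicityProfile(
            peak_centers=np.array([]), peak_orders=np.array([]),
            nrl_bp=float(r.nrl_bp), nrl_stderr_bp=float(r.nrl_stderr_bp),
            strength=float(r.strength), stratum=(r.state, r.condition),
            n_fragments=int(r.n_fragments))
    calls, summary = classify_all(profiles, TypingThresholds(),
                                  cfg.CONDITIONS)
    frame = calls_to_frame(calls)
    frame.to_csv(cfg.RESULTS_DIR / "state_type_calls.tsv",
                 sep="\t", index=False)
    summary.to_csv(cfg.RESULTS_DIR / "state_type_summary.tsv",
                   sep="\t", index=False)
    print(frame.to_string(index=False))
    print()
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
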