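"""Shared study configuration and paths for the numbered analysis scripts.

Run the scripts in order; each reads what the previous ones wrote under
``results/``. All randomness is seeded here.
"""
from pathlib import Path

from chromatac.simulate import FragmentSimParams, StateSimSpec

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

SEED = 20

CONDITIONS = ("WT", "iH1.0")
CHROM_LENGTH = 1_000_000
N_FRAGMENTS_PER_CONDITION = 150_000

# Three chromatin states spanning the qualitative response categories:
# open chromatin with no repeat signal in either condition (expected Type A),
# a weak ladder that strengthens and lengthens by ~4 bp (Type B), and
# de novo strong ordering at a 190 bp repeat (Type C).
STATE_SPECS = [
    StateSimSpec(
        "open_chromatin",
        wt_params=FragmentSimParams(periodic_fraction=0.0),
        tx_params=FragmentSimParams(periodic_fraction=0.0),
        gc_fraction=0.55, genome_share=0.3),
    StateSimSpec(
        "weak_ladder",
        wt_params=FragmentSimParams(periodic_fraction=0.30, period_bp=186.0),
        tx_params=FragmentSimParams(periodic_fraction=0.40, period_bp=190.0),
        gc_fraction=0.45, genome_share=0.3),
    StateSimSpec(
        "de_novo_ordered",
        wt_params=FragmentSimParams(periodic_fraction=0.0),
        tx_params=FragmentSimParams(periodic_fraction=0.70, period_bp=190.0),
        gc_fraction=0.35, genome_share=0.4),
]

# Mild treated-condition GC bias planted for the representation regression.
GC_BIAS_SLOPE = {"iH1.0": 1.5}

# Peak-count simulation: saturating planted effects at the stringent-tier
# closing/opening region counts.
N_PEAKS = 32_000
N_PLANTED_CLOSED = 242
N_PLANTED_OPEN = 78
PLANTED_FOLD = 8.0
MEAN_DEPTH = 100.0
DISPERSION = 0.05

# Linker-histone abundance scenario: H1.0 rises from a trace fraction of
# total H1 in control to a dominant fraction after induction.
H1_SUBTYPES = ("H1.0", "H1.2", "H1.4")
ABUNDANCE_SCENARIO = {
    "WT": ({"H1.0": 0.013, "H1.2": 0.494, "H1.4": 0.493}, 0.50),
    "iH1.0": ({"H1.0": 0.180, "H1.2": 0.410, "H1.4": 0.410}, 0.58),
}

SAMPLE_CONDITIONS = {f"{c}_{i}": c for c in CONDITIONS for i in (1, 2, 3)}
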