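"""Core genomic containers used throughout the pipeline.

Coordinates are 0-based, half-open everywhere (BED convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, with an optional label."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ParameterError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ParameterError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, slots=True)
class FragmentRecord:
    """One sequenced fragment (e.g. an ATAC fragment) from one sample."""

    interval: GenomicInterval
    sample: str
    condition: str

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class PeakCountTable:
    """Peak intervals x samples integer count matrix with condition labels."""

    peaks: list[GenomicInterval]
    counts: np.ndarray
    samples: list[str]
    condition_of: dict[str, str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ParameterError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.peaks), len(self.samples)):
            raise ParameterError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.peaks)} peaks x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ParameterError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ParameterError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        missing = [s for s in self.samples if s not in self.condition_of]
        if missing:
            raise ParameterError(f"samples without condition label: {missing}")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def sample_indices(self, condition: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples)
               if self.condition_of[s] == condition]
        return np.asarray(idx, dtype=int)
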