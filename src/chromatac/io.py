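"""Readers and writers for the external formats the pipeline touches.

All readers validate strictly and raise :class:`~chromatac.errors.FormatError`
naming the offending line where possible. Writers emit exactly what the
readers accept, so write -> read round-trips are identity.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import FragmentRecord, GenomicInterval, PeakCountTable
from .errors import FormatError

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path, expected_columns: int = 3) -> list[GenomicInterval]:
    """Read a BED3/BED4 file into validated intervals.

    Column 4, when present, is stored as the interval label. Comment,
    ``track`` and ``browser`` lines are skipped.
    """
    if expected_columns < 3:
        raise ValueError("expected_columns must be >= 3")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < expected_columns:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {expected_columns} "
                    f"tab-separated columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if not chrom:
                raise FormatError(f"{path}:{lineno}: empty chrom field")
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {start}-{end} "
                    "(require 0 <= start < end)"
                )
            label = fields[3] if len(fields) >= 4 else None
            out.append(GenomicInterval(chrom, start, end, label))
    return out


def write_bed(path: str | Path, intervals: list[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_fragments(path: str | Path, sample: str, condition: str) -> list[FragmentRecord]:
    """Read a fragment BED (one record per fragment) for one sample."""
    return [FragmentRecord(iv, sample, condition) for iv in read_bed(path)]


def write_fragments(path: str | Path, fragments: list[FragmentRecord]) -> None:
    write_bed(path, [f.interval for f in fragments])


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}.

    The key is the header token before the first whitespace. Duplicate
    headers and empty sequences are format errors.
    """
    out: dict[str, str] = {}
    n_records = 0
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            n_records += 1
            name = rec.id
            if name in out:
                raise FormatError(f"{path}: duplicate FASTA header {name!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"{path}: empty sequence for {name!r}")
            out[name] = seq
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FASTA ({exc})") from exc
    if n_records == 0 and Path(path).stat().st_size > 0:
        raise FormatError(f"{path}: no FASTA records (missing '>' header?)")
    return out


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    """Write FASTA with 60-column line wrapping."""
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


_COUNT_META_COLS = ["peak_id", "chrom", "start", "end"]


def read_count_table(path: str | Path,
                     condition_of: dict[str, str]) -> PeakCountTable:
    """Read a TSV peak-count table.

    Layout: header row ``peak_id chrom start end <sample> ...``; one row
    per peak; counts must be non-negative integers with no missing cells.
    `condition_of` maps each sample column to its condition.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COUNT_META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    samples = [c for c in df.columns if c not in _COUNT_META_COLS]
    if not samples:
        raise FormatError(f"{path}: no sample columns")
    mat = df[samples]
    if mat.isna().any().any():
        raise FormatError(f"{path}: missing (NA) count cells")
    arr = mat.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"{path}: non-integer counts")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise FormatError(f"{path}: negative counts")
    peaks = [GenomicInterval(r.chrom, int(r.start), int(r.end), str(r.peak_id))
             for r in df.itertuples()]
    unlabeled = [s for s in samples if s not in condition_of]
    if unlabeled:
        raise FormatError(f"{path}: samples without condition mapping: {unlabeled}")
    return PeakCountTable(peaks, arr, samples,
                          {s: condition_of[s] for s in samples})


def write_count_table(path: str | Path, table: PeakCountTable) -> None:
    rows = {
        "peak_id": [p.label if p.label is not None else f"peak_{i}"
                    for i, p in enumerate(table.peaks)],
        "chrom": [p.chrom for p in table.peaks],
        "start": [p.start for p in table.peaks],
        "end": [p.end for p in table.peaks],
    }
    df = pd.DataFrame(rows)
    for j, s in enumerate(table.samples):
        df[s] = table.counts[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    """Read a protein-abundance TSV (column ``protein`` + sample columns)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "protein" not in df.columns:
        raise FormatError(f"{path}: missing 'protein' column")
    df = df.set_index("protein")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing abundance cells")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative abundances")
    return df


def write_abundance_tsv(path: str | Path, abundance: pd.DataFrame) -> None:
    # %.17g round-trips any double exactly through the text file
    abundance.rename_axis("protein").to_csv(path, sep="\t",
                                            float_format="%.17g")


# ---------------------------------------------------------------------------
# BED12 gene models

def read_bed12(path: str | Path) -> list["Transcript"]:
    """Read a BED12 gene model into transcripts with exon blocks and CDS."""
    from .da import Transcript  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 requires 12 columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                cds_start, cds_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed BED12 fields") from exc
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            for (s0, e0) in exons:
                if not (start <= s0 < e0 <= end):
                    raise FormatError(f"{path}:{lineno}: exon outside transcript")
            out.append(Transcript(chrom, start, end, name, strand,
                                  cds_start, cds_end, exons))
    return out


def write_bed12(path: str | Path, transcripts) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons)
            offsets = ",".join(str(s - t.start) for s, _ in t.exons)
            fh.write("\t".join(map(str, [
                t.chrom, t.start, t.end, t.name, 0, t.strand,
                t.cds_start, t.cds_end, 0, len(t.exons), sizes, offsets,
            ])) + "\n")
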