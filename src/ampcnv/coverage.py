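"""Coverage matrices: amplicon x sample read counts plus a usability mask.

The matrix is the caller's sole view of the sequencing data.  Counts come
either from a TSV (amplicons as rows, samples as columns) or from aligned
reads counted by maximal overlap with the panel intervals.
"""

from __future__ import annotations

import os
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import AmpliconPanel

__all__ = ["CoverageMatrix", "CoverageError", "load_coverage_tsv",
           "write_coverage_tsv", "count_reads"]


class CoverageError(ValueError):
    """Malformed coverage input."""


@dataclass
class CoverageMatrix:
    """Integer read counts per (amplicon, sample) with a boolean QC mask
    (True = usable cell).  Row order follows the panel."""

    panel: AmpliconPanel
    counts: pd.DataFrame
    mask: pd.DataFrame = field(default=None)

    def __post_init__(self):
        ids = self.panel.ids
        if list(self.counts.index) != ids:
            missing = set(ids) - set(self.counts.index)
            unknown = set(self.counts.index) - set(ids)
            if missing or unknown:
                raise CoverageError(
                    f"coverage rows do not match panel "
                    f"(missing: {sorted(missing)[:5]}, unknown: {sorted(unknown)[:5]})")
            self.counts = self.counts.loc[ids]
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise CoverageError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise CoverageError("counts must be non-negative")
        if self.mask is None:
            self.mask = pd.DataFrame(True, index=self.counts.index,
                                     columns=self.counts.columns)
        if self.mask.shape != self.counts.shape:
            raise CoverageError("mask shape does not match counts")
        self.mask = self.mask.astype(bool)
        self.counts.index.name = None
        self.counts.columns.name = None

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def amplicon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "CoverageMatrix":
        return CoverageMatrix(self.panel, self.counts.copy(), self.mask.copy())

    def drop_samples(self, sample_ids) -> "CoverageMatrix":
        keep = [s for s in self.samples if s not in set(sample_ids)]
        return CoverageMatrix(self.panel, self.counts[keep], self.mask[keep])


def load_coverage_tsv(path, panel: AmpliconPanel) -> CoverageMatrix:
    """Read a coverage TSV (first column = amplicon id, header = sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise CoverageError(f"cannot parse coverage TSV {path}: {exc}") from exc
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = int(raw)
            except (TypeError, ValueError) as exc:
                raise CoverageError(
                    f"{path}: non-integer count {raw!r} at amplicon "
                    f"{df.index[i]!r}, sample {col!r}") from exc
    counts = pd.DataFrame(values, index=df.index, columns=df.columns)
    return CoverageMatrix(panel, counts)


def write_coverage_tsv(matrix: CoverageMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="amplicon")


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------

def _assign_read(chrom: str, start: int, end: int, by_chrom) -> str | None:
    """Assign an aligned span to the amplicon with maximal overlap
    (ties to the leftmost amplicon); None if no overlap."""
    entry = by_chrom.get(chrom)
    if entry is None:
        return None
    starts, amps, max_len = entry
    lo = bisect_left(starts, start - max_len)
    best_id, best_ov, best_start = None, 0, None
    for a in amps[max(0, lo):]:
        if a.start >= end:
            break
        ov = min(end, a.end) - max(start, a.start)
        if ov <= 0:
            continue
        if ov > best_ov or (ov == best_ov and (best_start is None or a.start < best_start)):
            best_id, best_ov, best_start = a.id, ov, a.start
    return best_id


def count_reads(panel: AmpliconPanel, alignment_paths, sample_names=None) -> CoverageMatrix:
    """Count primary, mapped, non-duplicate reads per amplicon for each
    alignment file (SAM/BAM, one per sample).

    Each read is assigned to the single amplicon whose interval has the
    largest overlap with the read's aligned span; ties go to the leftmost
    amplicon.  Files are scanned sequentially, so no index is required.
    Contig names in the alignment header must cover the panel's chroms.
    """
    import pysam

    if sample_names is None:
        sample_names = [os.path.splitext(os.path.basename(p))[0]
                        for p in alignment_paths]
    if len(sample_names) != len(alignment_paths):
        raise CoverageError("sample_names and alignment_paths differ in length")

    grouped: dict[str, list] = {}
    for a in panel.amplicons:
        grouped.setdefault(a.chrom, []).append(a)
    by_chrom = {chrom: ([a.start for a in amps], amps,
                        max(a.length for a in amps))
                for chrom, amps in grouped.items()}

    counts = pd.DataFrame(0, index=panel.ids, columns=sample_names, dtype=np.int64)
    for path, sample in zip(alignment_paths, sample_names):
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            refs = set(af.references or ())
            missing = sorted(panel.chroms - refs)
            if missing:
                raise CoverageError(
                    f"{path}: panel contigs absent from alignment header: {missing}")
            for read in af:
                if (read.is_unmapped or read.is_secondary
                        or read.is_supplementary or read.is_duplicate):
                    continue
                amp = _assign_read(read.reference_name, read.reference_start,
                                   read.reference_end, by_chrom)
                if amp is not None:
                    counts.at[amp, sample] += 1
    return CoverageMatrix(panel, counts)
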