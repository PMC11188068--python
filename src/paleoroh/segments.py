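"""Genomic interval primitives shared by the ROH modules.

Segments are 0-based, half-open ``[start, end)`` intervals on a named
chromosome, optionally carrying the number of supporting SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SegmentError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    """Half-open genomic interval with an optional SNP count."""

    chrom: str
    start: int
    end: int
    n_snps: int = 0

    def __post_init__(self):
        if self.end <= self.start:
            raise SegmentError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.start < 0:
            raise SegmentError("negative start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length / 1000.0

    def overlaps(self, other: "Segment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def sort_segments(segments) -> list[Segment]:
    return sorted(segments, key=lambda s: (s.chrom, s.start, s.end))


def merge_segments(segments) -> list[Segment]:
    """Merge overlapping or abutting segments; SNP counts are summed."""
    merged: list[Segment] = []
    for seg in sort_segments(segments):
        if merged and merged[-1].chrom == seg.chrom and seg.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = Segment(
                prev.chrom, prev.start, max(prev.end, seg.end), prev.n_snps + seg.n_snps
            )
        else:
            merged.append(seg)
    return merged


def total_length(segments) -> int:
    return sum(s.length for s in segments)


def check_disjoint(segments, label: str = "segments") -> list[Segment]:
    """Return sorted segments; raise if any two on a chromosome overlap."""
    srt = sort_segments(segments)
    for a, b in zip(srt, srt[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise SegmentError(f"{label} overlap: {a} vs {b}")
    return srt


def intersect_length(a, b) -> int:
    """Total bp shared between two internally disjoint segment sets."""
    a = check_disjoint(a, "first set")
    b = check_disjoint(b, "second set")
    shared = 0
    by_chrom: dict[str, list[Segment]] = {}
    for seg in b:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs_b in by_chrom.items():
        starts = np.array([s.start for s in segs_b])
        ends = np.array([s.end for s in segs_b])
        for seg in a:
            if seg.chrom != chrom:
                continue
            lo = np.maximum(starts, seg.start)
            hi = np.minimum(ends, seg.end)
            shared += int(np.clip(hi - lo, 0, None).sum())
    return shared


def write_bed(segments, path, extra_header: bool = False) -> None:
    """Write segments as BED-like TSV: chrom, start, end, n_snps, kb."""
    with open(path, "w") as fh:
        if extra_header:
            fh.write("chrom\tstart\tend\tn_snps\tkb\n")
        for seg in sort_segments(segments):
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.n_snps}\t{seg.length_kb:.3f}\n"
            )


def read_bed(path) -> list[Segment]:
    """Read a BED / BED-like TSV (first three columns used, optional 4th
    column taken as SNP count when integral)."""
    segments = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser", "chrom\t")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SegmentError(f"{path}: line {line_no}: expected >=3 columns")
            n_snps = 0
            if len(parts) >= 4:
                try:
                    n_snps = int(parts[3])
                except ValueError:
                    n_snps = 0
            segments.append(Segment(parts[0], int(parts[1]), int(parts[2]), n_snps))
    return segments


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, length = line.split("\t")[:2]
            sizes[name] = int(length)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{int(length)}\n")
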