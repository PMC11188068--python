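"""Sliding-window runs-of-homozygosity caller.

Algorithm, for one chromosome of a single diploid sample:

1. Slide a window of ``window_snp`` consecutive SNPs along the track; a
   window passes if it contains at most ``window_het`` heterozygous and at
   most ``window_missing`` missing calls.
2. Each SNP's hit fraction is the number of passing windows covering it
   divided by the number of windows covering it (fewer near chromosome
   ends, where only fully-contained windows are counted); a SNP is eligible
   when the fraction is at least ``window_threshold``.
3. Candidate segments are maximal runs of consecutively eligible SNPs,
   additionally split wherever adjacent eligible SNPs lie more than
   ``max_gap_kb`` apart.
4. A candidate is emitted iff it has at least ``min_snp`` SNPs, spans at
   least ``min_kb``, and its span per SNP does not exceed
   ``max_density_kb_per_snp``.

Segment boundaries are the positions of the outermost SNPs of the run
(half-open, 0-based), never extended into flanking inter-SNP gaps.
Heterozygous or missing calls that survive eligibility stay inside the
emitted segment; there is no segment-level heterozygote cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .callset import MISSING, GenotypeTable
from .filters import is_transversion
from .segments import Segment

logger = logging.getLogger(__name__)

HOM, HET, MISS = 0, 1, 2  # internal call codes


class RohCallerError(ValueError):
    pass


@dataclass
class ROHParams:
    """Window and segment thresholds of the sliding-window caller."""

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 50
    min_kb: float = 500.0
    max_gap_kb: float = 500.0
    max_density_kb_per_snp: float = 50.0

    def validate(self) -> None:
        for name in ("window_snp", "window_het", "window_missing", "min_snp",
                     "min_kb", "max_gap_kb", "max_density_kb_per_snp"):
            if getattr(self, name) < 0:
                raise RohCallerError(f"{name} must be nonnegative")
        if self.window_snp < 1 or self.min_snp < 1:
            raise RohCallerError("window_snp and min_snp must be positive")
        if not 0.0 < self.window_threshold <= 1.0:
            raise RohCallerError("window_threshold outside (0, 1]")


def encode_calls(gt: np.ndarray) -> np.ndarray:
    """Map alt doses to {HOM, HET, MISS} codes."""
    codes = np.full(gt.shape, HOM, dtype=np.int8)
    codes[gt == 1] = HET
    codes[gt == MISSING] = MISS
    return codes


def _call_chromosome(chrom: str, pos: np.ndarray, calls: np.ndarray, p: ROHParams) -> list[Segment]:
    n = len(pos)
    w = p.window_snp
    if n < w:
        logger.warning("chromosome %s has %d SNPs (< window of %d); no calls", chrom, n, w)
        return []

    het = (calls == HET).astype(np.int64)
    mis = (calls == MISS).astype(np.int64)
    # sliding-window counts via cumulative sums; window j covers SNPs [j, j+w)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = n - w + 1
    win_het = chet[w:] - chet[:-w]
    win_mis = cmis[w:] - cmis[:-w]
    passing = ((win_het <= p.window_het) & (win_mis <= p.window_missing)).astype(np.int64)

    # SNP i is covered by windows j in [max(0, i-w+1), min(i, n_win-1)]
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_win - 1)
    covering = (hi - lo + 1).astype(np.float64)
    cpass = np.concatenate([[0], np.cumsum(passing)])
    hits = cpass[hi + 1] - cpass[lo]
    eligible = hits / covering >= p.window_threshold

    max_gap_bp = p.max_gap_kb * 1000.0
    segments: list[Segment] = []
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and eligible[j + 1]
            and pos[j + 1] - pos[j] <= max_gap_bp
        ):
            j += 1
        n_snps = j - i + 1
        span = int(pos[j] - pos[i] + 1)
        if (
            n_snps >= p.min_snp
            and span >= p.min_kb * 1000.0
            and span / n_snps <= p.max_density_kb_per_snp * 1000.0
        ):
            segments.append(Segment(chrom, int(pos[i] - 1), int(pos[j]), n_snps))
        i = j + 1
    return segments


def call_roh_track(
    chrom: str, pos: np.ndarray, calls: np.ndarray, params: ROHParams | None = None
) -> list[Segment]:
    """Call ROH on one chromosome given positions and {HOM, HET, MISS} codes."""
    params = params or ROHParams()
    params.validate()
    pos = np.asarray(pos, dtype=np.int64)
    calls = np.asarray(calls, dtype=np.int8)
    if len(pos) != len(calls):
        raise RohCallerError("positions and calls differ in length")
    if np.any(np.diff(pos) <= 0):
        raise RohCallerError("positions must be strictly increasing")
    if len(calls) and (calls.min() < 0 or calls.max() > 2):
        raise RohCallerError("calls must be coded {0=hom, 1=het, 2=missing}")
    return _call_chromosome(chrom, pos, calls, params)


def call_roh(
    table: GenotypeTable, params: ROHParams | None = None, sample: str | None = None
) -> list[Segment]:
    """Call ROH for one sample of a genotype table, chromosome by chromosome."""
    params = params or ROHParams()
    params.validate()
    j = 0 if sample is None else table.samples.index(sample)
    codes = encode_calls(table.gt[:, j])
    segments: list[Segment] = []
    for chrom in dict.fromkeys(table.chrom.tolist()):
        mask = table.chrom == chrom
        segments.extend(
            _call_chromosome(str(chrom), table.pos[mask], codes[mask], params)
        )
    return segments


def call_roh_transversions(
    table: GenotypeTable, params: ROHParams | None = None, sample: str | None = None
) -> list[Segment]:
    """Call ROH after removing transition sites."""
    keep = is_transversion(table.ref, table.alt)
    return call_roh(table.take(keep), params, sample)
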