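"""Genotype concordance between an imputed callset and a high-coverage truth
callset: per-class error rates, non-reference discordance (NRD), and squared
Pearson correlation of allele doses stratified by MAF bin under INFO-score
cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .callset import MISSING, GenotypeTable

DEFAULT_MAF_BINS = (0.0, 0.001, 0.002, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5)
DEFAULT_INFO_CUTOFFS = (None, 0.8, 0.9, 0.95)


class ConcordanceError(ValueError):
    pass


@dataclass
class ConcordanceGate:
    """Which truth genotypes are trusted enough to score against."""

    min_truth_depth: int = 8
    min_posterior: float = 0.9

    def validate(self) -> None:
        if self.min_truth_depth < 0:
            raise ConcordanceError("negative depth gate")
        if not 0.0 <= self.min_posterior <= 1.0:
            raise ConcordanceError("posterior gate outside [0, 1]")


@dataclass
class ConfusionCounts:
    """3x3 truth-by-called genotype-class tally over {RR, RA, AA}.

    ``matrix[t, c]`` counts sites with truth class ``t`` called as ``c``.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=np.int64))
    n_missing_imputed: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (3, 3):
            raise ConcordanceError("confusion matrix must be 3x3")
        if np.any(self.matrix < 0):
            raise ConcordanceError("negative confusion cell")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    # diagonal matches
    @property
    def m_rr(self) -> int:
        return int(self.matrix[0, 0])

    @property
    def m_ra(self) -> int:
        return int(self.matrix[1, 1])

    @property
    def m_aa(self) -> int:
        return int(self.matrix[2, 2])

    # mismatches at each truth class
    @property
    def e_rr(self) -> int:
        return int(self.matrix[0, 1] + self.matrix[0, 2])

    @property
    def e_ra(self) -> int:
        return int(self.matrix[1, 0] + self.matrix[1, 2])

    @property
    def e_aa(self) -> int:
        return int(self.matrix[2, 0] + self.matrix[2, 1])

    @classmethod
    def from_named(cls, m_rr=0, m_ra=0, m_aa=0, e_rr=0, e_ra=0, e_aa=0) -> "ConfusionCounts":
        """Build counts from the named cells, splitting each truth class's
        mismatches evenly-arbitrarily across the two wrong call classes
        (only row sums matter for the derived rates)."""
        m = np.zeros((3, 3), dtype=np.int64)
        m[0, 0], m[1, 1], m[2, 2] = m_rr, m_ra, m_aa
        m[0, 1] = e_rr
        m[1, 0] = e_ra
        m[2, 1] = e_aa
        return cls(matrix=m)


def _align(truth: GenotypeTable, imputed: GenotypeTable):
    """Index pairs of shared (chrom, pos) sites; shared samples by name."""
    truth_keys = {k: i for i, k in enumerate(truth.site_keys())}
    ti, ii = [], []
    for j, key in enumerate(imputed.site_keys()):
        i = truth_keys.get(key)
        if i is not None:
            ti.append(i)
            ii.append(j)
    if not ti:
        raise ConcordanceError("no overlapping sites between truth and imputed callsets")
    shared = [s for s in truth.samples if s in set(imputed.samples)]
    if not shared:
        raise ConcordanceError("no shared samples between truth and imputed callsets")
    ts = [truth.samples.index(s) for s in shared]
    is_ = [imputed.samples.index(s) for s in shared]
    return np.array(ti), np.array(ii), np.array(ts), np.array(is_)


def tally_confusion(
    truth: GenotypeTable,
    imputed: GenotypeTable,
    gate: ConcordanceGate | None = None,
) -> ConfusionCounts:
    """Tally truth-vs-imputed genotype classes over gated shared sites.

    Only sites whose truth genotype passes the depth/posterior gate are
    scored; missing imputed genotypes are excluded from the matrix and
    counted in ``n_missing_imputed``.
    """
    gate = gate or ConcordanceGate()
    gate.validate()
    ti, ii, ts, is_ = _align(truth, imputed)

    tg = truth.gt[np.ix_(ti, ts)]
    ig = imputed.gt[np.ix_(ii, is_)]
    tdp = truth.dp[np.ix_(ti, ts)]
    tprob = truth.prob[np.ix_(ti, ts)]

    gated = (tg != MISSING) & (tdp >= gate.min_truth_depth) & (tprob >= gate.min_posterior)
    imputed_missing = gated & (ig == MISSING)
    scored = gated & ~imputed_missing

    matrix = np.zeros((3, 3), dtype=np.int64)
    t_flat = tg[scored]
    c_flat = ig[scored]
    np.add.at(matrix, (t_flat, c_flat), 1)
    return ConfusionCounts(matrix=matrix, n_missing_imputed=int(imputed_missing.sum()))


@dataclass
class ErrorRates:
    err_hom_ref: float
    err_het: float
    err_hom_alt: float
    nrd: float


def error_rates(counts: ConfusionCounts) -> ErrorRates:
    """Per-truth-class error rates and non-reference discordance.

    NRD = (eRR + eRA + eAA) / (eRR + eRA + eAA + mRA + mAA): the error rate
    excluding concordant homozygous-reference calls.  Empty truth classes
    yield NaN rates rather than zero.
    """
    if counts.total == 0:
        raise ConcordanceError("empty confusion counts")

    def _rate(err: int, match: int) -> float:
        total = err + match
        return err / total if total > 0 else math.nan

    errors = counts.e_rr + counts.e_ra + counts.e_aa
    denom = errors + counts.m_ra + counts.m_aa
    nrd = errors / denom if denom > 0 else math.nan
    return ErrorRates(
        err_hom_ref=_rate(counts.e_rr, counts.m_rr),
        err_het=_rate(counts.e_ra, counts.m_ra),
        err_hom_alt=_rate(counts.e_aa, counts.m_aa),
        nrd=nrd,
    )


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def r2_by_maf_bin(
    truth: GenotypeTable,
    imputed: GenotypeTable,
    bins=DEFAULT_MAF_BINS,
    info_cutoffs=DEFAULT_INFO_CUTOFFS,
    gate: ConcordanceGate | None = None,
) -> pd.DataFrame:
    """Squared dose correlation per (MAF bin, INFO cutoff) cell.

    Bins are left-open/right-closed on the folded panel MAF.  Cells with
    fewer than two scored genotypes, or with constant dose on either side,
    report NaN with ``defined=False`` rather than zero.
    """
    bins = tuple(bins)
    if any(lo >= hi for lo, hi in zip(bins, bins[1:])) or bins[-1] != 0.5:
        raise ConcordanceError("MAF bin edges must be strictly increasing and end at 0.5")
    gate = gate or ConcordanceGate()
    ti, ii, ts, is_ = _align(truth, imputed)

    tg = truth.gt[np.ix_(ti, ts)]
    ig = imputed.gt[np.ix_(ii, is_)]
    tdp = truth.dp[np.ix_(ti, ts)]
    tprob = truth.prob[np.ix_(ti, ts)]
    maf = truth.maf[ti]
    info = imputed.info[ii]

    scored = (
        (tg != MISSING)
        & (ig != MISSING)
        & (tdp >= gate.min_truth_depth)
        & (tprob >= gate.min_posterior)
    )

    rows = []
    for cutoff in info_cutoffs:
        if cutoff is None:
            site_ok = np.ones(len(maf), dtype=bool)
        else:
            site_ok = ~np.isnan(info) & (info >= cutoff)
        for lo, hi in zip(bins[:-1], bins[1:]):
            in_bin = site_ok & (maf > lo) & (maf <= hi)
            mask = scored & in_bin[:, None]
            x = tg[mask].astype(float)
            y = ig[mask].astype(float)
            r2 = _pearson_r2(x, y)
            rows.append(
                {
                    "bin_low": lo,
                    "bin_high": hi,
                    "info_cutoff": math.nan if cutoff is None else cutoff,
                    "n_sites": int(mask.any(axis=1).sum()),
                    "n_genotypes": int(mask.sum()),
                    "r2": r2,
                    "defined": not math.isnan(r2),
                }
            )
    return pd.DataFrame(rows)


def concordance_report(
    truth: GenotypeTable,
    imputed: GenotypeTable,
    bins=DEFAULT_MAF_BINS,
    info_cutoffs=DEFAULT_INFO_CUTOFFS,
    gate: ConcordanceGate | None = None,
) -> pd.DataFrame:
    """Per-INFO-cutoff class error rates and NRD plus the r2-by-bin table."""
    gate = gate or ConcordanceGate()
    rows = []
    for cutoff in info_cutoffs:
        if cutoff is None:
            imp = imputed
        else:
            keep = ~np.isnan(imputed.info) & (imputed.info >= cutoff)
            imp = imputed.take(keep)
        try:
            counts = tally_confusion(truth, imp, gate)
            rates = error_rates(counts)
        except ConcordanceError:
            continue
        rows.append(
            {
                "info_cutoff": math.nan if cutoff is None else cutoff,
                "n_scored": counts.total,
                "err_hom_ref": rates.err_hom_ref,
                "err_het": rates.err_het,
                "err_hom_alt": rates.err_hom_alt,
                "nrd": rates.nrd,
            }
        )
    return pd.DataFrame(rows)
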