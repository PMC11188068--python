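"""F_ROH inbreeding coefficients with a short/long decomposition, and
Mann-Whitney rank-sum comparisons between cohorts.

The exact rank-sum null is enumerated (with midranks, so ties are handled)
for combined sample sizes up to 20; larger comparisons fall back to the
tie-corrected normal approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .segments import merge_segments

LONG_CUTOFF_BP = 1_600_000  # segments of at least this length count as long
EXACT_ENUMERATION_MAX_N = 20


class InbreedingError(ValueError):
    pass


@dataclass
class FrohSummary:
    sample: str
    n_roh: int
    total_roh_bp: int
    froh_all: float
    froh_short: float
    froh_long: float
    cohort: str = ""
    age_bp: float = math.nan


def froh(
    segments,
    genome_length: int,
    sample: str = "",
    long_cutoff: int = LONG_CUTOFF_BP,
    cohort: str = "",
    age_bp: float = math.nan,
) -> FrohSummary:
    """Fraction of the genome in ROH, split at the long/short cutoff.

    The boundary is assigned to "long": a segment of exactly ``long_cutoff``
    bp is long.  Input segments are merged before tallying, so the result is
    invariant to splitting a segment into abutting pieces (note the split
    pieces are re-merged, and length classification happens after merging).
    """
    if genome_length <= 0:
        raise InbreedingError("genome_length must be positive")
    merged = merge_segments(segments)
    for seg in merged:
        if seg.length > genome_length:
            raise InbreedingError(f"segment {seg} longer than the genome")
    total = sum(s.length for s in merged)
    if total > genome_length:
        raise InbreedingError("segments exceed genome length")
    long_bp = sum(s.length for s in merged if s.length >= long_cutoff)
    short_bp = total - long_bp
    return FrohSummary(
        sample=sample,
        n_roh=len(merged),
        total_roh_bp=total,
        froh_all=total / genome_length,
        froh_short=short_bp / genome_length,
        froh_long=long_bp / genome_length,
        cohort=cohort,
        age_bp=age_bp,
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """U_A and U_B via midranks of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_b = len(a), len(b)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0
    return u_a, n_a * n_b - u_a


def rank_sum_compare(group_a, group_b) -> dict:
    """Two-sided Mann-Whitney U test.

    Returns the min-orientation U and the two-sided p-value: exact by
    exhaustive enumeration of all group labelings (midranks) when the
    combined size is at most 20, otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InbreedingError("both groups must be non-empty")

    u_a, u_b = _u_statistic(a, b)
    u_min = min(u_a, u_b)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b

    if n <= EXACT_ENUMERATION_MAX_N:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        base = n_a * (n_a + 1) / 2.0
        u_values = [
            sum(ranks[i] for i in combo) - base
            for combo in itertools.combinations(range(n), n_a)
        ]
        u_values = np.asarray(u_values)
        tol = 1e-9
        lower = np.mean(u_values <= u_a + tol)
        upper = np.mean(u_values >= u_a - tol)
        p = min(1.0, 2.0 * min(lower, upper))
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"

    return {"U": float(u_min), "U_A": float(u_a), "U_B": float(u_b),
            "p": float(p), "method": method, "n_a": n_a, "n_b": n_b}


def froh_table(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "cohort": s.cohort,
                "age_bp": s.age_bp,
                "n_roh": s.n_roh,
                "total_roh_bp": s.total_roh_bp,
                "froh_all": s.froh_all,
                "froh_short": s.froh_short,
                "froh_long": s.froh_long,
            }
            for s in summaries
        ]
    )


def pairwise_cohort_tests(table: pd.DataFrame, value: str = "froh_all") -> pd.DataFrame:
    """Rank-sum tests for every unordered cohort pair in a FrohSummary table."""
    cohorts = sorted(c for c in table["cohort"].unique() if c)
    rows = []
    for i, ca in enumerate(cohorts):
        for cb in cohorts[i + 1:]:
            res = rank_sum_compare(
                table.loc[table["cohort"] == ca, value].to_numpy(),
                table.loc[table["cohort"] == cb, value].to_numpy(),
            )
            rows.append({"cohort_a": ca, "cohort_b": cb, **res})
    return pd.DataFrame(rows)
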