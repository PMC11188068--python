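"""Site/genotype filtering for validation callsets, panel sites and
post-imputation cleanup.

Rules are evaluated in a fixed, documented order (QUAL, then depth bounds,
then heterozygote allele balance) so that removal tallies are reproducible:
each removed site is attributed to the first rule it fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .callset import MISSING, GenotypeTable

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


class FilterContractError(ValueError):
    pass


@dataclass
class FilterSpec:
    """Thresholds for validation and post-imputation filtering."""

    min_qual: float = 30.0
    depth_lower_floor: int = 8  # lower bound is max(mean/3, floor)
    depth_upper_factor: float = 2.0  # upper bound is factor * genome mean
    het_balance: tuple = (0.15, 0.85)
    maf_min: float = 0.01
    info_min: float = 0.8
    max_missing_fraction: float = 0.05

    def validate(self) -> None:
        lo, hi = self.het_balance
        if not (0.0 <= lo < hi <= 1.0):
            raise FilterContractError(f"bad het balance bounds {self.het_balance}")
        if not 0.0 <= self.maf_min <= 0.5:
            raise FilterContractError(f"maf_min {self.maf_min} outside [0, 0.5]")


def validation_filter(
    calls: GenotypeTable,
    mean_doc: float,
    spec: FilterSpec | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Filter a single-sample high-coverage validation callset.

    Removes, in order: sites with QUAL below the threshold (only where QUAL
    is annotated); sites with depth above ``2 x mean_doc`` or below
    ``max(mean_doc / 3, 8)``; heterozygous sites whose alt-read fraction
    falls outside ``[0.15, 0.85]``.  Returns the surviving table and a
    per-rule removal tally.
    """
    spec = spec or FilterSpec()
    spec.validate()
    if calls.n_samples != 1:
        raise FilterContractError("validation filtering operates on single-sample callsets")
    dp = calls.dp[:, 0]
    if not np.any(dp > 0):
        raise FilterContractError("depth fields absent or all zero")

    fail_qual = ~np.isnan(calls.qual) & (calls.qual < spec.min_qual)

    lower = max(mean_doc / 3.0, float(spec.depth_lower_floor))
    upper = spec.depth_upper_factor * mean_doc
    fail_depth = (dp < lower) | (dp > upper)

    ad = calls.ad[:, 0, :]
    total = ad.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(total > 0, ad[:, 1] / np.maximum(total, 1), np.nan)
    lo, hi = spec.het_balance
    is_het = calls.gt[:, 0] == 1
    fail_balance = is_het & ((alt_frac < lo) | (alt_frac > hi))

    removed_qual = fail_qual
    removed_depth = fail_depth & ~removed_qual
    removed_balance = fail_balance & ~removed_qual & ~fail_depth
    keep = ~(removed_qual | removed_depth | removed_balance)

    tally = pd.DataFrame(
        {
            "rule": ["qual", "depth", "het_balance"],
            "sites_removed": [
                int(removed_qual.sum()),
                int(removed_depth.sum()),
                int(removed_balance.sum()),
            ],
        }
    )
    return calls.take(keep), tally


def post_imputation_filter(calls: GenotypeTable, spec: FilterSpec | None = None) -> GenotypeTable:
    """Retain sites with folded MAF >= ``maf_min`` and INFO >= ``info_min``
    (both boundaries inclusive)."""
    spec = spec or FilterSpec()
    spec.validate()
    if np.all(np.isnan(calls.af)):
        raise FilterContractError("AF annotation absent")
    if np.all(np.isnan(calls.info)):
        raise FilterContractError("INFO annotation absent")
    keep = (calls.maf >= spec.maf_min) & (calls.info >= spec.info_min)
    return calls.take(keep)


def is_transversion(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Boolean mask of transversion sites; raises on non-ACGT alleles."""
    for allele in np.concatenate([np.asarray(ref), np.asarray(alt)]):
        if allele not in ("A", "C", "G", "T"):
            raise FilterContractError(f"non-ACGT allele {allele!r}")
    return np.array(
        [(r, a) not in TRANSITIONS for r, a in zip(ref, alt)], dtype=bool
    )


def restrict_to_transversions(calls: GenotypeTable) -> GenotypeTable:
    """Drop transition (C<->T, G<->A) sites."""
    return calls.take(is_transversion(calls.ref, calls.alt))


def panel_site_filter(
    panel_calls: GenotypeTable, max_missing_fraction: float = 0.05
) -> GenotypeTable:
    """Retain biallelic SNPs whose genotype missingness is at most the cap."""
    single_base = np.array(
        [len(str(r)) == 1 and len(str(a)) == 1 and r != a
         for r, a in zip(panel_calls.ref, panel_calls.alt)]
    )
    missing_frac = (panel_calls.gt == MISSING).mean(axis=1)
    keep = single_base & (missing_frac <= max_missing_fraction)
    return panel_calls.take(keep)
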