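"""Windowed ROH prevalence, depth-outlier window exclusion, desert
detection, and gene-category enrichment with permutation FWER.

The genome is tiled into fixed-width (default 500 kb) 0-based half-open
windows; the final partial window of each chromosome is retained at its
true width.  A sample counts as "having ROH" in a window when any of its
segments overlaps the window by at least one base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .segments import Segment

WINDOW_SIZE = 500_000
DESERT_THRESHOLD_PCT = 5.0


class LandscapeError(ValueError):
    pass


def tile_windows(chrom_sizes: dict, window_size: int = WINDOW_SIZE) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_sizes.items():
        start = 0
        while start < length:
            end = min(start + window_size, length)
            rows.append({"chrom": chrom, "start": start, "end": end})
            start = end
    return pd.DataFrame(rows)


def _overlap_mask(windows: pd.DataFrame, segments) -> np.ndarray:
    """Boolean per window: does any segment overlap it by >= 1 bp."""
    mask = np.zeros(len(windows), dtype=bool)
    by_chrom: dict[str, list] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        sel = np.flatnonzero(windows["chrom"].to_numpy() == chrom)
        if len(sel) == 0:
            continue
        ws = windows["start"].to_numpy()[sel]
        we = windows["end"].to_numpy()[sel]
        for seg in segs:
            hit = (ws < seg.end) & (seg.start < we)
            mask[sel[hit]] = True
    return mask


def window_prevalence(
    sample_segments: dict,
    cohorts: dict,
    chrom_sizes: dict,
    window_size: int = WINDOW_SIZE,
) -> pd.DataFrame:
    """Percentage of each cohort's samples with >= 1 bp of ROH per window.

    Parameters
    ----------
    sample_segments : mapping of sample name to its ROH segment list.
    cohorts : mapping of sample name to cohort label.
    """
    labels = sorted(set(cohorts.values()))
    members: dict[str, list[str]] = {c: [] for c in labels}
    for sample, cohort in cohorts.items():
        if sample not in sample_segments:
            raise LandscapeError(f"no segments supplied for sample {sample!r}")
        members[cohort].append(sample)
    for cohort, names in members.items():
        if not names:
            raise LandscapeError(f"cohort {cohort!r} has no samples")

    track = tile_windows(chrom_sizes, window_size)
    for cohort, names in members.items():
        counts = np.zeros(len(track), dtype=np.int64)
        for name in names:
            counts += _overlap_mask(track, sample_segments[name])
        track[f"prevalence_{cohort}"] = 100.0 * counts / len(names)
    track["excluded"] = False
    track["exclude_reason"] = ""
    return track


def exclude_outlier_windows(
    track: pd.DataFrame,
    mean_depth: np.ndarray,
    n_sites: np.ndarray | None = None,
) -> pd.DataFrame:
    """Flag windows whose mean depth lies outside mean +/- 2 sd (computed
    across windows) and windows containing zero imputed sites."""
    depth = np.asarray(mean_depth, dtype=float)
    if len(depth) != len(track):
        raise LandscapeError("depth vector length != number of windows")
    out = track.copy()
    mu, sd = depth.mean(), depth.std()
    depth_out = (depth < mu - 2 * sd) | (depth > mu + 2 * sd)
    reasons = np.where(depth_out, "depth_outlier", "")
    if n_sites is not None:
        zero_sites = np.asarray(n_sites) == 0
        reasons = np.where(zero_sites, "no_sites", reasons)
        depth_out = depth_out | zero_sites
    out["mean_depth"] = depth
    if n_sites is not None:
        out["n_sites"] = np.asarray(n_sites)
    out["excluded"] = depth_out
    out["exclude_reason"] = reasons
    prevalence_cols = [c for c in out.columns if c.startswith("prevalence_")]
    out.loc[out["excluded"], prevalence_cols] = np.nan
    return out


def detect_deserts(
    track: pd.DataFrame,
    cohorts,
    threshold_pct: float = DESERT_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Windows where prevalence is strictly below the threshold in every
    listed cohort, among retained (non-excluded) windows only."""
    for cohort in cohorts:
        if f"prevalence_{cohort}" not in track.columns:
            raise LandscapeError(f"cohort {cohort!r} missing from the window track")
    retained = ~track["excluded"].to_numpy(dtype=bool)
    is_desert = retained.copy()
    for cohort in cohorts:
        vals = track[f"prevalence_{cohort}"].to_numpy(dtype=float)
        is_desert &= vals < threshold_pct
    return track.loc[is_desert, ["chrom", "start", "end"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene-category enrichment


@dataclass
class EnrichmentResult:
    category: str
    n_candidate_genes: int
    n_background_genes: int
    p: float
    fwer: float = np.nan


def _genes_overlapping(genes: pd.DataFrame, windows: pd.DataFrame) -> set:
    hits: set[str] = set()
    for chrom, sub in windows.groupby("chrom"):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        ws = sub["start"].to_numpy()
        we = sub["end"].to_numpy()
        gs = gsub["start"].to_numpy()
        ge = gsub["end"].to_numpy()
        for name, s, e in zip(gsub["gene"], gs, ge):
            if np.any((ws < e) & (s < we)):
                hits.add(name)
    return hits


def hypergeometric_enrichment(
    candidate: set, background: set, categories: dict
) -> list[EnrichmentResult]:
    """Over-representation p-value per category.

    ``p = P(X >= k)`` with X hypergeometric over the background gene
    universe; ``k`` is the number of candidate genes in the category.
    """
    n_bg = len(background)
    n_cand = len(candidate)
    results = []
    for cat, genes in categories.items():
        in_bg = set(genes) & background
        if not in_bg:
            continue  # category absent from background: skipped
        k = len(in_bg & candidate)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(in_bg), n_cand))
        results.append(
            EnrichmentResult(
                category=cat,
                n_candidate_genes=k,
                n_background_genes=len(in_bg),
                p=p,
            )
        )
    return results


def enrichment(
    desert_windows: pd.DataFrame,
    genes: pd.DataFrame,
    gene_categories: pd.DataFrame,
    background_windows: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Category enrichment of genes in desert windows, with permutation FWER.

    Parameters
    ----------
    genes : DataFrame with columns chrom, start, end, gene.
    gene_categories : DataFrame with columns gene, category.
    background_windows : retained (non-excluded) windows defining the
        background gene universe.
    n_permutations : randomised candidate sets used for the FWER; each
        permuted set is drawn from the background with probability
        proportional to gene length (the gene-length correction).

    The FWER of a category is the fraction of randomised sets whose minimum
    p-value across categories is <= the category's observed p-value.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    background = _genes_overlapping(genes, background_windows)
    if not background:
        raise LandscapeError("no genes overlap the background windows")
    candidate = _genes_overlapping(genes, desert_windows) & background

    categories: dict[str, set] = {}
    for _, row in gene_categories.iterrows():
        categories.setdefault(str(row["category"]), set()).add(str(row["gene"]))

    observed = hypergeometric_enrichment(candidate, background, categories)
    if not observed:
        return pd.DataFrame(
            columns=["category", "n_candidate_genes", "n_background_genes", "p", "fwer"]
        )

    bg_list = sorted(background)
    lengths = (
        genes.set_index("gene").loc[bg_list]
        .assign(length=lambda d: d["end"] - d["start"])["length"]
        .to_numpy(dtype=float)
    )
    weights = lengths / lengths.sum()
    n_cand = len(candidate)
    min_ps = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = set(rng.choice(bg_list, size=n_cand, replace=False, p=weights))
        perm_results = hypergeometric_enrichment(perm, background, categories)
        min_ps[b] = min((r.p for r in perm_results), default=1.0)

    rows = []
    for res in observed:
        res.fwer = float(np.mean(min_ps <= res.p))
        rows.append(
            {
                "category": res.category,
                "n_candidate_genes": res.n_candidate_genes,
                "n_background_genes": res.n_background_genes,
                "p": res.p,
                "fwer": res.fwer,
            }
        )
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def read_genes_bed(path) -> pd.DataFrame:
    """BED with a 4th column naming the gene."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            rows.append(
                {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2]), "gene": parts[3]}
            )
    return pd.DataFrame(rows)


def read_gene_categories(path) -> pd.DataFrame:
    """Two-column TSV: gene, category (one row per membership)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "category"], comment="#")
    return df
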