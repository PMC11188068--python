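"""Synthetic diploid callsets with planted autozygosity and imputation-like
corruption.

The generator follows a deliberately simple mosaic-copy model: founder
haplotypes are drawn site-wise, additional panel haplotypes are mosaics of
the founders with per-bp template switching and per-site mutation.  Diploid
individuals are pairs of panel haplotypes; runs of homozygosity are planted
by duplicating one haplotype of the pair across a target interval.  A
corruption model then emulates what an imputation pipeline would emit:
genotype flips with class-dependent error rates that worsen at low minor
allele frequency, a per-site INFO score produced by a monotone map of the
planted error probability, Poisson read depth, and allelic depths.

All randomness derives from a single top-level seed via independent
spawned substreams so that stages can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .callset import MISSING, GenotypeTable, read_vcf, write_vcf
from .segments import Segment, check_disjoint, merge_segments, total_length

_BASES = np.array(list("ACGT"), dtype=object)


class SyntheticConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Panel simulation


@dataclass
class PanelConfig:
    """Parameters of the mosaic-copy haplotype panel."""

    n_haplotypes: int
    chrom_lengths: list  # [(name, bp), ...]
    site_density: float  # expected segregating sites per bp
    mosaic_switch_rate: float = 1e-5  # per-bp template switch probability
    mutation_rate: float = 0.005  # per-site flip probability on copy
    n_founders: int = 32
    seed: int = 0

    def validate(self) -> None:
        if self.n_haplotypes < 1:
            raise SyntheticConfigError("need at least one haplotype")
        if not self.chrom_lengths:
            raise SyntheticConfigError("no chromosomes configured")
        for name, length in self.chrom_lengths:
            if length <= 0:
                raise SyntheticConfigError(f"chromosome {name} has length {length}")
        for rate in (self.site_density, self.mosaic_switch_rate, self.mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise SyntheticConfigError(f"rate {rate} outside [0, 1]")
        if self.n_founders < 1:
            raise SyntheticConfigError("need at least one founder")


@dataclass
class Panel:
    """Binary haplotype panel with per-site allele frequencies."""

    chrom_lengths: dict
    positions: dict  # chrom -> 1-based positions, strictly increasing
    ref: dict
    alt: dict
    haplotypes: dict  # chrom -> (n_sites, n_haplotypes) uint8
    af: dict  # chrom -> alt allele frequency per site

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def n_haplotypes(self) -> int:
        first = next(iter(self.haplotypes.values()))
        return first.shape[1]

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())


def simulate_panel(cfg: PanelConfig) -> Panel:
    """Simulate the haplotype panel; deterministic given ``cfg.seed``."""
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(len(cfg.chrom_lengths))

    positions, ref, alt, haps, af = {}, {}, {}, {}, {}
    n_founders = min(cfg.n_founders, max(cfg.n_haplotypes, 1))
    for (name, length), ss in zip(cfg.chrom_lengths, streams):
        rng = np.random.default_rng(ss)
        n_sites = int(round(cfg.site_density * length))
        if n_sites < 1:
            raise SyntheticConfigError(f"chromosome {name}: zero sites at configured density")
        if n_sites > length:
            n_sites = length
        pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1

        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_shift = rng.integers(1, 4, size=n_sites)
        ref[name] = _BASES[ref_idx]
        alt[name] = _BASES[(ref_idx + alt_shift) % 4]

        founder_p = rng.beta(0.6, 0.6, size=n_sites)
        founders = (rng.random((n_sites, n_founders)) < founder_p[:, None]).astype(np.uint8)

        H = np.empty((n_sites, cfg.n_haplotypes), dtype=np.uint8)
        gaps = np.diff(pos, prepend=pos[0])
        switch_p = 1.0 - np.exp(-cfg.mosaic_switch_rate * gaps)
        for h in range(cfg.n_haplotypes):
            switches = rng.random(n_sites) < switch_p
            switches[0] = True
            idx = np.flatnonzero(switches)
            choices = rng.integers(0, n_founders, size=len(idx))
            template = choices[np.searchsorted(idx, np.arange(n_sites), side="right") - 1]
            hap = founders[np.arange(n_sites), template].copy()
            if cfg.mutation_rate > 0:
                flips = rng.random(n_sites) < cfg.mutation_rate
                hap[flips] ^= 1
            H[:, h] = hap

        positions[name] = pos
        haps[name] = H
        af[name] = H.mean(axis=1)

    return Panel(
        chrom_lengths=dict(cfg.chrom_lengths),
        positions=positions,
        ref=ref,
        alt=alt,
        haplotypes=haps,
        af=af,
    )


# ---------------------------------------------------------------------------
# Individuals and ROH planting


@dataclass
class Individual:
    """A diploid individual: a pair of haplotype tracks per chromosome."""

    panel: Panel
    name: str
    haps: dict  # chrom -> (n_sites, 2) uint8


@dataclass
class TruthGenome:
    """Ground-truth genotypes with the exact planted ROH coordinates."""

    table: GenotypeTable
    planted_segments: list
    genome_length: int

    @property
    def froh_truth(self) -> float:
        return total_length(merge_segments(self.planted_segments)) / self.genome_length


def sample_individual(panel: Panel, name: str, seed: int) -> Individual:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    haps = {}
    for chrom in panel.chroms:
        i, j = rng.choice(panel.n_haplotypes, size=2, replace=panel.n_haplotypes < 2)
        haps[chrom] = np.stack(
            [panel.haplotypes[chrom][:, i], panel.haplotypes[chrom][:, j]], axis=1
        )
    return Individual(panel=panel, name=name, haps=haps)


def _draw_segments(panel: Panel, target_froh: float, long_fraction: float, rng) -> list[Segment]:
    """Place non-overlapping segments totalling ~target_froh of the genome,
    mixing short (0.5-1.6 Mb) and long (1.6-8 Mb) tract lengths."""
    genome_length = panel.genome_length
    target_bp = target_froh * genome_length
    segments: list[Segment] = []
    placed_bp = 0
    chroms = panel.chroms
    weights = np.array([panel.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    attempts = 0
    min_len = 500_000
    while placed_bp < target_bp and attempts < 10000:
        attempts += 1
        remaining = target_bp - placed_bp
        if remaining < min_len:
            break
        if rng.random() < long_fraction:
            length = int(rng.uniform(1.6e6, 8e6))
        else:
            length = int(rng.uniform(5e5, 1.6e6))
        if length > remaining:
            length = max(int(remaining), min_len)
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        clen = panel.chrom_lengths[chrom]
        if length >= clen:
            continue
        start = int(rng.integers(0, clen - length))
        cand = Segment(chrom, start, start + length)
        if any(cand.overlaps(s) for s in segments):
            continue
        segments.append(cand)
        placed_bp += length
    return merge_segments(segments)


def plant_roh(
    individual: Individual,
    segments: list | None = None,
    target_froh: float | None = None,
    long_fraction: float = 0.5,
    seed: int = 0,
    mean_depth: float = 30.0,
) -> TruthGenome:
    """Force homozygosity inside the requested tracts by duplicating one
    haplotype of the pair, leaving all other sites untouched.

    Either an explicit segment list or a ``target_froh`` (with a short/long
    length mix) must be given.
    """
    panel = individual.panel
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if target_froh is not None:
        if not 0.0 <= target_froh <= 1.0:
            raise SyntheticConfigError(f"target F_ROH {target_froh} outside [0, 1]")
        if segments is not None:
            raise SyntheticConfigError("give either segments or target_froh, not both")
        segments = [] if target_froh == 0 else _draw_segments(panel, target_froh, long_fraction, rng)
    elif segments is None:
        raise SyntheticConfigError("give either segments or target_froh")
    else:
        for seg in segments:
            if seg.chrom not in panel.chrom_lengths:
                raise SyntheticConfigError(f"unknown chromosome {seg.chrom}")
            if seg.end > panel.chrom_lengths[seg.chrom]:
                raise SyntheticConfigError(f"segment {seg} exceeds chromosome bounds")
        segments = merge_segments(segments)
    check_disjoint(segments, "planted segments")

    haps = {c: h.copy() for c, h in individual.haps.items()}
    for seg in segments:
        pos = panel.positions[seg.chrom]
        in_seg = (pos - 1 >= seg.start) & (pos - 1 < seg.end)
        keep = int(rng.integers(0, 2))
        haps[seg.chrom][in_seg, 1 - keep] = haps[seg.chrom][in_seg, keep]

    table = _individual_table(panel, individual.name, haps, mean_depth, rng)
    return TruthGenome(
        table=table, planted_segments=segments, genome_length=panel.genome_length
    )


def _individual_table(panel: Panel, name: str, haps: dict, mean_depth: float, rng) -> GenotypeTable:
    chrom_col, pos_col, ref_col, alt_col, af_col, gt_col = [], [], [], [], [], []
    for chrom in panel.chroms:
        pos = panel.positions[chrom]
        chrom_col.append(np.full(len(pos), chrom, dtype=object))
        pos_col.append(pos)
        ref_col.append(panel.ref[chrom])
        alt_col.append(panel.alt[chrom])
        af_col.append(panel.af[chrom])
        gt_col.append(haps[chrom].sum(axis=1).astype(np.int8))
    gt = np.concatenate(gt_col)[:, None]
    n = gt.shape[0]
    dp = rng.poisson(mean_depth, size=(n, 1)).astype(np.int32)
    ad = _draw_allelic_depths(gt, dp, rng)
    return GenotypeTable(
        chrom=np.concatenate(chrom_col),
        pos=np.concatenate(pos_col),
        ref=np.concatenate(ref_col),
        alt=np.concatenate(alt_col),
        af=np.concatenate(af_col),
        info=np.full(n, np.nan),
        samples=[name],
        gt=gt,
        dp=dp,
        ad=ad,
        prob=np.ones((n, 1)),
        contigs=dict(panel.chrom_lengths),
    )


def _draw_allelic_depths(gt, dp, rng) -> np.ndarray:
    """Alt-read counts ~ Binomial(DP, dose/2) with a small base-error floor
    at homozygous sites so allele-balance filters have something to act on."""
    frac = np.clip(gt.astype(float) / 2.0, 0.01, 0.99)
    frac[gt == MISSING] = 0.0
    alt_reads = rng.binomial(dp, frac)
    return np.stack([dp - alt_reads, alt_reads], axis=-1).astype(np.int32)


# ---------------------------------------------------------------------------
# Imputation-like corruption


@dataclass
class CorruptionModel:
    """Error structure of an imputation-like observation process.

    Per-class flip probabilities apply at sites whose truth genotype is
    hom-ref / het / hom-alt; sites with folded MAF below ``maf_threshold``
    have their error probability multiplied by ``maf_error_multiplier``.
    The emitted INFO score is ``clip(1 - info_slope * p_err + noise, 0, 1)``
    — a monotone (for zero noise, strictly order-reversing) function of the
    planted per-site error probability, so INFO filtering provably enriches
    accuracy.
    """

    coverage: float = 1.0
    err_hom_ref: float = 0.01
    err_het: float = 0.03
    err_hom_alt: float = 0.06
    maf_error_multiplier: float = 2.0
    maf_threshold: float = 0.05
    info_slope: float = 4.0
    info_noise_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for p in (self.err_hom_ref, self.err_het, self.err_hom_alt, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise SyntheticConfigError(f"probability {p} outside [0, 1]")
        if self.coverage < 0:
            raise SyntheticConfigError("negative coverage")
        if self.maf_error_multiplier < 0:
            raise SyntheticConfigError("negative MAF multiplier")


def planted_error_probability(truth: GenotypeTable, model: CorruptionModel) -> np.ndarray:
    """Per-site, per-sample genotype error probability under the model."""
    base = np.select(
        [truth.gt == 0, truth.gt == 1, truth.gt == 2],
        [model.err_hom_ref, model.err_het, model.err_hom_alt],
        default=0.0,
    )
    low_maf = truth.maf < model.maf_threshold
    mult = np.where(low_maf, model.maf_error_multiplier, 1.0)
    return np.clip(base * mult[:, None], 0.0, 0.95)


def corrupt_genotypes(truth: TruthGenome | GenotypeTable, model: CorruptionModel) -> GenotypeTable:
    """Produce an imputation-like observed callset from a truth callset.

    Site and sample dimensions are preserved exactly; deterministic given
    ``model.seed``.
    """
    model.validate()
    table = truth.table if isinstance(truth, TruthGenome) else truth
    rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    n, s = table.n_sites, table.n_samples

    p_err = planted_error_probability(table, model)
    flips = rng.random((n, s)) < p_err
    gt = table.gt.copy()

    # error destination: homs mostly slip to het, hets split between homs
    u = rng.random((n, s))
    dest = np.empty_like(gt)
    dest[gt == 0] = np.where(u[gt == 0] < 0.9, 1, 2)
    dest[gt == 1] = np.where(u[gt == 1] < 0.5, 0, 2)
    dest[gt == 2] = np.where(u[gt == 2] < 0.9, 1, 0)
    observed = np.where(flips & (gt >= 0), dest, gt).astype(np.int8)

    if model.missing_rate > 0:
        observed[rng.random((n, s)) < model.missing_rate] = MISSING

    site_err = p_err.mean(axis=1)
    info = 1.0 - model.info_slope * site_err
    if model.info_noise_sd > 0:
        info = info + rng.normal(0.0, model.info_noise_sd, size=n)
    info = np.clip(info, 0.0, 1.0)

    dp = rng.poisson(model.coverage, size=(n, s)).astype(np.int32)
    ad = _draw_allelic_depths(observed, dp, rng)
    prob = np.clip(1.0 - p_err, 0.0, 1.0)

    return GenotypeTable(
        chrom=table.chrom.copy(),
        pos=table.pos.copy(),
        ref=table.ref.copy(),
        alt=table.alt.copy(),
        af=table.af.copy(),
        info=info,
        qual=table.qual.copy(),
        samples=list(table.samples),
        gt=observed,
        dp=dp,
        ad=ad,
        prob=prob,
        contigs=dict(table.contigs),
    )


def pseudohaploidize(table: GenotypeTable, seed: int = 0) -> GenotypeTable:
    """Emulate pseudohaploid calling: at each site sample a single allele
    and report it as a homozygous diploid dose (0 or 2)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gt = table.gt.copy()
    hets = gt == 1
    gt[hets] = rng.choice([0, 2], size=int(hets.sum())).astype(np.int8)
    gt[gt == 2] = 2
    out = table.take(np.arange(table.n_sites))
    out.gt = gt
    return out


def attach_read_data(table: GenotypeTable, mean_depth: float, seed: int = 0) -> GenotypeTable:
    """Redraw DP/AD around a new mean depth (used for coverage sweeps)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = table.take(np.arange(table.n_sites))
    out.dp = rng.poisson(mean_depth, size=out.gt.shape).astype(np.int32)
    out.ad = _draw_allelic_depths(out.gt, out.dp, rng)
    return out


# ---------------------------------------------------------------------------
# Serialization (VCF plumbing)


def write_callset(table: GenotypeTable, path) -> None:
    write_vcf(table, path)


def read_callset(path) -> GenotypeTable:
    return read_vcf(path)
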