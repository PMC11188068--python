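"""End-to-end orchestration.

Two modes:

* benchmark — synthesize a panel and truth genomes, emit imputation-like
  corrupted copies at several coverage levels, then score concordance,
  ROH-call accuracy, and PC-distance for imputed-like vs pseudohaploid-like
  tracks at each level.
* analysis — synthesize (or load) per-sample callsets for labelled cohorts,
  call ROH, summarise F_ROH with cohort rank-sum tests, build the windowed
  prevalence track, detect deserts, and (when annotations are supplied)
  run the enrichment test.

Coverage "downsampling" is emulated by scaling the corruption model's depth
and error parameters; the mapping is an explicit config table.  Every output
is reproducible byte-for-byte under a fixed seed, and a JSON manifest
records the seed, a config hash, and a checksum per output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance, filters, inbreeding, landscape, pca, roh_accuracy, roh_caller
from . import synthetic
from .segments import Segment, write_bed, write_chrom_sizes

logger = logging.getLogger(__name__)

#: error-rate scale factor applied to the base corruption model per coverage
DEFAULT_COVERAGE_ERROR_SCALE = {
    0.05: 8.0,
    0.1: 5.0,
    0.2: 3.0,
    0.5: 1.5,
    1.0: 1.0,
    2.0: 0.6,
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    mode: str = "benchmark"
    seed: int = 0
    outdir: str = "paleoroh_out"
    coverage_levels: tuple = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0)
    coverage_error_scale: dict = field(
        default_factory=lambda: dict(DEFAULT_COVERAGE_ERROR_SCALE)
    )
    # synthetic scale (kept desk-sized by default)
    n_haplotypes: int = 40
    chrom_lengths: tuple = (("chr1", 30_000_000), ("chr2", 20_000_000))
    site_density: float = 1.0 / 5000.0
    n_samples: int = 4
    target_froh: float = 0.10
    # cohort design for analysis mode
    cohort_froh: dict = field(default_factory=lambda: {"ancient": 0.05, "modern": 0.15})
    samples_per_cohort: int = 6
    window_size: int = 500_000
    filter_spec: filters.FilterSpec = field(default_factory=filters.FilterSpec)
    roh_params: roh_caller.ROHParams = field(default_factory=roh_caller.ROHParams)
    base_model: synthetic.CorruptionModel = field(default_factory=synthetic.CorruptionModel)

    def validate(self) -> None:
        if self.mode not in ("benchmark", "analysis"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if any(c <= 0 for c in self.coverage_levels):
            raise PipelineError("coverage levels must be positive")


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, cfg: RunConfig, outputs: list[Path]) -> Path:
    manifest = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(outputs)
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _scaled_model(cfg: RunConfig, coverage: float, seed: int) -> synthetic.CorruptionModel:
    scale = cfg.coverage_error_scale.get(coverage)
    if scale is None:  # interpolate on log-coverage for unlisted levels
        known = sorted(cfg.coverage_error_scale.items())
        xs = np.log([c for c, _ in known])
        ys = [s for _, s in known]
        scale = float(np.interp(np.log(coverage), xs, ys))
    base = cfg.base_model
    return synthetic.CorruptionModel(
        coverage=coverage,
        err_hom_ref=min(base.err_hom_ref * scale, 0.5),
        err_het=min(base.err_het * scale, 0.5),
        err_hom_alt=min(base.err_hom_alt * scale, 0.5),
        maf_error_multiplier=base.maf_error_multiplier,
        maf_threshold=base.maf_threshold,
        info_slope=base.info_slope,
        info_noise_sd=base.info_noise_sd,
        missing_rate=base.missing_rate,
        seed=seed,
    )


def _stage(name: str):
    logger.info("stage=%s event=start", name)
    return time.monotonic()


def _stage_done(name: str, t0: float):
    logger.info("stage=%s event=done elapsed=%.2fs", name, time.monotonic() - t0)


def run_benchmark(cfg: RunConfig) -> dict:
    """Benchmark mode; returns the report bundle paths."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    root = np.random.SeedSequence(cfg.seed)
    panel_seed, *sample_seeds = [int(s.generate_state(1)[0]) for s in root.spawn(1 + cfg.n_samples)]

    t0 = _stage("simulate_panel")
    panel = synthetic.simulate_panel(
        synthetic.PanelConfig(
            n_haplotypes=cfg.n_haplotypes,
            chrom_lengths=list(cfg.chrom_lengths),
            site_density=cfg.site_density,
            seed=panel_seed,
        )
    )
    _stage_done("simulate_panel", t0)

    truths = []
    for i, seed in enumerate(sample_seeds):
        ind = synthetic.sample_individual(panel, f"sample{i}", seed)
        truths.append(synthetic.plant_roh(ind, target_froh=cfg.target_froh, seed=seed + 1))

    genome_length = panel.genome_length
    conc_rows, roh_rows, pca_rows, r2_frames = [], [], [], []
    gate = concordance.ConcordanceGate()

    t0 = _stage("reference_pca")
    ref_tables = [
        synthetic.plant_roh(
            synthetic.sample_individual(panel, f"ref{i}", 90_000 + i), target_froh=0.0, seed=90_000 + i
        ).table
        for i in range(12)
    ]
    reference = _hstack_tables(ref_tables)
    space = pca.fit_pca(reference, n_components=min(10, len(ref_tables) - 1))
    _stage_done("reference_pca", t0)

    for coverage in cfg.coverage_levels:
        t0 = _stage(f"coverage_{coverage}")
        for i, truth in enumerate(truths):
            model = _scaled_model(cfg, coverage, seed=sample_seeds[i] + 7)
            imputed = synthetic.corrupt_genotypes(truth, model)
            filtered = filters.post_imputation_filter(imputed, cfg.filter_spec)

            report = concordance.concordance_report(truth.table, imputed, gate=gate)
            for _, row in report.iterrows():
                conc_rows.append({"coverage": coverage, "sample": truth.table.samples[0], **row})
            r2 = concordance.r2_by_maf_bin(truth.table, imputed, gate=gate)
            r2.insert(0, "coverage", coverage)
            r2.insert(1, "sample", truth.table.samples[0])
            r2_frames.append(r2)

            truth_segments = roh_caller.call_roh(truth.table, cfg.roh_params)
            pred_segments = roh_caller.call_roh(filtered, cfg.roh_params)
            metrics = roh_accuracy.score_roh(pred_segments, truth_segments, genome_length)
            roh_rows.append(
                {
                    "coverage": coverage,
                    "sample": truth.table.samples[0],
                    **{f"length_{k}": v for k, v in metrics["length"].items()},
                    **{f"segment_{k}": v for k, v in metrics["segment"].items()},
                }
            )

            hc_coords = pca.project(truth.table, space)
            imp_coords = pca.project(filtered, space)
            pseudo = synthetic.pseudohaploidize(truth.table, seed=sample_seeds[i] + 13)
            ph_coords = pca.project(pseudo, space)
            kk = space.n_components
            pca_rows.append(
                {
                    "coverage": coverage,
                    "sample": truth.table.samples[0],
                    "dist_imputed": pca.weighted_pc_distance(imp_coords, hc_coords, space, kk),
                    "dist_pseudohaploid": pca.weighted_pc_distance(ph_coords, hc_coords, space, kk),
                }
            )
        _stage_done(f"coverage_{coverage}", t0)

    conc_path = outdir / "concordance.tsv"
    pd.DataFrame(conc_rows).to_csv(conc_path, sep="\t", index=False)
    r2_path = outdir / "concordance_r2.tsv"
    pd.concat(r2_frames, ignore_index=True).to_csv(r2_path, sep="\t", index=False)
    roh_path = outdir / "roh_accuracy.tsv"
    pd.DataFrame(roh_rows).to_csv(roh_path, sep="\t", index=False)
    pca_path = outdir / "pc_distances.tsv"
    pd.DataFrame(pca_rows).to_csv(pca_path, sep="\t", index=False)
    sizes_path = outdir / "chrom.sizes"
    write_chrom_sizes(panel.chrom_lengths, sizes_path)
    outputs += [conc_path, roh_path, pca_path, sizes_path, r2_path]

    manifest = _write_manifest(outdir, cfg, outputs)
    return {"manifest": manifest, "outputs": outputs}


def _hstack_tables(tables) -> "synthetic.GenotypeTable":
    """Column-bind single-sample tables sharing identical sites."""
    from .callset import GenotypeTable

    first = tables[0]
    return GenotypeTable(
        chrom=first.chrom,
        pos=first.pos,
        ref=first.ref,
        alt=first.alt,
        af=first.af,
        info=first.info,
        qual=first.qual,
        samples=[t.samples[0] for t in tables],
        gt=np.concatenate([t.gt for t in tables], axis=1),
        dp=np.concatenate([t.dp for t in tables], axis=1),
        ad=np.concatenate([t.ad for t in tables], axis=1),
        prob=np.concatenate([t.prob for t in tables], axis=1),
        contigs=dict(first.contigs),
    )


def run_analysis(
    cfg: RunConfig,
    genes: pd.DataFrame | None = None,
    gene_categories: pd.DataFrame | None = None,
) -> dict:
    """Analysis mode on synthesized cohorts; returns report bundle paths."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    root = np.random.SeedSequence(cfg.seed)
    panel_seed = int(root.spawn(1)[0].generate_state(1)[0])

    t0 = _stage("simulate_cohorts")
    panel = synthetic.simulate_panel(
        synthetic.PanelConfig(
            n_haplotypes=cfg.n_haplotypes,
            chrom_lengths=list(cfg.chrom_lengths),
            site_density=cfg.site_density,
            seed=panel_seed,
        )
    )
    genome_length = panel.genome_length

    sample_segments: dict[str, list[Segment]] = {}
    cohort_of: dict[str, str] = {}
    summaries = []
    meta_rows = []
    idx = 0
    for cohort, target in cfg.cohort_froh.items():
        for _ in range(cfg.samples_per_cohort):
            name = f"{cohort}{idx}"
            seed = int(np.random.SeedSequence((cfg.seed, 1000 + idx)).generate_state(1)[0])
            ind = synthetic.sample_individual(panel, name, seed)
            truth = synthetic.plant_roh(ind, target_froh=target, seed=seed + 1)
            segments = roh_caller.call_roh(truth.table, cfg.roh_params)
            sample_segments[name] = segments
            cohort_of[name] = cohort
            summaries.append(
                inbreeding.froh(segments, genome_length, sample=name, cohort=cohort)
            )
            meta_rows.append({"sample": name, "cohort": cohort, "age_bp": np.nan, "region": ""})
            write_bed(segments, outdir / f"{name}.roh.bed")
            outputs.append(outdir / f"{name}.roh.bed")
            idx += 1
    _stage_done("simulate_cohorts", t0)

    t0 = _stage("froh")
    froh_df = inbreeding.froh_table(summaries)
    froh_path = outdir / "froh.tsv"
    froh_df.to_csv(froh_path, sep="\t", index=False)
    tests_df = inbreeding.pairwise_cohort_tests(froh_df)
    tests_path = outdir / "froh_tests.tsv"
    tests_df.to_csv(tests_path, sep="\t", index=False)
    outputs += [froh_path, tests_path]
    _stage_done("froh", t0)

    t0 = _stage("landscape")
    track = landscape.window_prevalence(
        sample_segments, cohort_of, panel.chrom_lengths, cfg.window_size
    )
    depth = np.full(len(track), cfg.base_model.coverage)
    n_sites = _sites_per_window(panel, track)
    track = landscape.exclude_outlier_windows(track, depth, n_sites)
    track_path = outdir / "window_track.tsv"
    track.to_csv(track_path, sep="\t", index=False)
    deserts = landscape.detect_deserts(track, list(cfg.cohort_froh))
    desert_path = outdir / "deserts.bed"
    deserts.to_csv(desert_path, sep="\t", index=False, header=False)
    outputs += [track_path, desert_path]
    _stage_done("landscape", t0)

    if genes is not None and gene_categories is not None:
        t0 = _stage("enrichment")
        retained = track.loc[~track["excluded"], ["chrom", "start", "end"]]
        enr = landscape.enrichment(
            deserts, genes, gene_categories, retained, seed=cfg.seed
        )
        enr_path = outdir / "enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False)
        outputs.append(enr_path)
        _stage_done("enrichment", t0)

    meta_path = outdir / "metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)
    outputs.append(meta_path)
    manifest = _write_manifest(outdir, cfg, outputs)
    return {"manifest": manifest, "outputs": outputs, "froh": froh_df, "deserts": deserts}


def _sites_per_window(panel, track: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(track), dtype=np.int64)
    for chrom in panel.chroms:
        pos0 = panel.positions[chrom] - 1
        sel = track["chrom"] == chrom
        starts = track.loc[sel, "start"].to_numpy()
        ends = track.loc[sel, "end"].to_numpy()
        idx = np.flatnonzero(sel.to_numpy())
        for i, (s, e) in enumerate(zip(starts, ends)):
            counts[idx[i]] = int(np.sum((pos0 >= s) & (pos0 < e)))
    return counts
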