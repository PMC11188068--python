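import numpy as np
import pytest

from paleoroh import synthetic as sy
from paleoroh.callset import MISSING
from paleoroh.segments import Segment, merge_segments, total_length


def _tiny_cfg(**kw):
    base = dict(
        n_haplotypes=8,
        chrom_lengths=[("chr1", 1_000_000)],
        site_density=1 / 1000,
        seed=5,
    )
    base.update(kw)
    return sy.PanelConfig(**base)


class TestSimulatePanel:
    def test_single_founder_no_mutation_is_monomorphic(self):
        cfg = _tiny_cfg(n_haplotypes=4, n_founders=1, mutation_rate=0.0)
        panel = sy.simulate_panel(cfg)
        af = panel.af["chr1"]
        maf = np.minimum(af, 1 - af)
        assert np.all(maf == 0.0)

    def test_determinism(self):
        a = sy.simulate_panel(_tiny_cfg())
        b = sy.simulate_panel(_tiny_cfg())
        for chrom in a.chroms:
            assert np.array_equal(a.positions[chrom], b.positions[chrom])
            assert np.array_equal(a.haplotypes[chrom], b.haplotypes[chrom])
            assert np.array_equal(a.ref[chrom], b.ref[chrom])
            assert np.array_equal(a.alt[chrom], b.alt[chrom])

    def test_af_matches_brute_force_count(self):
        # oracle: per-site allele counts / n, tallied site by site in a loop
        cfg = _tiny_cfg(
            n_haplotypes=200, chrom_lengths=[("chr1", 10_000_000)], site_density=1 / 1000
        )
        panel = sy.simulate_panel(cfg)
        H = panel.haplotypes["chr1"]
        expected = np.array([sum(H[i, :]) / H.shape[1] for i in range(H.shape[0])])
        assert np.allclose(panel.af["chr1"], expected)

    def test_positions_strictly_increasing(self, small_panel):
        for chrom in small_panel.chroms:
            assert np.all(np.diff(small_panel.positions[chrom]) > 0)

    def test_ref_alt_differ_and_are_acgt(self, small_panel):
        for chrom in small_panel.chroms:
            ref, alt = small_panel.ref[chrom], small_panel.alt[chrom]
            assert set(ref) <= set("ACGT") and set(alt) <= set("ACGT")
            assert np.all(ref != alt)

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_haplotypes": 0},
            {"chrom_lengths": []},
            {"chrom_lengths": [("chr1", 0)]},
            {"site_density": -0.1},
            {"mutation_rate": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(sy.SyntheticConfigError):
            sy.simulate_panel(_tiny_cfg(**kw))

    def test_zero_sites_rejected(self):
        with pytest.raises(sy.SyntheticConfigError):
            sy.simulate_panel(_tiny_cfg(chrom_lengths=[("chr1", 10)], site_density=1e-6))


class TestPlantRoh:
    def test_zero_target_leaves_genotypes_unchanged(self, small_panel):
        ind = sy.sample_individual(small_panel, "s", 3)
        truth = sy.plant_roh(ind, target_froh=0.0, seed=4)
        assert truth.planted_segments == []
        assert truth.froh_truth == 0.0
        expected = np.concatenate(
            [ind.haps[c].sum(axis=1) for c in small_panel.chroms]
        )
        assert np.array_equal(truth.table.gt[:, 0], expected)

    def test_froh_truth_is_definitional(self, small_panel):
        segs = [Segment("chr1", 0, 6_000_000), Segment("chr2", 0, 4_000_000)]
        ind = sy.sample_individual(small_panel, "s", 3)
        truth = sy.plant_roh(ind, segments=segs, seed=4)
        assert truth.froh_truth == pytest.approx(10_000_000 / 50_000_000)

    def test_no_heterozygotes_inside_planted_tracts(self, truth_genome):
        # oracle: full scan of every planted tract
        table = truth_genome.table
        for seg in truth_genome.planted_segments:
            mask = (table.chrom == seg.chrom) & (table.pos - 1 >= seg.start) & (
                table.pos - 1 < seg.end
            )
            doses = table.gt[mask, 0]
            assert np.all((doses == 0) | (doses == 2))

    def test_sites_outside_tracts_untouched(self, small_panel):
        ind = sy.sample_individual(small_panel, "s", 3)
        seg = Segment("chr1", 1_000_000, 3_000_000)
        truth = sy.plant_roh(ind, segments=[seg], seed=4)
        baseline = sy.plant_roh(ind, target_froh=0.0, seed=4)
        outside = ~(
            (truth.table.chrom == "chr1")
            & (truth.table.pos - 1 >= seg.start)
            & (truth.table.pos - 1 < seg.end)
        )
        assert np.array_equal(truth.table.gt[outside, 0], baseline.table.gt[outside, 0])

    def test_target_froh_above_one_rejected(self, small_panel):
        ind = sy.sample_individual(small_panel, "s", 3)
        with pytest.raises(sy.SyntheticConfigError):
            sy.plant_roh(ind, target_froh=1.5, seed=4)

    def test_out_of_bounds_segment_rejected(self, small_panel):
        ind = sy.sample_individual(small_panel, "s", 3)
        with pytest.raises(sy.SyntheticConfigError):
            sy.plant_roh(ind, segments=[Segment("chr1", 0, 99_000_000)], seed=4)

    def test_target_froh_hit_closely(self, small_panel):
        for target in (0.05, 0.10, 0.25):
            ind = sy.sample_individual(small_panel, "s", 3)
            truth = sy.plant_roh(ind, target_froh=target, seed=8)
            assert truth.froh_truth == pytest.approx(target, abs=0.011)


class TestCorruptGenotypes:
    def test_zero_error_is_identity(self, truth_genome):
        model = sy.CorruptionModel(
            err_hom_ref=0, err_het=0, err_hom_alt=0, seed=2
        )
        obs = sy.corrupt_genotypes(truth_genome, model)
        assert np.array_equal(obs.gt, truth_genome.table.gt)

    def test_conserves_shape(self, truth_genome):
        obs = sy.corrupt_genotypes(truth_genome, sy.CorruptionModel(seed=2))
        assert obs.n_sites == truth_genome.table.n_sites
        assert obs.samples == truth_genome.table.samples

    def test_determinism(self, truth_genome):
        m = sy.CorruptionModel(seed=77)
        a = sy.corrupt_genotypes(truth_genome, m)
        b = sy.corrupt_genotypes(truth_genome, m)
        assert a.equals(b)

    def test_het_flip_rate_within_binomial_bound(self):
        # >= 100k het sites; realized flip fraction within 3 binomial SDs
        p = 0.05
        n = 120_000
        table = _constant_table(gt_value=1, n=n)
        model = sy.CorruptionModel(
            err_hom_ref=0, err_het=p, err_hom_alt=0,
            maf_error_multiplier=1.0, seed=5,
        )
        obs = sy.corrupt_genotypes(table, model)
        flipped = np.mean(obs.gt[:, 0] != 1)
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(flipped - p) < 3 * sd

    def test_low_info_sites_have_higher_planted_error(self, small_panel):
        ind = sy.sample_individual(small_panel, "s", 3)
        truth = sy.plant_roh(ind, target_froh=0.05, seed=4)
        model = sy.CorruptionModel(err_het=0.08, err_hom_alt=0.12, info_slope=6.0, seed=5)
        obs = sy.corrupt_genotypes(truth, model)
        p_err = sy.planted_error_probability(truth.table, model)[:, 0]
        low = obs.info < 0.8
        assert low.any() and (~low).any()
        assert p_err[low].mean() > p_err[~low].mean()


def _constant_table(gt_value: int, n: int):
    from paleoroh.callset import GenotypeTable

    return GenotypeTable(
        chrom=np.full(n, "chr1", dtype=object),
        pos=np.arange(1, n + 1),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "C", dtype=object),
        af=np.full(n, 0.5),
        info=np.full(n, np.nan),
        samples=["s"],
        gt=np.full((n, 1), gt_value, dtype=np.int8),
        dp=np.full((n, 1), 30, dtype=np.int32),
        ad=np.full((n, 1, 2), 15, dtype=np.int32),
        prob=np.ones((n, 1)),
        contigs={"chr1": n + 1},
    )


class TestCallsetRoundTrip:
    def test_round_trip_equality(self, tmp_path, small_panel):
        ind = sy.sample_individual(small_panel, "s", 3)
        truth = sy.plant_roh(ind, target_froh=0.05, seed=4)
        obs = sy.corrupt_genotypes(truth, sy.CorruptionModel(seed=5, missing_rate=0.01))
        sub = obs.take(np.arange(100))
        path = tmp_path / "x.vcf"
        sy.write_callset(sub, path)
        back = sy.read_callset(path)
        assert back.equals(sub)
        assert back.samples == sub.samples

    def test_af_written_to_six_decimals(self, tmp_path, truth_genome):
        sub = truth_genome.table.take(np.arange(50))
        path = tmp_path / "x.vcf"
        sy.write_callset(sub, path)
        back = sy.read_callset(path)
        assert np.allclose(back.af, sub.af, atol=1e-6)

    def test_sample_column_order_preserved(self, tmp_path):
        from paleoroh.callset import GenotypeTable

        n = 10
        table = GenotypeTable(
            chrom=np.full(n, "chr1", dtype=object),
            pos=np.arange(1, n + 1) * 100,
            ref=np.full(n, "A", dtype=object),
            alt=np.full(n, "T", dtype=object),
            af=np.full(n, 0.25),
            info=np.full(n, 0.9),
            samples=["zeta", "alpha", "mid"],
            gt=np.tile(np.array([0, 1, 2], dtype=np.int8), (n, 1)),
            dp=np.full((n, 3), 12, dtype=np.int32),
            ad=np.full((n, 3, 2), 6, dtype=np.int32),
            prob=np.ones((n, 3)),
            contigs={"chr1": 2000},
        )
        path = tmp_path / "multi.vcf"
        sy.write_callset(table, path)
        back = sy.read_callset(path)
        assert back.samples == ["zeta", "alpha", "mid"]
        assert np.array_equal(back.gt, table.gt)

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts\n"
            "chr1\tnot_a_number\t.\tA\tC\t.\tPASS\tAF=0.5\tGT\t0/1\n"
        )
        from paleoroh.callset import VcfParseError

        with pytest.raises(VcfParseError, match="line"):
            sy.read_callset(path)


class TestPseudohaploid:
    def test_doses_are_homozygous(self, truth_genome):
        ph = sy.pseudohaploidize(truth_genome.table, seed=6)
        assert set(np.unique(ph.gt)) <= {0, 2, MISSING}

    def test_hom_sites_unchanged(self, truth_genome):
        ph = sy.pseudohaploidize(truth_genome.table, seed=6)
        hom = truth_genome.table.gt != 1
        assert np.array_equal(ph.gt[hom], truth_genome.table.gt[hom])


class TestSegments:
    def test_merge_abutting(self):
        merged = merge_segments(
            [Segment("chr1", 0, 100), Segment("chr1", 100, 200), Segment("chr2", 0, 50)]
        )
        assert merged == [Segment("chr1", 0, 200, 0), Segment("chr2", 0, 50)]
        assert total_length(merged) == 250
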