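import numpy as np
import pytest

from paleoroh import roh_caller as rc
from paleoroh import synthetic as sy
from paleoroh.roh_caller import HET, HOM, MISS
from paleoroh.segments import Segment


def oracle_call(pos, calls, p: rc.ROHParams):
    """Independent brute-force enumerator of the window rules.

    Enumerates every fully-contained window directly, computes each SNP's
    hit fraction from the windows covering it, then applies the run/gap and
    segment emission rules literally.
    """
    n = len(pos)
    w = p.window_snp
    if n < w:
        return []
    passing = []
    for j in range(n - w + 1):
        win = calls[j : j + w]
        n_het = int(np.sum(win == HET))
        n_mis = int(np.sum(win == MISS))
        passing.append(n_het <= p.window_het and n_mis <= p.window_missing)
    eligible = []
    for i in range(n):
        covering = [j for j in range(n - w + 1) if j <= i <= j + w - 1]
        frac = sum(passing[j] for j in covering) / len(covering)
        eligible.append(frac >= p.window_threshold)
    segments = []
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1] and pos[j + 1] - pos[j] <= p.max_gap_kb * 1000:
            j += 1
        n_snps = j - i + 1
        span = int(pos[j] - pos[i] + 1)
        if (
            n_snps >= p.min_snp
            and span >= p.min_kb * 1000
            and span / n_snps <= p.max_density_kb_per_snp * 1000
        ):
            segments.append((int(pos[i] - 1), int(pos[j]), n_snps))
        i = j + 1
    return segments


def as_tuples(segments):
    return [(s.start, s.end, s.n_snps) for s in segments]


class TestCallRohBasics:
    def test_long_homozygous_run_single_segment(self):
        pos = np.arange(1, 1001) * 10_000  # 1,000 SNPs spaced 10 kb
        calls = np.full(1000, HOM, dtype=np.int8)
        segs = rc.call_roh_track("chr1", pos, calls)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.n_snps == 1000
        assert seg.start == pos[0] - 1 and seg.end == pos[-1]
        assert as_tuples(segs) == oracle_call(pos, calls, rc.ROHParams())

    def test_all_heterozygous_no_segments(self):
        pos = np.arange(1, 1001) * 10_000
        calls = np.full(1000, HET, dtype=np.int8)
        assert rc.call_roh_track("chr1", pos, calls) == []

    def test_run_of_49_fails_min_snp(self):
        # 49 hom SNPs flanked by dense heterozygosity
        calls = np.array([HET] * 200 + [HOM] * 49 + [HET] * 200, dtype=np.int8)
        pos = np.arange(1, len(calls) + 1) * 15_000
        assert rc.call_roh_track("chr1", pos, calls) == []
        assert oracle_call(pos, calls, rc.ROHParams()) == []

    def test_short_chromosome_warns_and_returns_empty(self, caplog):
        pos = np.arange(1, 31) * 10_000
        calls = np.full(30, HOM, dtype=np.int8)
        with caplog.at_level("WARNING"):
            assert rc.call_roh_track("chr1", pos, calls) == []
        assert "no calls" in caplog.text

    def test_unsorted_positions_rejected(self):
        with pytest.raises(rc.RohCallerError):
            rc.call_roh_track("chr1", np.array([100, 50]), np.zeros(2, dtype=np.int8))

    def test_invalid_params_rejected(self):
        with pytest.raises(rc.RohCallerError):
            rc.ROHParams(window_threshold=0.0).validate()

    def test_gap_splits_runs(self):
        # two 100-SNP hom blocks separated by a 600 kb gap
        left = np.arange(1, 101) * 10_000
        right = left[-1] + 600_000 + np.arange(1, 101) * 10_000
        pos = np.concatenate([left, right])
        calls = np.full(200, HOM, dtype=np.int8)
        segs = rc.call_roh_track("chr1", pos, calls)
        assert len(segs) == 2
        assert as_tuples(segs) == oracle_call(pos, calls, rc.ROHParams())

    def test_missing_calls_do_not_break_runs(self):
        calls = np.full(300, HOM, dtype=np.int8)
        calls[150] = MISS
        pos = np.arange(1, 301) * 10_000
        segs = rc.call_roh_track("chr1", pos, calls)
        assert len(segs) == 1
        assert segs[0].n_snps == 300


def random_track(rng, n):
    """State-switching track: hom stretches interleaved with noisy regions."""
    calls = np.empty(n, dtype=np.int8)
    i = 0
    in_roh = rng.random() < 0.5
    while i < n:
        run = int(rng.integers(20, 400))
        end = min(i + run, n)
        if in_roh:
            block = rng.choice(
                [HOM, HET, MISS], size=end - i, p=[0.96, 0.02, 0.02]
            )
        else:
            block = rng.choice(
                [HOM, HET, MISS], size=end - i, p=[0.55, 0.40, 0.05]
            )
        calls[i:end] = block
        in_roh = not in_roh
        i = end
    gaps = rng.integers(200, 40_000, size=n)
    # occasional huge gap to exercise the split rule
    big = rng.random(n) < 0.005
    gaps[big] = rng.integers(400_000, 800_000, size=int(big.sum()))
    pos = np.cumsum(gaps) + 1
    return pos.astype(np.int64), calls


def random_params(rng):
    return rc.ROHParams(
        window_snp=int(rng.integers(10, 60)),
        window_het=int(rng.integers(0, 3)),
        window_missing=int(rng.integers(1, 6)),
        window_threshold=float(rng.uniform(0.02, 0.3)),
        min_snp=int(rng.integers(20, 70)),
        min_kb=float(rng.choice([100.0, 300.0, 500.0])),
        max_gap_kb=float(rng.choice([200.0, 500.0, 1000.0])),
        max_density_kb_per_snp=float(rng.choice([50.0, 100.0])),
    )


class TestOracleEquivalence:
    def test_exact_equivalence_on_random_tracks(self):
        """>= 200 random tracks up to 5,000 SNPs, random parameters."""
        rng = np.random.default_rng(2024)
        n_with_segments = 0
        for trial in range(210):
            n = int(rng.integers(60, 1200)) if trial < 200 else int(rng.integers(3000, 5001))
            pos, calls = random_track(rng, n)
            params = random_params(rng) if trial % 2 else rc.ROHParams()
            got = as_tuples(rc.call_roh_track("chr1", pos, calls, params))
            expected = oracle_call(pos, calls, params)
            assert got == expected, f"trial {trial}"
            n_with_segments += bool(expected)
        assert n_with_segments >= 50  # the comparison is not vacuous

    def test_outputs_never_overlap_and_fit_chromosome(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pos, calls = random_track(rng, 2000)
            segs = rc.call_roh_track("chr1", pos, calls)
            for a, b in zip(segs, segs[1:]):
                assert a.end <= b.start
            assert sum(s.length for s in segs) <= pos[-1]

    def test_threshold_monotonicity(self):
        # lowering the threshold never removes a called base pair
        rng = np.random.default_rng(99)
        base = dict(max_density_kb_per_snp=1e9)  # density rule off (see ledger)
        for _ in range(20):
            pos, calls = random_track(rng, 1500)
            hi = rc.call_roh_track("chr1", pos, calls, rc.ROHParams(window_threshold=0.2, **base))
            lo = rc.call_roh_track("chr1", pos, calls, rc.ROHParams(window_threshold=0.05, **base))
            covered = np.zeros(int(pos[-1]) + 1, dtype=bool)
            for s in lo:
                covered[s.start : s.end] = True
            for s in hi:
                assert covered[s.start : s.end].all()


class TestOnGenotypeTables:
    def test_planted_segment_recovery(self, truth_genome):
        """Error-free genotypes at >= 1 SNP / 10 kb: every planted segment
        >= 1 Mb recovered with reciprocal overlap >= 0.95."""
        called = rc.call_roh(truth_genome.table)
        for planted in truth_genome.planted_segments:
            if planted.length < 1_000_000:
                continue
            best = 0.0
            for seg in called:
                if seg.chrom != planted.chrom:
                    continue
                inter = min(seg.end, planted.end) - max(seg.start, planted.start)
                if inter <= 0:
                    continue
                best = max(best, min(inter / planted.length, inter / seg.length))
            assert best >= 0.95, planted

    def test_transversion_mode_no_transitions_identity(self, truth_genome):
        table = truth_genome.table
        from paleoroh.filters import is_transversion

        tv_table = table.take(is_transversion(table.ref, table.alt))
        assert rc.call_roh_transversions(tv_table) == rc.call_roh(tv_table)

    def test_transition_only_segment_absent_in_transversion_mode(self):
        """A hom block supported only by transitions disappears when
        restricting to transversions."""
        n = 400
        pos = np.arange(1, n + 1) * 10_000
        gt = np.zeros((n, 1), dtype=np.int8)
        gt[:100] = 1
        gt[300:] = 1
        ref = np.full(n, "A", dtype=object)
        alt = np.full(n, "T", dtype=object)  # transversions outside the block
        ref[100:300] = "C"
        alt[100:300] = "T"  # the hom block is all transitions
        from paleoroh.callset import GenotypeTable

        table = GenotypeTable(
            chrom=np.full(n, "chr1", dtype=object),
            pos=pos,
            ref=ref,
            alt=alt,
            af=np.full(n, 0.3),
            info=np.full(n, np.nan),
            samples=["s"],
            gt=gt,
            dp=np.full((n, 1), 30, dtype=np.int32),
            ad=np.zeros((n, 1, 2), dtype=np.int32),
            prob=np.ones((n, 1)),
            contigs={"chr1": int(pos[-1]) + 1},
        )
        with_all = rc.call_roh(table)
        assert any(s.start >= 900_000 and s.end <= 3_010_000 for s in with_all)
        tv_only = rc.call_roh_transversions(table)
        assert tv_only == []

    def test_mixed_modes_match_oracle(self, truth_genome):
        table = truth_genome.table
        from paleoroh.filters import is_transversion

        params = rc.ROHParams()
        for tbl in (table, table.take(is_transversion(table.ref, table.alt))):
            for chrom in ("chr1", "chr2"):
                mask = tbl.chrom == chrom
                codes = rc.encode_calls(tbl.gt[mask, 0])
                got = as_tuples(rc.call_roh_track(chrom, tbl.pos[mask], codes, params))
                assert got == oracle_call(tbl.pos[mask], codes, params)
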