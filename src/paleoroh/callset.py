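"""In-memory genotype callset and VCF v4.2 round-trip I/O.

The central container is :class:`GenotypeTable`, a column-oriented table of
biallelic SNP sites by samples.  Genotypes are stored as alt-allele dose
(0, 1, 2) with ``-1`` as the missing sentinel.  Site-level annotations carry
the panel allele frequency (``AF``) and the imputation-quality score
(``INFO``); per-genotype fields carry depth (``DP``), allelic depths (``AD``)
and a genotype posterior probability (``PR``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

_VALID_BASES = frozenset("ACGT")


class CallsetError(ValueError):
    """Contract violation in a genotype table or its serialization."""


class VcfParseError(CallsetError):
    """Malformed VCF record; the message names the offending line."""


@dataclass
class GenotypeTable:
    """Biallelic diploid genotype calls for one or more samples.

    Attributes
    ----------
    chrom, pos : arrays of chromosome name and 1-based position.
    ref, alt : single-nucleotide reference/alternative alleles.
    af : panel alternative-allele frequency per site.
    info : imputation INFO score per site (NaN when not annotated).
    qual : site QUAL (NaN when not annotated).
    samples : ordered sample names.
    gt : ``(n_sites, n_samples)`` int8 alt dose, ``-1`` for missing.
    dp : ``(n_sites, n_samples)`` int32 read depth.
    ad : ``(n_sites, n_samples, 2)`` int32 ref/alt read depths.
    prob : ``(n_sites, n_samples)`` genotype posterior in [0, 1].
    contigs : chromosome lengths, used to emit VCF header contig lines.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    af: np.ndarray
    info: np.ndarray
    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray
    ad: np.ndarray
    prob: np.ndarray
    qual: np.ndarray = None  # type: ignore[assignment]
    contigs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.pos)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.af = np.asarray(self.af, dtype=np.float64)
        self.info = np.asarray(self.info, dtype=np.float64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        self.ad = np.asarray(self.ad, dtype=np.int32)
        self.prob = np.asarray(self.prob, dtype=np.float64)
        if self.qual is None:
            self.qual = np.full(n, np.nan)
        self.qual = np.asarray(self.qual, dtype=np.float64)
        s = self.n_samples
        if self.gt.shape != (n, s):
            raise CallsetError(f"gt shape {self.gt.shape} != ({n}, {s})")
        if self.dp.shape != (n, s) or self.prob.shape != (n, s):
            raise CallsetError("dp/prob shape mismatch")
        if self.ad.shape != (n, s, 2):
            raise CallsetError(f"ad shape {self.ad.shape} != ({n}, {s}, 2)")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def maf(self) -> np.ndarray:
        """Folded minor allele frequency, ``min(AF, 1 - AF)``."""
        return np.minimum(self.af, 1.0 - self.af)

    def take(self, index) -> "GenotypeTable":
        """Subset sites by boolean mask or integer index, keeping order."""
        idx = np.asarray(index)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            af=self.af[idx],
            info=self.info[idx],
            qual=self.qual[idx],
            gt=self.gt[idx],
            dp=self.dp[idx],
            ad=self.ad[idx],
            prob=self.prob[idx],
        )

    def site_keys(self) -> list[tuple]:
        return list(zip(self.chrom.tolist(), self.pos.tolist()))

    def equals(self, other: "GenotypeTable", check_read_data: bool = True) -> bool:
        if self.samples != other.samples or self.n_sites != other.n_sites:
            return False
        same = (
            bool(np.all(self.chrom == other.chrom))
            and bool(np.array_equal(self.pos, other.pos))
            and bool(np.all(self.ref == other.ref))
            and bool(np.all(self.alt == other.alt))
            and bool(np.allclose(self.af, other.af, atol=1e-6))
            and bool(np.allclose(self.info, other.info, atol=1e-6, equal_nan=True))
            and bool(np.array_equal(self.gt, other.gt))
        )
        if not same:
            return False
        if check_read_data:
            same = (
                bool(np.array_equal(self.dp, other.dp))
                and bool(np.array_equal(self.ad, other.ad))
                and bool(np.allclose(self.prob, other.prob, atol=1e-4))
            )
        return same


def _format_float(x: float, decimals: int = 6) -> str:
    return f"{x:.{decimals}f}"


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a GenotypeTable as uncompressed VCF v4.2.

    Emits ``INFO=AF,INFO`` site annotations and ``FORMAT=GT:DP:AD:PR``
    genotype fields.  The INFO annotation is omitted at sites where it is
    NaN (e.g. truth callsets that never went through imputation).
    """
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=paleoroh\n")
    for name, length in table.contigs.items():
        buf.write(f"##contig=<ID={name},length={int(length)}>\n")
    buf.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Panel alternative allele frequency">\n')
    buf.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality score">\n')
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    buf.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
    buf.write('##FORMAT=<ID=PR,Number=1,Type=Float,Description="Genotype posterior probability">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(table.samples))
    buf.write("\n")

    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for i in range(table.n_sites):
        info_parts = [f"AF={_format_float(table.af[i])}"]
        if not np.isnan(table.info[i]):
            info_parts.append(f"INFO={_format_float(table.info[i], 4)}")
        qual = "." if np.isnan(table.qual[i]) else f"{table.qual[i]:g}"
        fields = [
            str(table.chrom[i]),
            str(int(table.pos[i])),
            ".",
            str(table.ref[i]),
            str(table.alt[i]),
            qual,
            "PASS",
            ";".join(info_parts),
            "GT:DP:AD:PR",
        ]
        for j in range(table.n_samples):
            fields.append(
                f"{gt_strings[int(table.gt[i, j])]}:{int(table.dp[i, j])}:"
                f"{int(table.ad[i, j, 0])},{int(table.ad[i, j, 1])}:"
                f"{_format_float(table.prob[i, j], 4)}"
            )
        buf.write("\t".join(fields))
        buf.write("\n")

    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_vcf(path) -> GenotypeTable:
    """Read a VCF produced by :func:`write_vcf` (or any biallelic SNP VCF
    with GT and the optional DP/AD/PR fields) back into a GenotypeTable.

    Raises :class:`VcfParseError` naming the 1-based file line of the first
    malformed record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    contigs = {}
    for raw in vcf.raw_header.splitlines():
        if raw.startswith("##contig="):
            body = raw.split("<", 1)[1].rstrip(">")
            kv = dict(part.split("=", 1) for part in body.split(","))
            if "ID" in kv and "length" in kv:
                contigs[kv["ID"]] = int(kv["length"])
    n_header = vcf.raw_header.count("\n")

    chrom, pos, ref, alt = [], [], [], []
    af, info_score, qual = [], [], []
    gt_rows, dp_rows, ad_rows, pr_rows = [], [], [], []
    ns = len(samples)
    line_no = n_header
    try:
        for var in vcf:
            line_no += 1
            if len(var.ALT) != 1:
                raise VcfParseError(f"line {line_no}: expected biallelic site")
            chrom.append(var.CHROM)
            pos.append(var.POS)
            ref.append(var.REF)
            alt.append(var.ALT[0])
            site_af = var.INFO.get("AF")
            af.append(float(site_af) if site_af is not None else np.nan)
            site_info = var.INFO.get("INFO")
            info_score.append(float(site_info) if site_info is not None else np.nan)
            qual.append(var.QUAL if var.QUAL is not None else np.nan)

            doses = np.full(ns, MISSING, dtype=np.int8)
            for j, g in enumerate(var.genotypes):
                a, b = g[0], g[1]
                if a >= 0 and b >= 0:
                    doses[j] = a + b
            gt_rows.append(doses)

            dp = var.format("DP")
            dp_rows.append(
                np.zeros(ns, dtype=np.int32)
                if dp is None
                else np.where(dp[:, 0] < 0, 0, dp[:, 0]).astype(np.int32)
            )
            ad = var.format("AD")
            ad_rows.append(
                np.zeros((ns, 2), dtype=np.int32)
                if ad is None
                else np.clip(ad[:, :2], 0, None).astype(np.int32)
            )
            pr = var.format("PR")
            pr_rows.append(
                np.ones(ns) if pr is None else pr[:, 0].astype(np.float64)
            )
    except VcfParseError:
        raise
    except Exception as exc:  # htslib propagates malformed-record failures
        raise VcfParseError(f"line {line_no + 1}: {exc}") from exc

    n = len(pos)
    return GenotypeTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        af=np.array(af),
        info=np.array(info_score),
        qual=np.array(qual),
        samples=samples,
        gt=np.array(gt_rows, dtype=np.int8).reshape(n, ns),
        dp=np.array(dp_rows, dtype=np.int32).reshape(n, ns),
        ad=np.array(ad_rows, dtype=np.int32).reshape(n, ns, 2),
        prob=np.array(pr_rows).reshape(n, ns),
        contigs=contigs,
    )
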