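"""Genotype containers, VCF input/output, and variant/sample quality control.

Genotypes are stored as integer alternate-allele counts for diploid biallelic
SNPs: 0 (hom ref), 1 (het), 2 (hom alt), with :data:`MISSING` (-1) for missing
calls.  QC applies the standard array-genotyping filters — minor allele
frequency, an exact Hardy-Weinberg equilibrium test, and per-variant /
per-sample missingness — with strict threshold comparisons (a variant passes
MAF QC only if its MAF is strictly greater than the threshold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

VARIANT_COLUMNS = ("chrom", "pos", "id", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of alternate-allele counts.

    Parameters
    ----------
    calls
        ``(n_samples, n_variants)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt`` (1-based ``pos``).
    samples
        Sample identifiers, one per row of ``calls``.
    """

    calls: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if not isinstance(self.variants, pd.DataFrame):
            self.variants = pd.DataFrame(self.variants, columns=list(VARIANT_COLUMNS))
        self.samples = list(self.samples)
        n, L = self.calls.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} rows")
        if len(self.variants) != L:
            raise ValueError(f"{len(self.variants)} variant records for {L} columns")
        if (self.variants["pos"] < 1).any():
            raise ValueError("variant positions must be >= 1 (1-based)")
        if (self.variants["ref"] == self.variants["alt"]).any():
            raise ValueError("ref and alt alleles must differ")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def variant_keys(self) -> pd.Index:
        """``chrom:pos:ref:alt`` keys used to match variants across cohorts."""
        v = self.variants
        return pd.Index(
            v["chrom"].astype(str)
            + ":"
            + v["pos"].astype(str)
            + ":"
            + v["ref"].astype(str)
            + ":"
            + v["alt"].astype(str)
        )

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            self.samples,
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[index, :],
            self.variants.copy(),
            [self.samples[i] for i in np.atleast_1d(index)],
        )


@dataclass(frozen=True)
class QCThresholds:
    """QC cut-offs; comparisons are strict (pass iff strictly better)."""

    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    max_variant_missing: float = 0.1
    max_sample_missing: float = 0.1

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_min", "max_variant_missing", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_variants_in: int = 0
    n_samples_in: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_variant_missing: int = 0
    removed_all_missing: int = 0
    removed_samples: int = 0
    n_variants_out: int = 0
    n_samples_out: int = 0
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "thresholds"}
        d.update({f"threshold_{k}": v for k, v in self.thresholds.__dict__.items()})
        return d


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF (v4.x) into a :class:`GenotypeMatrix`.

    Multiallelic records and non-SNP alleles are skipped (their count is
    logged).  Any missing allele in a genotype makes the whole call MISSING;
    phase is ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"no samples (or no GT field) in {path}")
    rows: list[np.ndarray] = []
    records: list[tuple] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.asarray(var.genotype.array())  # (n, 3): allele0, allele1, phased
        alleles = gts[:, :2]
        calls = alleles.sum(axis=1)
        calls[(alleles < 0).any(axis=1)] = MISSING
        rows.append(calls.astype(np.int8))
        records.append((var.CHROM, var.POS, var.ID or ".", var.REF, var.ALT[0]))
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not records:
        raise ValueError(f"no biallelic SNP records with GT found in {path}")
    calls = np.column_stack(rows) if rows else np.empty((len(samples), 0), dtype=np.int8)
    variants = pd.DataFrame(records, columns=list(VARIANT_COLUMNS))
    return GenotypeMatrix(calls, variants, samples)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write ``G`` as a minimal VCF v4.2 with GT-only diploid records."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = pd.unique(G.variants["chrom"].astype(str))
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j in range(G.n_variants):
            v = G.variants.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(g)] for g in G.calls[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Per-variant statistics
# ---------------------------------------------------------------------------

def compute_maf(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-variant minor-allele frequency, ignoring missing calls.

    Returns ``min(p, 1-p)`` with ``p = (sum of alt alleles) / (2 * n_called)``.
    All-missing variants get NaN (flagged, excluded downstream).
    """
    calls = G.calls if isinstance(G, GenotypeMatrix) else np.asarray(G)
    ok = calls != MISSING
    n_called = ok.sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return np.minimum(p, 1.0 - p)


def variant_missing_rate(G: GenotypeMatrix) -> np.ndarray:
    return (G.calls == MISSING).mean(axis=0)


def sample_missing_rate(G: GenotypeMatrix) -> np.ndarray:
    return (G.calls == MISSING).mean(axis=1)


def genotype_counts(G: GenotypeMatrix) -> np.ndarray:
    """``(n_variants, 3)`` counts of hom-ref, het, hom-alt (missing ignored)."""
    out = np.empty((G.n_variants, 3), dtype=np.int64)
    for g in (0, 1, 2):
        out[:, g] = (G.calls == g).sum(axis=0)
    return out


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg equilibrium test
# ---------------------------------------------------------------------------

def _het_weights(N: int, n_minor: int) -> tuple[list[int], list[int]]:
    """Exact integer weights of each possible heterozygote count.

    Conditional on ``N`` diploid genotypes and ``n_minor`` copies of the minor
    allele, HWE makes the heterozygote count ``h`` hypergeometric with
    probability proportional to ``N! / (n_mm! h! n_MM!) * 2**h`` where
    ``n_mm = (n_minor - h) / 2``; only ``h`` with the parity of ``n_minor``
    are possible.  Weights are exact integers so probability comparisons
    ("no more probable than observed") involve no rounding.
    """
    h0 = n_minor % 2
    hets = list(range(h0, min(n_minor, 2 * N - n_minor) + 1, 2))
    n_mm0 = (n_minor - h0) // 2
    w = (
        math.factorial(N)
        // (math.factorial(n_mm0) * math.factorial(h0) * math.factorial(N - n_mm0 - h0))
    ) * (1 << h0)
    weights = [w]
    for h in hets[:-1]:
        # w(h+2)/w(h) = 4 * n_mm * n_MM / ((h+1)(h+2)); the division is exact
        n_mm = (n_minor - h) // 2
        n_MM = N - n_mm - h
        w = w * (4 * n_mm * n_MM) // ((h + 1) * (h + 2))
        weights.append(w)
    return hets, weights


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value for one biallelic variant.

    Sums, under the hypergeometric null conditioned on the allele totals, the
    probabilities of all heterozygote counts no more probable than the
    observed one.  Computed in exact integer arithmetic.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    N = n_AA + n_Aa + n_aa
    if N == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hets, weights = _het_weights(N, n_minor)
    w_obs = weights[hets.index(n_Aa)]
    num = sum(w for w in weights if w <= w_obs)
    return min(1.0, num / sum(weights))


def hwe_p_values(G: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p per variant; NaN for all-missing variants."""
    counts = genotype_counts(G)
    out = np.empty(G.n_variants)
    cache: dict[tuple[int, int, int], float] = {}
    for j, (a, b, c) in enumerate(counts):
        key = (int(a), int(b), int(c))
        if key not in cache:
            cache[key] = hwe_exact_p(*key) if sum(key) > 0 else np.nan
        out[j] = cache[key]
    return out


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def qc_filter(
    G: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply variant then sample filters in a single fixed-order pass.

    A variant is kept iff MAF > ``maf_min``, HWE p > ``hwe_p_min`` and its
    missing rate < ``max_variant_missing`` (strict comparisons).  Samples are
    then kept iff their missing rate, over the retained variants, is
    < ``max_sample_missing``.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport(
        n_variants_in=G.n_variants, n_samples_in=G.n_samples, thresholds=thresholds
    )

    maf = compute_maf(G)
    miss_v = variant_missing_rate(G)
    hwe = hwe_p_values(G)

    all_missing = np.isnan(maf)
    pass_maf = np.where(all_missing, False, maf > thresholds.maf_min)
    pass_hwe = np.where(all_missing, False, hwe > thresholds.hwe_p_min)
    pass_miss = miss_v < thresholds.max_variant_missing
    keep_v = pass_maf & pass_hwe & pass_miss

    report.removed_all_missing = int(all_missing.sum())
    report.removed_maf = int((~pass_maf & ~all_missing).sum())
    report.removed_hwe = int((~pass_hwe & ~all_missing).sum())
    report.removed_variant_missing = int((~pass_miss).sum())

    G2 = G.take_variants(np.flatnonzero(keep_v))
    if G2.n_variants == 0:
        raise ValueError("QC removed every variant")

    miss_s = sample_missing_rate(G2)
    keep_s = miss_s < thresholds.max_sample_missing
    report.removed_samples = int((~keep_s).sum())
    G3 = G2.take_samples(np.flatnonzero(keep_s))
    if G3.n_samples == 0:
        raise ValueError("QC removed every sample")

    report.n_variants_out = G3.n_variants
    report.n_samples_out = G3.n_samples
    logger.info(
        "QC: %d/%d variants, %d/%d samples retained",
        report.n_variants_out,
        report.n_variants_in,
        report.n_samples_out,
        report.n_samples_in,
    )
    return G3, report


# ---------------------------------------------------------------------------
# Plain-matrix alternative format
# ---------------------------------------------------------------------------

def write_matrix(G: GenotypeMatrix, prefix: str) -> None:
    """Tab-separated integer matrix (``NA`` for missing) + sidecar tables."""
    df = pd.DataFrame(G.calls.astype(object))
    df[df == MISSING] = "NA"
    df.to_csv(f"{prefix}.matrix.tsv", sep="\t", header=False, index=False)
    G.variants.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
    pd.Series(G.samples, name="sample_id").to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)


def read_matrix(prefix: str) -> GenotypeMatrix:
    calls = pd.read_csv(f"{prefix}.matrix.tsv", sep="\t", header=None, na_values="NA")
    calls = calls.fillna(MISSING).to_numpy().astype(np.int8)
    variants = pd.read_csv(f"{prefix}.variants.tsv", sep="\t")
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t")["sample_id"].astype(str).tolist()
    return GenotypeMatrix(calls, variants, samples)
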