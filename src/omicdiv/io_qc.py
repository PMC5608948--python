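"""Genotype/matrix input-output and the sequential QC filter cascade.

Genotypes live in a :class:`GenotypeMatrix`: a samples x SNPs dosage frame
(alt-allele counts 0/1/2, NaN = missing) plus SNP and sample metadata.
Filters are small pure functions that return a new matrix together with a
:class:`QcStage` record; :class:`QcReport` accumulates stages in application
order and checks the removed+retained=input conservation at every step.

The cascade mirrors a standard array-genotyping workflow: merge overlapping
array content keeping the copy with less missingness, drop samples with
high missingness (or on an explicit exclusion list for duplicates/ethnicity
mismatches), then drop SNPs with high missingness or gross Hardy-Weinberg
departure within any single population.  Call-rate filters for quantitative
platforms (miRNA call rate, clinical-variable missingness) share the same
report machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "QcStage",
    "QcReport",
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "filter_snp_missingness",
    "filter_sample_missingness",
    "exclude_samples",
    "hwe_exact_test",
    "filter_hwe",
    "filter_call_rate",
    "merge_arrays",
    "genotype_concordance",
    "filter_concordance",
]

MISSING_TOKEN = "NA"


@dataclass
class GenotypeMatrix:
    """Dosage matrix with SNP and sample metadata.

    ``dosages``: DataFrame (samples x SNPs), values in {0, 1, 2, NaN}.
    ``snp_meta``: DataFrame indexed by SNP ID with ``chrom``, ``pos``
    (1-based), ``ref``, ``alt``.
    ``sample_meta``: DataFrame indexed by sample ID with at least
    ``population``; optionally ``sex``.
    """

    dosages: pd.DataFrame
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.is_unique:
            raise ValueError("duplicate sample IDs")
        if not self.dosages.columns.is_unique:
            raise ValueError("duplicate SNP IDs")
        if not self.dosages.columns.equals(self.snp_meta.index):
            self.snp_meta = self.snp_meta.reindex(self.dosages.columns)
        if not self.dosages.index.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.reindex(self.dosages.index)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        d = self.dosages
        if samples is not None:
            d = d.loc[samples]
        if snps is not None:
            d = d[snps]
        return GenotypeMatrix(
            d, self.snp_meta.loc[d.columns], self.sample_meta.loc[d.index]
        )


@dataclass
class QcStage:
    name: str
    axis: str  # "sample" | "snp" | "feature"
    n_input: int
    n_removed: int
    threshold: float | None = None
    removed_ids: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class QcReport:
    """Ordered record of QC stages with conservation checking."""

    stages: list = field(default_factory=list)

    def add(self, stage: QcStage) -> None:
        if stage.n_removed < 0 or stage.n_removed > stage.n_input:
            raise ValueError("removed count outside [0, n_input]")
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "axis": s.axis,
                    "n_input": s.n_input,
                    "n_removed": s.n_removed,
                    "n_retained": s.n_retained,
                    "threshold": s.threshold,
                }
                for s in self.stages
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = [
            {
                "stage": s.name,
                "axis": s.axis,
                "n_input": s.n_input,
                "n_removed": s.n_removed,
                "n_retained": s.n_retained,
                "threshold": s.threshold,
                "removed_ids": list(map(str, s.removed_ids)),
            }
            for s in self.stages
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------- I/O


def read_vcf(path, populations: pd.Series | None = None) -> GenotypeMatrix:
    """Read a VCF (v4.2, GT field) into a :class:`GenotypeMatrix`.

    Diploid GT is mapped to alt-allele dosage; ``./.`` becomes NaN.
    Multi-allelic records are rejected with an error naming the variant.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record not supported: {var.CHROM}:{var.POS} "
                f"({var.ID or '.'}) with ALT={var.ALT}"
            )
        gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    dosages = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample"),
        columns=pd.Index(snp_ids, name="snp"),
    )
    snp_meta = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=dosages.columns,
    )
    sample_meta = pd.DataFrame(index=dosages.index)
    sample_meta["population"] = (
        populations.reindex(dosages.index) if populations is not None else pd.NA
    )
    return GenotypeMatrix(dosages, snp_meta, sample_meta)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with a GT field only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.snp_meta["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.dosages.index))
            + "\n"
        )
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        dos = g.dosages.to_numpy()
        for j, snp in enumerate(g.dosages.columns):
            meta = g.snp_meta.loc[snp]
            gts = "\t".join(
                "./." if np.isnan(v) else code[v] for v in dos[:, j]
            )
            fh.write(
                f"{meta['chrom']}\t{int(meta['pos'])}\t{snp}\t{meta['ref']}\t"
                f"{meta['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_dosage_tsv(path, populations: pd.Series | None = None) -> GenotypeMatrix:
    """Read a samples x SNPs dosage TSV (header = SNP IDs, ``NA`` missing)."""
    dosages = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    dosages.index.name = "sample"
    snp_meta = pd.DataFrame(
        {"chrom": "NA", "pos": 0, "ref": "N", "alt": "N"}, index=dosages.columns
    )
    sample_meta = pd.DataFrame(index=dosages.index)
    sample_meta["population"] = (
        populations.reindex(dosages.index) if populations is not None else pd.NA
    )
    return GenotypeMatrix(dosages, snp_meta, sample_meta)


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    out = g.dosages.copy()
    out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------- filters


def filter_snp_missingness(
    g: GenotypeMatrix, max_miss: float = 0.05, report: QcReport | None = None
) -> tuple[GenotypeMatrix, QcStage]:
    """Drop SNPs whose missing fraction is *strictly greater* than max_miss."""
    if not 0.0 <= max_miss <= 1.0:
        raise ValueError("max_miss must be in [0, 1]")
    miss = g.dosages.isna().mean(axis=0)
    drop = miss.index[miss > max_miss]
    stage = QcStage(
        "snp_missingness", "snp", g.n_snps, len(drop), max_miss, list(drop)
    )
    if report is not None:
        report.add(stage)
    return g.subset(snps=g.dosages.columns.difference(drop, sort=False)), stage


def filter_sample_missingness(
    g: GenotypeMatrix, max_miss: float = 0.02, report: QcReport | None = None
) -> tuple[GenotypeMatrix, QcStage]:
    """Drop samples whose missing fraction is strictly greater than max_miss."""
    if not 0.0 <= max_miss <= 1.0:
        raise ValueError("max_miss must be in [0, 1]")
    miss = g.dosages.isna().mean(axis=1)
    drop = miss.index[miss > max_miss]
    stage = QcStage(
        "sample_missingness", "sample", g.n_samples, len(drop), max_miss, list(drop)
    )
    if report is not None:
        report.add(stage)
    return g.subset(samples=g.dosages.index.difference(drop, sort=False)), stage


def exclude_samples(
    g: GenotypeMatrix,
    exclude: Sequence[str],
    reason: str = "exclusion_list",
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcStage]:
    """List-based sample removal (duplicates, relatedness, label mismatch).

    Those removals require external genetic inference, so callers supply the
    IDs; this stage only applies and records them.
    """
    present = [s for s in exclude if s in g.dosages.index]
    stage = QcStage(reason, "sample", g.n_samples, len(present), None, present)
    if report is not None:
        report.add(stage)
    keep = g.dosages.index.difference(present, sort=False)
    return g.subset(samples=keep), stage


# ---------------------------------------------------------------- HWE


@lru_cache(maxsize=None)
def _hwe_pvalue_table(n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and two-sided p-values of the conditional heterozygote count.

    Given minor/major allele counts (n_a, n_b) with n_a + n_b = 2N, the
    heterozygote count H under Hardy-Weinberg has the exact conditional pmf

        P(H = h) = N! / (n_AA! h! n_BB!) * 2^h * n_a! n_b! / (2N)!

    with n_AA = (n_a - h)/2, n_BB = (n_b - h)/2 and h running over values of
    the same parity as n_a.  The two-sided p-value of an observed h is the
    total probability of all heterozygote counts no more probable than h
    (the usual exact-test convention for genotyping QC).

    Returns (support, pvals) arrays aligned elementwise; cached per
    unordered allele-count pair.
    """
    if n_a > n_b:
        n_a, n_b = n_b, n_a
    n = (n_a + n_b) // 2
    h = np.arange(n_a % 2, n_a + 1, 2)
    log_pmf = (
        gammaln(n + 1)
        - gammaln((n_a - h) / 2 + 1)
        - gammaln(h + 1)
        - gammaln((n_b - h) / 2 + 1)
        + h * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    pmf = np.exp(log_pmf - log_pmf.max())
    pmf /= pmf.sum()
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    # p(h) = total mass of support points with pmf <= pmf(h) (with a float
    # tolerance so exactly tied, symmetric points are always included)
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + 1e-9), side="right")
    pvals = np.minimum(csum[np.clip(idx - 1, 0, len(csum) - 1)], 1.0)
    return h, pvals


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test on one population's genotype counts.

    Conditions on the observed allele counts and sums the probability of
    every heterozygote count no more probable than the observed one.
    Monomorphic input returns p = 1 by convention.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n_hom_ref, n_het, n_hom_alt = map(int, counts)
    if n_hom_ref + n_het + n_hom_alt < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_hom_alt + n_het
    n_b = 2 * n_hom_ref + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    support, pvals = _hwe_pvalue_table(n_a, n_b)
    return float(pvals[np.searchsorted(support, n_het)])


def filter_hwe(
    g: GenotypeMatrix,
    p_threshold: float = 1e-3,
    mode: Literal["any", "all"] = "any",
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcStage]:
    """Drop SNPs departing from HWE within the populations.

    The exact test runs separately in each population; with ``mode="any"``
    (default) a SNP is removed when p < p_threshold in *any* population,
    with ``mode="all"`` only when it fails in every population.
    """
    pops = g.sample_meta["population"]
    if pops.isna().any():
        raise ValueError("population labels required for the HWE filter")
    fail_counts = pd.Series(0, index=g.dosages.columns)
    n_pops = pops.nunique()
    for _, block in g.dosages.groupby(pops, sort=False):
        arr = block.to_numpy()
        n0 = np.nansum(arr == 0, axis=0)
        n1 = np.nansum(arr == 1, axis=0)
        n2 = np.nansum(arr == 2, axis=0)
        pvals = np.array(
            [
                hwe_exact_test(int(a), int(b), int(c)) if a + b + c > 0 else 1.0
                for a, b, c in zip(n0, n1, n2)
            ]
        )
        fail_counts += (pvals < p_threshold).astype(int)
    drop = (
        fail_counts.index[fail_counts > 0]
        if mode == "any"
        else fail_counts.index[fail_counts == n_pops]
    )
    stage = QcStage(
        f"hwe_{mode}", "snp", g.n_snps, len(drop), p_threshold, list(drop)
    )
    if report is not None:
        report.add(stage)
    return g.subset(snps=g.dosages.columns.difference(drop, sort=False)), stage


# ------------------------------------------------ quantitative call rate


def filter_call_rate(
    matrix: pd.DataFrame,
    threshold: float,
    axis: Literal["feature", "sample"] = "feature",
    rule: Literal["call_rate_le", "missing_gt"] = "call_rate_le",
    report: QcReport | None = None,
    name: str | None = None,
) -> tuple[pd.DataFrame, QcStage]:
    """Call-rate / missingness filter for a quantitative samples x features matrix.

    Two published rules are supported:

    - ``"call_rate_le"``: remove when call rate <= threshold (assay panels
      often state e.g. "call rate of 90% or less excluded": a call rate of
      exactly 0.90 is removed);
    - ``"missing_gt"``: remove when missing fraction > threshold (a
      variable with exactly the threshold missingness is retained).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    ax = 0 if axis == "feature" else 1
    call_rate = matrix.notna().mean(axis=ax)
    if rule == "call_rate_le":
        drop = call_rate.index[call_rate <= threshold]
    elif rule == "missing_gt":
        drop = call_rate.index[(1.0 - call_rate) > threshold]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    n_input = matrix.shape[1] if axis == "feature" else matrix.shape[0]
    stage = QcStage(
        name or f"{axis}_{rule}", axis, n_input, len(drop), threshold, list(drop)
    )
    if report is not None:
        report.add(stage)
    if axis == "feature":
        kept = matrix.drop(columns=drop)
    else:
        kept = matrix.drop(index=drop)
    return kept, stage


# ---------------------------------------------------------------- merging


def merge_arrays(
    a: GenotypeMatrix, b: GenotypeMatrix, report: QcReport | None = None
) -> GenotypeMatrix:
    """Merge two array datasets over shared samples.

    For SNPs present on both arrays the copy with the smaller missing
    fraction is kept (ties keep the first input).  Samples are intersected;
    SNP union is taken.
    """
    samples = a.dosages.index.intersection(b.dosages.index, sort=False)
    da = a.dosages.loc[samples]
    db = b.dosages.loc[samples]
    shared = da.columns.intersection(db.columns, sort=False)
    keep_from_b = [s for s in shared if db[s].isna().mean() < da[s].isna().mean()]
    merged = da.copy()
    if keep_from_b:
        merged[keep_from_b] = db[keep_from_b]
    only_b = db.columns.difference(da.columns, sort=False)
    merged = pd.concat([merged, db[only_b]], axis=1)
    snp_meta = pd.concat(
        [a.snp_meta, b.snp_meta.loc[b.snp_meta.index.difference(a.snp_meta.index, sort=False)]]
    ).reindex(merged.columns)
    overridden = pd.Index(keep_from_b)
    snp_meta.loc[overridden] = b.snp_meta.loc[overridden]
    if report is not None:
        report.add(
            QcStage("array_merge_overlap_resolved", "snp", len(shared), 0, None,
                    list(overridden))
        )
    return GenotypeMatrix(merged, snp_meta, a.sample_meta.loc[samples])


def genotype_concordance(a: pd.DataFrame, b: pd.DataFrame) -> pd.Series:
    """Per-SNP fraction of agreeing non-missing genotype pairs.

    Compares shared samples/SNPs of two dosage matrices; SNPs with no
    jointly called genotype get NaN.
    """
    samples = a.index.intersection(b.index, sort=False)
    snps = a.columns.intersection(b.columns, sort=False)
    x = a.loc[samples, snps].to_numpy()
    y = b.loc[samples, snps].to_numpy()
    both = ~np.isnan(x) & ~np.isnan(y)
    agree = (x == y) & both
    with np.errstate(invalid="ignore"):
        conc = agree.sum(axis=0) / both.sum(axis=0)
    return pd.Series(conc, index=snps)


def filter_concordance(
    g: GenotypeMatrix,
    reference: GenotypeMatrix,
    min_concordance: float = 0.95,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcStage]:
    """Drop panel SNPs with < min_concordance agreement against a reference
    genotyping of the same samples; SNPs absent from the reference are kept."""
    conc = genotype_concordance(g.dosages, reference.dosages)
    drop = conc.index[conc < min_concordance]
    stage = QcStage(
        "panel_concordance", "snp", g.n_snps, len(drop), min_concordance, list(drop)
    )
    if report is not None:
        report.add(stage)
    return g.subset(snps=g.dosages.columns.difference(drop, sort=False)), stage
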