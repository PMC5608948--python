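"""Binomial window scan for regions over-represented in high-F_ST SNPs.

Each chromosome is tiled into non-overlapping 100-kb windows (0-based,
half-open).  A SNP is "high" when its F_ST exceeds the top-quantile cutoff
of the genome-wide distribution.  Each occupied window is scored by the
upper binomial tail P(X >= n_high) with X ~ Binomial(n_snps, q), q being
the genome-wide realized fraction of high SNPs; windows significant after
Bonferroni correction over occupied windows are merged into maximal runs of
adjacent windows ("regions").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "assign_windows",
    "binomial_overrepresentation",
    "scan",
    "merge_regions",
    "write_bed",
]

WINDOW_SIZE = 100_000


def assign_windows(snp_meta: pd.DataFrame, window_size: int = WINDOW_SIZE) -> pd.Series:
    """Window index per SNP: floor((pos - 1) / window_size) within chromosome.

    Positions are 1-based; window i spans the 0-based half-open interval
    [i * window_size, (i + 1) * window_size), so 1-based position 100000
    falls in window 0 and 100001 in window 1 (at the 100-kb default).
    """
    pos = snp_meta["pos"].to_numpy()
    if np.any(pos < 1):
        raise ValueError("positions must be positive 1-based integers")
    return pd.Series((pos - 1) // window_size, index=snp_meta.index, name="window")


def binomial_overrepresentation(n_snps: int, n_high: int, q: float) -> float:
    """Upper-tail binomial probability P(X >= n_high), X ~ Bin(n_snps, q).

    Computed by explicit log-space summation of the pmf over the tail
    (numerically exact to ~1e-14 relative).
    """
    if not 0 <= n_high <= n_snps:
        raise ValueError("need 0 <= n_high <= n_snps")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    if n_snps == 0:
        raise ValueError("empty window: no probability defined")
    if n_high == 0:
        return 1.0
    k = np.arange(n_high, n_snps + 1)
    log_pmf = (
        gammaln(n_snps + 1)
        - gammaln(k + 1)
        - gammaln(n_snps - k + 1)
        + k * np.log(q)
        + (n_snps - k) * np.log1p(-q)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


@dataclass
class WindowScanResult:
    """Per-window table plus merged significant regions."""

    windows: pd.DataFrame
    regions: pd.DataFrame
    high_threshold: float
    background_rate: float
    alpha_corrected: float


def scan(
    fst: pd.Series,
    snp_meta: pd.DataFrame,
    high_quantile: float = 0.01,
    alpha: float = 0.05,
    window_size: int = WINDOW_SIZE,
) -> WindowScanResult:
    """Scan the genome for windows enriched in high-F_ST SNPs.

    Parameters
    ----------
    fst
        Per-SNP F_ST indexed like ``snp_meta`` (NaN entries are dropped).
    snp_meta
        Needs ``chrom`` and 1-based ``pos`` columns.
    high_quantile
        Fraction of the genome-wide distribution called "high" (top 1%
        by default).
    alpha
        Family-wise error target; the per-window cutoff is
        ``alpha / #occupied windows`` (Bonferroni).

    Returns
    -------
    WindowScanResult
        ``windows``: one row per occupied window with counts, the binomial
        tail p and a significance flag; ``regions``: maximal runs of
        adjacent significant windows as 0-based half-open intervals.
    """
    fst = fst.dropna()
    meta = snp_meta.loc[fst.index]
    if len(fst) == 0:
        raise ValueError("no F_ST values to scan")
    threshold = float(np.quantile(fst.to_numpy(), 1.0 - high_quantile))
    high = fst > threshold
    q = float(high.mean())
    if q <= 0.0:
        raise ValueError("no SNP exceeds the high-F_ST threshold")

    win = assign_windows(meta, window_size)
    grouped = pd.DataFrame(
        {"chrom": meta["chrom"], "window": win, "high": high.astype(int)}
    ).groupby(["chrom", "window"], sort=True)
    table = grouped.agg(n_snps=("high", "size"), n_high=("high", "sum")).reset_index()
    if len(table) < 2:
        raise ValueError("fewer than two occupied windows; scan not meaningful")
    table["p"] = [
        binomial_overrepresentation(int(n), int(x), q)
        for n, x in zip(table["n_snps"], table["n_high"])
    ]
    alpha_corrected = alpha / len(table)
    table["significant"] = table["p"] < alpha_corrected
    table["start"] = table["window"] * window_size
    table["end"] = (table["window"] + 1) * window_size
    regions = merge_regions(table, window_size)
    return WindowScanResult(table, regions, threshold, q, alpha_corrected)


def merge_regions(windows: pd.DataFrame, window_size: int = WINDOW_SIZE) -> pd.DataFrame:
    """Merge adjacent significant windows into maximal contiguous regions."""
    sig = windows[windows["significant"]].sort_values(["chrom", "window"])
    regions = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        idx = grp["window"].to_numpy()
        if idx.size == 0:
            continue
        breaks = np.where(np.diff(idx) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for s, e in zip(starts, ends):
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(idx[s]) * window_size,
                    "end": (int(idx[e]) + 1) * window_size,
                    "n_windows": int(e - s + 1),
                    "n_snps": int(grp.iloc[s : e + 1]["n_snps"].sum()),
                    "n_high": int(grp.iloc[s : e + 1]["n_high"].sum()),
                    "min_p": float(grp.iloc[s : e + 1]["p"].min()),
                }
            )
    return pd.DataFrame(
        regions,
        columns=["chrom", "start", "end", "n_windows", "n_snps", "n_high", "min_p"],
    )


def write_bed(regions: pd.DataFrame, path) -> None:
    """Write regions as BED (0-based half-open, score = -log10 min p)."""
    with open(path, "w") as fh:
        for i, row in regions.iterrows():
            score = -np.log10(max(row["min_p"], 1e-300))
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"region_{i}\t{score:.2f}\n"
            )
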