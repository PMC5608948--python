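"""Principal component analysis of genotype and quantitative matrices.

Two standardisations are provided:

- ``genotype``: columns centred at twice the sample allele frequency and
  scaled by sqrt(p_hat * (1 - p_hat)), the convention of the classical
  population-structure eigenanalysis (so each SNP contributes variance
  proportional to its drift, not its frequency);
- ``quantitative``: column z-scores, appropriate for matrices mixing
  heterogeneous units.

The eigen-decomposition is done via SVD of the standardised matrix;
components are ordered by eigenvalue with signs fixed so each component's
largest-magnitude loading is positive, making outputs reproducible.  A
greedy linkage-pruning helper thins genotype matrices before PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix

__all__ = ["PcaResult", "pca", "thin_genotypes", "cumulative_variance", "biplot"]


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_explained: np.ndarray  # fraction per component, non-increasing
    mode: str
    dropped_features: list

    def to_tsvs(self, prefix) -> dict:
        paths = {
            "scores": f"{prefix}_scores.tsv",
            "loadings": f"{prefix}_loadings.tsv",
            "variance": f"{prefix}_variance.tsv",
        }
        self.scores.to_csv(paths["scores"], sep="\t")
        self.loadings.to_csv(paths["loadings"], sep="\t")
        pd.DataFrame(
            {
                "component": self.scores.columns,
                "variance_explained": self.variance_explained,
            }
        ).to_csv(paths["variance"], sep="\t", index=False)
        return paths


def pca(
    matrix: pd.DataFrame,
    mode: str = "quantitative",
    n_components: int | None = None,
) -> PcaResult:
    """PCA of a samples x features matrix.

    Missing entries are column-mean imputed for the decomposition only
    (never written back); constant columns are dropped with a record in
    ``dropped_features``.  ``variance_explained`` is each eigenvalue over
    the total variance of the standardised matrix, so it sums to 1 over
    the full rank.
    """
    if mode not in {"genotype", "quantitative"}:
        raise ValueError("mode must be 'genotype' or 'quantitative'")
    X = matrix.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]

    if mode == "genotype":
        p_hat = col_mean / 2.0
        scale = np.sqrt(p_hat * (1.0 - p_hat))
        center = col_mean
    else:
        center = col_mean
        scale = X.std(axis=0, ddof=1)

    keep = scale > 0
    dropped = [str(c) for c in matrix.columns[~keep]]
    X = (X[:, keep] - center[keep]) / scale[keep]
    features = matrix.columns[keep]

    n, p = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # fix signs: largest |loading| positive per component
    for c in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    eigvals = s**2 / (n - 1)
    total_var = (X.var(axis=0, ddof=1)).sum()
    var_explained = eigvals / total_var

    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    n_keep = min(n_components or rank, rank)
    comps = [f"PC{i + 1}" for i in range(n_keep)]
    scores = pd.DataFrame(
        U[:, :n_keep] * s[:n_keep], index=matrix.index, columns=comps
    )
    loadings = pd.DataFrame(Vt[:n_keep].T, index=features, columns=comps)
    return PcaResult(scores, loadings, var_explained[:n_keep], mode, dropped)


def cumulative_variance(result: PcaResult, target: float) -> int:
    """Smallest number of leading components explaining >= target variance."""
    if not 0.0 < target <= 1.0:
        raise ValueError("target must lie in (0, 1]")
    csum = np.cumsum(result.variance_explained)
    reached = np.flatnonzero(csum >= target - 1e-12)
    if reached.size == 0:
        raise ValueError(
            f"retained components explain only {csum[-1]:.3f} < target {target}"
        )
    return int(reached[0]) + 1


def thin_genotypes(
    g: GenotypeMatrix,
    target_n: int,
    r2_max: float = 0.2,
    window: int = 500_000,
    seed: int = 0,
) -> GenotypeMatrix:
    """LD-prune then pseudo-randomly down-sample a genotype matrix.

    A single greedy pass in position order drops any SNP whose genotype
    r^2 with an already-retained SNP within ``window`` bp (same
    chromosome) exceeds ``r2_max``; the survivors are then down-sampled to
    ``target_n`` with a seeded generator.  If pruning leaves fewer than
    ``target_n`` SNPs, all survivors are returned.
    """
    if target_n > g.n_snps:
        raise ValueError("target_n exceeds available SNP count")
    meta = g.snp_meta.sort_values(["chrom", "pos"])
    X = g.dosages[meta.index].to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    idx_nan = np.where(np.isnan(X))
    X[idx_nan] = col_mean[idx_nan[1]]
    X = X - X.mean(axis=0)
    norms = np.sqrt((X**2).sum(axis=0))

    retained: list[int] = []
    active: list[int] = []  # retained SNPs within the current window
    chroms = meta["chrom"].to_numpy()
    poss = meta["pos"].to_numpy()
    for j in range(len(meta)):
        active = [
            i
            for i in active
            if chroms[i] == chroms[j] and poss[j] - poss[i] <= window
        ]
        if norms[j] == 0:
            continue
        ok = True
        for i in active:
            if norms[i] == 0:
                continue
            r = (X[:, i] @ X[:, j]) / (norms[i] * norms[j])
            if r * r > r2_max:
                ok = False
                break
        if ok:
            retained.append(j)
            active.append(j)
    kept_ids = meta.index[retained]
    if len(kept_ids) > target_n:
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(len(kept_ids), size=target_n, replace=False))
        kept_ids = kept_ids[pick]
    return g.subset(snps=kept_ids)


def biplot(result: PcaResult, populations: pd.Series, path) -> None:
    """Scatter of PC1 vs PC2 coloured by population label (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pops = populations.reindex(result.scores.index)
    for pop, grp in result.scores.groupby(pops):
        ax.scatter(grp["PC1"], grp["PC2"], s=12, label=str(pop), alpha=0.7)
    ve = result.variance_explained
    ax.set_xlabel(f"PC1 ({ve[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({ve[1] * 100:.1f}%)" if len(ve) > 1 else "PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
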