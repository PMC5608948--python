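"""Correlation-based tagging of lipid species within each population.

A species is "tagged" when its squared Pearson correlation with a chosen
representative ("tag") exceeds a threshold (0.8 by default), by analogy
with tag SNPs: assaying the tag recovers the information of its tagged
members.  Tags are chosen by a deterministic greedy set cover: repeatedly
promote the feature with the most not-yet-covered above-threshold
neighbours (ties: larger mean r^2 to those neighbours, then lexicographic
ID); its uncovered neighbours become its tagged members.  Features left
with no above-threshold link to anything are singletons and must be
assayed themselves.

Bookkeeping: with K species of which ``n_tagged`` are non-tag members of
multi-species clusters, the whole panel is representable by
``n_representative = K - n_tagged`` assays (all tags plus all singletons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "pairwise_r2",
    "select_tags",
    "tag_summary",
    "representative_count",
    "TagReport",
]


def representative_count(k: int, n_covered: int, n_tags: int) -> int:
    """Number of assays needed when ``n_tags`` tags represent ``n_covered``
    species (tags included in the covered count) out of ``k`` total.

    Equals ``k - (n_covered - n_tags)``: every species outside the covered
    set plus one tag per cluster.
    """
    if not 0 <= n_tags <= n_covered <= k:
        raise ValueError("need 0 <= n_tags <= n_covered <= k")
    return k - (n_covered - n_tags)


@dataclass
class TagReport:
    """Per-population tagging outcome.

    ``tags`` maps each tag feature to the list of features it tags (the
    tag itself excluded); ``singletons`` are features in no cluster.
    """

    population: str
    threshold: float
    tags: dict
    singletons: list
    r2_to_tag: dict = field(default_factory=dict)
    zero_variance: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.n_tags + self.n_tagged + len(self.singletons)

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    @property
    def n_tagged(self) -> int:
        return sum(len(v) for v in self.tags.values())

    @property
    def n_covered(self) -> int:
        """Tags plus tagged members (the 'represented by tags' headcount)."""
        return self.n_tags + self.n_tagged

    @property
    def n_representative(self) -> int:
        return self.n_features - self.n_tagged

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tag, members in self.tags.items():
            rows.append({"feature": tag, "role": "tag", "tag_id": tag, "r2_to_tag": 1.0})
            for mem in members:
                rows.append(
                    {
                        "feature": mem,
                        "role": "tagged",
                        "tag_id": tag,
                        "r2_to_tag": self.r2_to_tag.get(mem, np.nan),
                    }
                )
        for s in self.singletons:
            rows.append({"feature": s, "role": "singleton", "tag_id": "", "r2_to_tag": np.nan})
        return pd.DataFrame(rows, columns=["feature", "role", "tag_id", "r2_to_tag"])

    def counts(self) -> dict:
        return {
            "population": self.population,
            "K": self.n_features,
            "n_tags": self.n_tags,
            "n_tagged": self.n_tagged,
            "n_covered": self.n_covered,
            "n_singletons": len(self.singletons),
            "n_representative": self.n_representative,
        }


def pairwise_r2(
    matrix: pd.DataFrame,
    population: pd.Series | None = None,
    pop: str | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Squared Pearson correlation between all feature pairs, one population.

    Parameters
    ----------
    matrix
        samples x features log2 values (NaN = missing).
    population, pop
        When given, restrict to samples with ``population == pop``.
    min_pairs
        Minimum complete-case sample count per pair; sparser pairs get NaN.

    Returns
    -------
    features x features symmetric DataFrame of r^2 with unit diagonal.
    Zero-variance features get NaN off-diagonal entries (they cannot tag
    or be tagged and end up singletons).
    """
    if population is not None:
        matrix = matrix[population.reindex(matrix.index) == pop]
    if matrix.shape[0] < min_pairs:
        raise ValueError("need at least min_pairs samples in the population")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        r = _pairwise_corr_masked(X, min_pairs)
    else:
        sd = X.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X, rowvar=False)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
    r2 = r**2
    np.fill_diagonal(r2, 1.0)
    return pd.DataFrame(np.clip(r2, 0.0, 1.0), index=matrix.columns, columns=matrix.columns)


def _pairwise_corr_masked(X: np.ndarray, min_pairs: int) -> np.ndarray:
    """Complete-case Pearson correlation per pair (handles missing values)."""
    p = X.shape[1]
    r = np.full((p, p), np.nan)
    valid = ~np.isnan(X)
    for i in range(p):
        r[i, i] = 1.0
        for j in range(i + 1, p):
            m = valid[:, i] & valid[:, j]
            if m.sum() < min_pairs:
                continue
            xi, xj = X[m, i], X[m, j]
            si, sj = xi.std(), xj.std()
            if si == 0.0 or sj == 0.0:
                continue
            r[i, j] = r[j, i] = np.corrcoef(xi, xj)[0, 1]
    return r


def select_tags(
    corr: pd.DataFrame,
    threshold: float = 0.8,
    population: str = "all",
    transitive: bool = False,
) -> TagReport:
    """Greedy tag selection on a squared-correlation matrix.

    Direct mode (default): each tagged member must itself exceed the
    threshold against its tag.  Transitive mode: clusters are connected
    components of the above-threshold graph and one tag (highest degree)
    is chosen per component, so members may be linked to the tag only
    through intermediates.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    features = list(corr.index)
    r2 = corr.to_numpy(dtype=float).copy()
    np.fill_diagonal(r2, 0.0)
    zero_var = [
        f
        for i, f in enumerate(features)
        if np.all(np.isnan(np.delete(r2[i], i)))
    ]
    adj = np.nan_to_num(r2, nan=0.0) > threshold

    if transitive:
        return _transitive_tags(features, adj, r2, threshold, population, zero_var)

    uncovered = np.ones(len(features), dtype=bool)
    tags: dict = {}
    r2_to_tag: dict = {}
    while True:
        degree = (adj & uncovered[None, :]).sum(axis=1)
        degree[~uncovered] = 0  # only uncovered features can become tags
        if degree.max() == 0:
            break
        best = np.flatnonzero(degree == degree.max())
        if best.size > 1:  # tie-break: mean r2 to coverable neighbours, then ID
            means = []
            for b in best:
                nb = adj[b] & uncovered
                means.append(np.nan_to_num(r2[b], nan=0.0)[nb].mean())
            means = np.asarray(means)
            best = best[means == means.max()]
            if best.size > 1:
                best = np.array([min(best, key=lambda i: features[i])])
        t = int(best[0])
        members = np.flatnonzero(adj[t] & uncovered)
        members = members[members != t]
        tags[features[t]] = [features[m] for m in members]
        for m in members:
            r2_to_tag[features[m]] = float(r2[t, m])
        uncovered[t] = False
        uncovered[members] = False
    singletons = [features[i] for i in np.flatnonzero(uncovered)]
    return TagReport(population, threshold, tags, singletons, r2_to_tag, zero_var)


def _transitive_tags(features, adj, r2, threshold, population, zero_var) -> TagReport:
    n = len(features)
    seen = np.zeros(n, dtype=bool)
    tags, r2_to_tag, singletons = {}, {}, []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.flatnonzero(adj[u]):
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        if len(comp) == 1:
            singletons.append(features[i])
            continue
        comp = sorted(comp)
        degrees = [adj[c].sum() for c in comp]
        tag = comp[int(np.argmax(degrees))]
        members = [c for c in comp if c != tag]
        tags[features[tag]] = [features[m] for m in members]
        for m in members:
            r2_to_tag[features[m]] = float(np.nan_to_num(r2[tag, m], nan=0.0))
    return TagReport(population, threshold, tags, singletons, r2_to_tag, zero_var)


def tag_summary(reports: list[TagReport]) -> pd.DataFrame:
    """Cross-population comparison table of tagging outcomes."""
    rows = []
    all_tag_sets = {r.population: set(r.tags) for r in reports}
    for r in reports:
        others = set().union(
            *(s for p, s in all_tag_sets.items() if p != r.population)
        ) if len(reports) > 1 else set()
        counts = r.counts()
        counts["tags_shared_with_other_populations"] = (
            len(set(r.tags) & others) if others else 0
        )
        rows.append(counts)
    return pd.DataFrame(rows)
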