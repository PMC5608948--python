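"""Wright's F_ST across k populations, driving-pair attribution, empirical p-values.

The statistic used throughout is the k-population frequency-variance form

    F_ST = (k - 1) * sigma^2 / (k * p_bar * (1 - p_bar))

where ``sigma^2`` is the *sample* variance (divisor k-1) of the allele
frequency across populations and ``p_bar`` the unweighted mean frequency.
With the sample variance the k=2 case reduces to the familiar
``(p1 - p2)^2 / (2 * p_bar * (1 - p_bar))``-free form
``F_ST = (p1 - p2)^2 / (4 * p_bar * (1 - p_bar))`` ... actually
``(p1-p2)^2 / (2 p_bar q_bar) * 1/2``; see :func:`wright_fst` for the exact
algebra.  A variant monomorphic in every population (p_bar of 0 or 1) has an
undefined ratio and is reported as F_ST = 0 with a flag.

Empirical p-values situate an observed F_ST within a genome-wide null
distribution using a strict-inequality exceedance fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FstResult",
    "wright_fst",
    "wright_fst_array",
    "frequencies_from_genotypes",
    "hla_one_vs_rest",
    "driving_pair",
    "empirical_pvalue",
    "fst_table",
]


@dataclass
class FstResult:
    """Per-variant differentiation summary.

    Attributes
    ----------
    variant_id : str
        Identifier of the SNP or one-vs-rest allele.
    fst : float
        Wright's F_ST in [0, 1]; 0 by convention when monomorphic.
    sigma2 : float
        Sample variance (ddof=1) of the frequency across populations.
    p_bar : float
        Mean allele frequency across populations.
    freqs : tuple of float
        The per-population frequencies the statistic was computed from.
    driving_pair : str or None
        Label ``"A-B"`` of the population pair with the largest pairwise
        F_ST, or ``"none"`` when all frequencies are equal.
    p_empirical : float or None
        Exceedance fraction against a genome-wide null, when assigned.
    monomorphic : bool
        True when p_bar is exactly 0 or 1 (F_ST set to 0 by convention).
    """

    variant_id: str
    fst: float
    sigma2: float
    p_bar: float
    freqs: tuple = field(default_factory=tuple)
    driving_pair: str | None = None
    p_empirical: float | None = None
    monomorphic: bool = False


def _validate_freqs(freqs: Sequence[float]) -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 1 or f.size < 2:
        raise ValueError("need a 1-D vector of at least two population frequencies")
    if np.any(~np.isfinite(f)) or np.any(f < 0) or np.any(f > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return f


def wright_fst(
    freqs: Sequence[float],
    variant_id: str = "variant",
    pop_labels: Sequence[str] | None = None,
) -> FstResult:
    """Compute Wright's F_ST from per-population allele frequencies.

    Parameters
    ----------
    freqs
        One allele frequency per population (k >= 2), each in [0, 1].
    variant_id
        Identifier carried into the result.
    pop_labels
        Population names used for driving-pair attribution (k=3 only);
        positional indices are used when omitted.

    Returns
    -------
    FstResult
        With ``fst = (k-1) * sigma2 / (k * p_bar * (1 - p_bar))`` where
        sigma2 is the across-population sample variance.  Monomorphic
        input (all 0 or all 1) yields fst 0 and ``monomorphic=True``.
    """
    f = _validate_freqs(freqs)
    k = f.size
    p_bar = float(f.mean())
    sigma2 = float(f.var(ddof=1))
    if p_bar <= 0.0 or p_bar >= 1.0:
        return FstResult(variant_id, 0.0, sigma2, p_bar, tuple(f), "none", None, True)
    fst = (k - 1) * sigma2 / (k * p_bar * (1.0 - p_bar))
    pair = driving_pair(f, pop_labels) if k == 3 else None
    return FstResult(variant_id, float(fst), sigma2, p_bar, tuple(f), pair)


def wright_fst_array(freq_matrix: np.ndarray) -> np.ndarray:
    """Vectorised F_ST for a (variants x populations) frequency matrix.

    Monomorphic rows (mean frequency 0 or 1) get F_ST 0.  NaN frequencies
    propagate to NaN so callers can flag variants with an unobserved
    population.
    """
    p = np.asarray(freq_matrix, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("freq_matrix must be 2-D with at least two populations")
    k = p.shape[1]
    p_bar = p.mean(axis=1)
    sigma2 = p.var(axis=1, ddof=1)
    denom = k * p_bar * (1.0 - p_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = (k - 1) * sigma2 / denom
    fst = np.where(denom == 0.0, 0.0, fst)
    fst[np.any(np.isnan(p), axis=1)] = np.nan
    return fst


def driving_pair(
    freqs: Sequence[float], pop_labels: Sequence[str] | None = None
) -> str:
    """Attribute a three-population F_ST to the most divergent pair.

    The pair with the largest two-population F_ST (same formula at k=2) is
    returned as ``"A-B"`` in the declared population order; exact ties are
    broken by that order.  Equal frequencies everywhere return ``"none"``.
    """
    f = _validate_freqs(freqs)
    if f.size != 3:
        raise ValueError("driving-pair attribution is defined for k=3")
    labels = list(pop_labels) if pop_labels is not None else ["pop1", "pop2", "pop3"]
    if len(labels) != 3:
        raise ValueError("pop_labels must name exactly three populations")
    if f[0] == f[1] == f[2]:
        return "none"
    best_pair, best_fst = None, -1.0
    for i, j in combinations(range(3), 2):
        pb = (f[i] + f[j]) / 2.0
        if pb <= 0.0 or pb >= 1.0:
            pair_fst = 0.0
        else:
            s2 = float(np.var([f[i], f[j]], ddof=1))
            pair_fst = s2 / (2.0 * pb * (1.0 - pb))
        if pair_fst > best_fst:  # strict: first pair in order wins ties
            best_pair, best_fst = (i, j), pair_fst
    i, j = best_pair
    return f"{labels[i]}-{labels[j]}"


def frequencies_from_genotypes(
    dosages: pd.DataFrame, populations: pd.Series
) -> pd.DataFrame:
    """Per-population alternate-allele frequencies from a dosage matrix.

    Parameters
    ----------
    dosages
        samples x SNPs matrix of alt-allele dosages in {0, 1, 2}, NaN for
        missing genotypes.
    populations
        Population label per sample (index aligned with ``dosages``).

    Returns
    -------
    DataFrame indexed by SNP with columns ``freq_<pop>`` (NaN where a
    population has no called genotype) and ``n_<pop>`` (number of called
    chromosomes, i.e. 2 x non-missing samples).
    """
    populations = populations.reindex(dosages.index)
    if populations.isna().any():
        missing = dosages.index[populations.isna()].tolist()
        raise ValueError(f"samples without a population label: {missing[:5]}")
    out = {}
    for pop, block in dosages.groupby(populations, sort=False):
        called = block.notna().sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = block.sum(axis=0, skipna=True) / (2.0 * called)
        freq[called == 0] = np.nan
        out[f"freq_{pop}"] = freq
        out[f"n_{pop}"] = 2 * called
    return pd.DataFrame(out)


def hla_one_vs_rest(
    hla_table: pd.DataFrame, populations: pd.Series
) -> pd.DataFrame:
    """One-vs-rest allele frequencies for multi-allelic (HLA-style) loci.

    Each distinct classical allele observed at a locus is treated as the
    alternate allele of a biallelic variant: its per-population frequency is
    the count of that allele over the number of called chromosomes (2 per
    sample with both calls present; samples with a missing call at a locus
    contribute only their non-missing allele).

    Parameters
    ----------
    hla_table
        Long table with columns ``sample``, ``locus``, ``allele1``,
        ``allele2``; missing calls as NaN/None.
    populations
        Population per sample ID.

    Returns
    -------
    DataFrame indexed by ``"<locus>*<allele>"``-style variant ID (the
    allele name is used verbatim) with ``locus``, ``allele`` columns and
    ``freq_<pop>`` / ``n_<pop>`` columns, suitable for
    :func:`wright_fst_array`.
    """
    required = {"sample", "locus", "allele1", "allele2"}
    if not required.issubset(hla_table.columns):
        raise ValueError(f"hla_table must have columns {sorted(required)}")
    long = hla_table.melt(
        id_vars=["sample", "locus"],
        value_vars=["allele1", "allele2"],
        value_name="allele",
    ).dropna(subset=["allele"])
    long["population"] = long["sample"].map(populations)
    if long["population"].isna().any():
        raise ValueError("every sample in hla_table needs a population label")

    pops = list(pd.unique(populations.reindex(hla_table["sample"].unique()).dropna()))
    rows = []
    for locus, grp in long.groupby("locus", sort=False):
        totals = grp.groupby("population")["allele"].size()
        counts = grp.groupby(["allele", "population"]).size().unstack(fill_value=0)
        for allele in counts.index:
            rec = {"variant_id": f"{locus}:{allele}", "locus": locus, "allele": allele}
            for pop in pops:
                n = int(totals.get(pop, 0))
                c = int(counts.loc[allele].get(pop, 0))
                rec[f"freq_{pop}"] = c / n if n else np.nan
                rec[f"n_{pop}"] = n
            rows.append(rec)
    return pd.DataFrame(rows).set_index("variant_id")


def empirical_pvalue(
    observed_fst: float | np.ndarray, null_fst: np.ndarray
) -> float | np.ndarray:
    """Exceedance fraction of a genome-wide null above an observed F_ST.

    ``p = #{null > observed} / #null`` with a *strict* inequality, so an
    observation at or above the null maximum has p exactly 0 (no
    pseudocount).  Vectorised over ``observed_fst``.
    """
    null = np.asarray(null_fst, dtype=float)
    null = null[~np.isnan(null)]
    if null.size == 0:
        raise ValueError("null F_ST distribution is empty")
    null_sorted = np.sort(null)
    obs = np.asarray(observed_fst, dtype=float)
    # #{null > obs} = n - #{null <= obs}
    n_le = np.searchsorted(null_sorted, obs, side="right")
    p = (null.size - n_le) / null.size
    return float(p) if np.isscalar(observed_fst) else p


def fst_table(
    freq_table: pd.DataFrame,
    pop_labels: Sequence[str] | None = None,
    null_fst: np.ndarray | None = None,
    flag_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Full per-variant F_ST table from a per-population frequency table.

    Parameters
    ----------
    freq_table
        Indexed by variant with ``freq_<pop>`` columns (as produced by
        :func:`frequencies_from_genotypes` or :func:`hla_one_vs_rest`).
    pop_labels
        Order of populations; inferred from column order when omitted.
    null_fst
        Optional genome-wide null; adds ``p_empirical`` and a
        ``significant`` flag at ``p_empirical < flag_threshold``.

    Returns
    -------
    DataFrame with the input frequencies plus ``p_bar``, ``sigma2``,
    ``fst``, ``driving_pair`` (k=3 only) and, when a null is supplied,
    ``p_empirical`` / ``significant``.
    """
    freq_cols = [c for c in freq_table.columns if c.startswith("freq_")]
    if pop_labels is None:
        pop_labels = [c[len("freq_") :] for c in freq_cols]
    else:
        freq_cols = [f"freq_{p}" for p in pop_labels]
    p = freq_table[freq_cols].to_numpy(dtype=float)
    k = p.shape[1]
    out = freq_table.copy()
    out["p_bar"] = p.mean(axis=1)
    out["sigma2"] = p.var(axis=1, ddof=1)
    out["fst"] = wright_fst_array(p)
    out["monomorphic"] = (out["p_bar"] == 0.0) | (out["p_bar"] == 1.0)
    if k == 3:
        pairs = []
        for row in p:
            pairs.append(
                "NA" if np.any(np.isnan(row)) else driving_pair(row, pop_labels)
            )
        out["driving_pair"] = pairs
    if null_fst is not None:
        valid = ~out["fst"].isna()
        pe = np.full(len(out), np.nan)
        pe[valid.to_numpy()] = empirical_pvalue(
            out.loc[valid, "fst"].to_numpy(), null_fst
        )
        out["p_empirical"] = pe
        out["significant"] = out["p_empirical"] < flag_threshold
    return out
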