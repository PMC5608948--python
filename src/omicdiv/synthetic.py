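"""Synthetic three-population cohort generator.

Emulates the statistical structure of a multi-ethnic, multi-platform cohort
so that every downstream stage (QC, F_ST, window scan, group contrasts,
lipid tagging, ordination) can be exercised end-to-end without any data
download:

- SNP allele frequencies diverge between populations under the
  Balding-Nichols model: given an ancestral frequency p and a divergence
  parameter F, each population's frequency is drawn from
  Beta(p(1-F)/F, (1-p)(1-F)/F), whose expected pairwise differentiation is
  governed directly by F.  Genotypes are then binomial (Hardy-Weinberg)
  within population, with uniform missingness.
- Multi-allelic (HLA-style) loci draw per-population allele frequency
  simplexes from a Dirichlet centred on an ancestral simplex with
  concentration (1-F)/F, the natural multi-allelic analogue of
  Balding-Nichols; two alleles per sample are drawn independently.
- Quantitative platforms (lipids, transcripts, miRNAs) are multivariate
  normal on the log2 scale.  Lipid features are organised into correlated
  blocks via a shared latent factor (member = sqrt(rho)*factor +
  sqrt(1-rho)*noise with rho chosen so pairwise r^2 matches the design's
  ``block_r2``).  A chosen subset of features receives additive population
  mean shifts in within-group-SD units; additive sex and batch/plate
  effects are injected; missingness is uniform.

Everything is driven by a single integer seed and is byte-reproducible.
The ``truth`` record carries the simulated differentiated variants and
features, and block memberships, for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .io_qc import GenotypeMatrix, write_vcf, write_dosage_tsv

__all__ = [
    "CohortDesign",
    "SyntheticCohort",
    "simulate_balding_nichols_frequencies",
    "simulate_genotypes",
    "simulate_multiallelic_locus",
    "simulate_hla_table",
    "simulate_quantitative_platform",
    "simulate_cohort",
]

# positions are laid down at a fixed stride so each 100-kb window holds a
# deterministic number of SNPs (100_000 / STRIDE)
POSITION_STRIDE = 5_000
SNPS_PER_CHROM = 2_000


@dataclass
class CohortDesign:
    """Parameters of the simulated cohort.

    Defaults mirror the recruited cohort the pipeline is modelled on
    (122/120/122 Chinese/Malay/Indian) and a desk-scale version of its
    platforms; the genome-wide divergence default F=0.01 matches the
    1-3% pairwise F_ST range typical of the three source populations.
    """

    n_per_pop: tuple = (122, 120, 122)
    pop_labels: tuple = ("Chinese", "Malay", "Indian")
    n_snps: int = 4_000
    fst_target: float = 0.01
    n_hla_loci: int = 4
    alleles_per_locus: int = 8
    n_lipids: int = 282
    n_blocks: int = 20
    block_size: int = 4
    block_r2: float = 0.85
    n_transcripts: int = 400
    n_mirnas: int = 274
    n_diff_features: int = 10
    effect_size: float = 1.0
    missing_rate: float = 0.01
    n_batches: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_pop) != len(self.pop_labels):
            raise ValueError("n_per_pop and pop_labels lengths differ")
        if any(n <= 0 for n in self.n_per_pop):
            raise ValueError("population sizes must be positive")
        for name in ("fst_target", "block_r2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_blocks * self.block_size > self.n_lipids:
            raise ValueError("lipid blocks exceed n_lipids")

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_pop))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("n_per_pop", "pop_labels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticCohort:
    """All simulated platforms plus covariates and ground truth."""

    design: CohortDesign
    genotypes: GenotypeMatrix
    hla_table: pd.DataFrame
    lipid_matrix: pd.DataFrame
    expression_matrix: pd.DataFrame
    mirna_matrix: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> dict:
        """Write every platform as plain text; returns a path manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "design": outdir / "design.yaml",
            "vcf": outdir / "genotypes.vcf",
            "dosages": outdir / "genotypes.tsv",
            "hla": outdir / "hla.tsv",
            "lipids": outdir / "lipids.tsv",
            "expression": outdir / "expression.tsv",
            "mirna": outdir / "mirna.tsv",
            "covariates": outdir / "covariates.tsv",
            "truth": outdir / "truth.json",
        }
        self.design.to_yaml(paths["design"])
        write_vcf(self.genotypes, paths["vcf"])
        write_dosage_tsv(self.genotypes, paths["dosages"])
        self.hla_table.to_csv(paths["hla"], sep="\t", index=False, na_rep="NA")
        self.lipid_matrix.to_csv(paths["lipids"], sep="\t", na_rep="NA")
        self.expression_matrix.to_csv(paths["expression"], sep="\t", na_rep="NA")
        self.mirna_matrix.to_csv(paths["mirna"], sep="\t", na_rep="NA")
        self.covariates.to_csv(paths["covariates"], sep="\t")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2)
        return {k: str(v) for k, v in paths.items()}


def simulate_balding_nichols_frequencies(
    p_ancestral: np.ndarray,
    F,
    n_pops: int | None = None,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Draw per-population allele frequencies under Balding-Nichols.

    Parameters
    ----------
    p_ancestral
        Ancestral frequency per locus, each strictly inside (0, 1).
    F
        Divergence parameter(s) in (0, 1): a scalar, one value per
        population, or a (loci x populations) array.
    n_pops
        Number of populations (required when F is scalar).
    rng
        ``numpy`` Generator or integer seed.

    Returns
    -------
    (loci x populations) frequency matrix, each column drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = np.atleast_1d(np.asarray(p_ancestral, dtype=float))
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    F = np.asarray(F, dtype=float)
    if F.ndim == 0:
        if n_pops is None:
            raise ValueError("n_pops required with scalar F")
        F = np.full((p.size, n_pops), float(F))
    elif F.ndim == 1:
        F = np.broadcast_to(F, (p.size, F.size)).copy()
    if np.any(F <= 0.0) or np.any(F >= 1.0):
        raise ValueError("F must lie strictly in (0, 1)")
    scale = (1.0 - F) / F
    a = p[:, None] * scale
    b = (1.0 - p[:, None]) * scale
    return rng.beta(a, b)


def simulate_genotypes(
    freqs: np.ndarray,
    design: CohortDesign,
    rng: np.random.Generator | int | None = None,
) -> GenotypeMatrix:
    """Binomial (HWE) genotypes per population from a frequency matrix.

    SNP positions are laid out at a fixed stride (POSITION_STRIDE bp) on
    synthetic chromosomes of SNPS_PER_CHROM SNPs each, so non-overlapping
    window occupancy downstream is deterministic.
    """
    rng = np.random.default_rng(design.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    freqs = np.asarray(freqs, dtype=float)
    n_snps, k = freqs.shape
    if np.any(freqs < 0.0) or np.any(freqs > 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    blocks = []
    for i in range(k):
        n_i = design.n_per_pop[i]
        blocks.append(rng.binomial(2, freqs[:, i], size=(n_i, n_snps)).astype(float))
    dosages = np.vstack(blocks)
    if design.missing_rate > 0:
        mask = rng.random(dosages.shape) < design.missing_rate
        dosages[mask] = np.nan

    sample_ids = [
        f"{pop}_{i:03d}"
        for pop, n in zip(design.pop_labels, design.n_per_pop)
        for i in range(n)
    ]
    snp_ids = [f"snp{j:06d}" for j in range(n_snps)]
    chrom = 1 + np.arange(n_snps) // SNPS_PER_CHROM
    offset = np.arange(n_snps) % SNPS_PER_CHROM
    pos = 1 + offset * POSITION_STRIDE
    dosage_df = pd.DataFrame(
        dosages,
        index=pd.Index(sample_ids, name="sample"),
        columns=pd.Index(snp_ids, name="snp"),
    )
    snp_meta = pd.DataFrame(
        {"chrom": chrom.astype(str), "pos": pos, "ref": "A", "alt": "G"},
        index=dosage_df.columns,
    )
    pops = [
        pop for pop, n in zip(design.pop_labels, design.n_per_pop) for _ in range(n)
    ]
    sample_meta = pd.DataFrame({"population": pops}, index=dosage_df.index)
    return GenotypeMatrix(dosage_df, snp_meta, sample_meta)


def simulate_multiallelic_locus(
    allele_freqs_per_pop: np.ndarray,
    design: CohortDesign,
    locus: str = "HLA-X",
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Two independent allele draws per sample at one multi-allelic locus.

    ``allele_freqs_per_pop``: (populations x alleles) simplex rows.
    Returns a long table (sample, locus, allele1, allele2) with stable
    allele labels ``<locus>*01 ...``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    freqs = np.asarray(allele_freqs_per_pop, dtype=float)
    if freqs.ndim != 2 or freqs.shape[0] != len(design.pop_labels):
        raise ValueError("need one simplex row per population")
    if np.any(freqs < 0) or not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each population's allele frequencies must sum to 1")
    n_alleles = freqs.shape[1]
    labels = [f"{locus}*{a + 1:02d}" for a in range(n_alleles)]
    rows = []
    for pop, n in zip(design.pop_labels, design.n_per_pop):
        i = design.pop_labels.index(pop)
        draws = rng.choice(n_alleles, size=(n, 2), p=freqs[i] / freqs[i].sum())
        for s in range(n):
            rows.append(
                {
                    "sample": f"{pop}_{s:03d}",
                    "locus": locus,
                    "allele1": labels[draws[s, 0]],
                    "allele2": labels[draws[s, 1]],
                }
            )
    return pd.DataFrame(rows)


def simulate_hla_table(
    design: CohortDesign, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Multi-locus HLA-style table with Dirichlet-divergent allele simplexes.

    The ancestral simplex at each locus is Dirichlet(1,...,1); population
    simplexes are Dirichlet(ancestral * (1-F)/F), the multi-allelic
    analogue of the biallelic Balding-Nichols beta draw.
    """
    rng = np.random.default_rng(design.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    k = len(design.pop_labels)
    conc = (1.0 - design.fst_target) / design.fst_target
    tables, truth_freqs = [], {}
    for l in range(design.n_hla_loci):
        locus = f"HLA-{chr(ord('A') + l)}"
        ancestral = rng.dirichlet(np.ones(design.alleles_per_locus))
        ancestral = np.clip(ancestral, 1e-4, None)
        ancestral /= ancestral.sum()
        per_pop = rng.dirichlet(ancestral * conc, size=k)
        tables.append(simulate_multiallelic_locus(per_pop, design, locus, rng))
        truth_freqs[locus] = per_pop.tolist()
    return pd.concat(tables, ignore_index=True), truth_freqs


def _covariates(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    sample_ids, pops = [], []
    for pop, n in zip(design.pop_labels, design.n_per_pop):
        sample_ids += [f"{pop}_{i:03d}" for i in range(n)]
        pops += [pop] * n
    n_total = len(sample_ids)
    # balanced sexes within population, batches assigned round-robin
    sex = []
    for pop, n in zip(design.pop_labels, design.n_per_pop):
        half = n // 2
        s = np.array(["F"] * half + ["M"] * (n - half))
        rng.shuffle(s)
        sex += list(s)
    batch = [f"b{i % design.n_batches + 1}" for i in range(n_total)]
    plate = [f"p{i % max(2, design.n_batches) + 1}" for i in range(n_total)]
    return pd.DataFrame(
        {"population": pops, "sex": sex, "batch": batch, "rt_plate": plate},
        index=pd.Index(sample_ids, name="sample"),
    )


def simulate_quantitative_platform(
    design: CohortDesign,
    platform: Literal["lipid", "expression", "mirna"],
    covariates: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One samples x features log2-scale matrix plus its ground truth.

    Features are unit-SD normal around feature-specific baselines (log2
    abundances around 18, the scale of typical qPCR/LC-MS panels).  The
    lipid platform organises the first ``n_blocks * block_size`` features
    into latent-factor blocks with pairwise correlation sqrt(block_r2),
    i.e. pairwise squared correlation ``block_r2``.  The first
    ``n_diff_features`` features receive a population shift of
    ``effect_size`` SD in one population (rotating across populations).
    Sex (+0.5 SD on every 5th feature) and batch/plate offsets (N(0, 0.4)
    per level on every 3rd feature) exercise covariate adjustment.
    """
    rng = np.random.default_rng(design.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    n_features = {
        "lipid": design.n_lipids,
        "expression": design.n_transcripts,
        "mirna": design.n_mirnas,
    }[platform]
    prefix = {"lipid": "lip", "expression": "tx", "mirna": "miR"}[platform]
    n = len(covariates)
    baseline = rng.normal(18.0, 2.0, size=n_features)
    noise = rng.standard_normal((n, n_features))

    blocks = {}
    n_block_features = 0
    if platform == "lipid":
        # member = loading * factor + sqrt(1 - loading^2) * noise gives
        # pairwise correlation loading^2, so loading = block_r2 ** 0.25
        # yields pairwise squared correlation of exactly block_r2
        loading = float(design.block_r2**0.25)
        for b in range(design.n_blocks):
            cols = np.arange(b * design.block_size, (b + 1) * design.block_size)
            factor = rng.standard_normal(n)
            noise[:, cols] = (
                loading * factor[:, None]
                + np.sqrt(1.0 - loading**2) * rng.standard_normal((n, cols.size))
            )
            blocks[f"block{b:02d}"] = [f"{prefix}{c:04d}" for c in cols]
        n_block_features = design.n_blocks * design.block_size

    values = baseline[None, :] + noise

    # planted population shifts occupy the trailing features (outside the
    # correlated blocks), rotating the shifted population across features
    pops = covariates["population"].to_numpy()
    pop_labels = list(design.pop_labels)
    shifted = {}
    n_diff = min(design.n_diff_features, n_features - n_block_features)
    diff_cols = np.arange(n_features - n_diff, n_features)
    for rank, j in enumerate(diff_cols):
        target = pop_labels[rank % len(pop_labels)]
        values[pops == target, j] += design.effect_size
        shifted[f"{prefix}{j:04d}"] = {
            "population": target,
            "shift_sd": design.effect_size,
        }

    # sex and batch/plate nuisance effects on non-block features only (block
    # correlations stay at their design target)
    free = np.arange(n_block_features, n_features)
    sex_cols = free[::5]
    values[:, sex_cols] += 0.5 * (covariates["sex"].to_numpy() == "M")[:, None]
    batch_key = "rt_plate" if platform == "mirna" else "batch"
    batch_cols = free[::3]
    levels = pd.unique(covariates[batch_key])
    offsets = rng.normal(0.0, 0.4, size=len(levels))
    for lev, off in zip(levels, offsets):
        values[np.ix_(covariates[batch_key].to_numpy() == lev, batch_cols)] += off

    if design.missing_rate > 0:
        mask = rng.random(values.shape) < design.missing_rate
        values[mask] = np.nan

    matrix = pd.DataFrame(
        values,
        index=covariates.index,
        columns=pd.Index([f"{prefix}{j:04d}" for j in range(n_features)], name="feature"),
    )
    truth = {
        "platform": platform,
        "shifted_features": shifted,
        "blocks": blocks,
        "batch_covariate": batch_key,
        "sex_effect_features": [f"{prefix}{j:04d}" for j in sex_cols],
        "note": "generative distributions are implementer choices; "
        "no published generative model exists for these platforms",
    }
    return matrix, truth


def simulate_cohort(design: CohortDesign) -> SyntheticCohort:
    """Generate the full cohort: genotypes, HLA, three quantitative platforms.

    A single ``numpy`` Generator seeded from ``design.seed`` drives every
    draw, so a fixed design reproduces the cohort byte-for-byte.
    """
    rng = np.random.default_rng(design.seed)
    covariates = _covariates(design, rng)

    p_anc = rng.uniform(0.05, 0.95, size=design.n_snps)
    freqs = simulate_balding_nichols_frequencies(
        p_anc, design.fst_target, n_pops=len(design.pop_labels), rng=rng
    )
    genotypes = simulate_genotypes(freqs, design, rng=rng)
    genotypes.sample_meta["sex"] = covariates["sex"]

    hla_table, hla_truth = simulate_hla_table(design, rng=rng)

    lipids, lipid_truth = simulate_quantitative_platform(design, "lipid", covariates, rng)
    expr, expr_truth = simulate_quantitative_platform(design, "expression", covariates, rng)
    mirna, mirna_truth = simulate_quantitative_platform(design, "mirna", covariates, rng)

    truth = {
        "snp_ancestral_freqs": p_anc.tolist(),
        "snp_fst_target": design.fst_target,
        "hla_population_freqs": hla_truth,
        "lipid": lipid_truth,
        "expression": expr_truth,
        "mirna": mirna_truth,
    }
    return SyntheticCohort(
        design=design,
        genotypes=genotypes,
        hla_table=hla_table,
        lipid_matrix=lipids,
        expression_matrix=expr,
        mirna_matrix=mirna,
        covariates=covariates,
        truth=truth,
    )
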