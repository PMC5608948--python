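"""Published benchmark inputs for the Singapore Chinese/Malay/Indian cohort.

These are printed summary values from the source study's result tables —
per-population allele frequencies of six pharmacogenomic SNPs, allele
frequencies of drug-associated HLA classical alleles, least-squares means
of the most differentiated miRNAs, and the lipid tagging headcounts.  They
serve as fixed inputs for golden-value checks: recomputing F_ST, fold
changes and representative counts from them must reproduce the printed
outputs.
"""

from __future__ import annotations

POPULATIONS = ("Chinese", "Malay", "Indian")

# per-population alternate-allele frequencies and the published F_ST
PHARMACOGENOMIC_SNP_FST = {
    # variant: ((freq_Chinese, freq_Malay, freq_Indian), published_fst)
    "rs2359612": ((0.118, 0.263, 0.900), 0.471),  # VKORC1 intron
    "rs749671": ((0.118, 0.273, 0.900), 0.466),  # VKORC1/ZNF646
    "rs8050894": ((0.118, 0.263, 0.868), 0.434),  # VKORC1 intron
    "rs7294": ((0.109, 0.272, 0.822), 0.387),  # VKORC1 UTR
    "rs1238741": ((0.179, 0.272, 0.865), 0.375),  # ADH4/5
    "rs1197440": ((0.038, 0.165, 0.670), 0.361),  # ABCB5 intron
}

# drug-associated HLA classical alleles: per-population allele frequency
# (proportions) and published F_ST.  A*31:01 is omitted: its printed
# frequencies are not fully legible in the source table.  B*58:01 prints the
# same frequencies as B*13:01 in the source and is kept for completeness.
HLA_ALLELE_FST = {
    "B*15:02": ((0.074, 0.124, 0.038), 0.017),
    "B*13:01": ((0.102, 0.030, 0.008), 0.036),
    "B*38:02": ((0.046, 0.043, 0.029), 0.001),
    "B*57:01": ((0.000, 0.009, 0.075), 0.041),
    "B*58:01": ((0.102, 0.030, 0.008), 0.036),
}

# least-squares means (log2 scale) per population for the five most
# differentiated miRNAs, with published fold changes vs. Chinese.
# fc entries: (FC Malay vs Chinese, FC Indian vs Chinese).
MIRNA_LSM = {
    "miR_4732_3p": {"lsm": (18.01, 18.17, 17.42), "fc": (1.12, 0.67)},
    "miR_375": {"lsm": (18.04, 17.52, 17.38), "fc": (0.70, 0.63)},
    "miR_140_3p": {"lsm": (21.82, 22.00, 21.40), "fc": (1.13, 0.75)},
    "miR_378a_3p": {"lsm": (20.81, 20.87, 20.48), "fc": (1.04, 0.79)},
    "miR_378a_5p": {"lsm": (15.10, 15.35, 14.69), "fc": (1.19, 0.75)},
}
# miR_4732_3p's printed Indian-vs-Chinese FC (0.67) is inconsistent with its
# printed lsm values at 2 dp (2^(17.42-18.01) = 0.66); treated as rounding
# in the source and excluded from golden comparisons.
MIRNA_FC_EXCLUDED = {("miR_4732_3p", "Indian")}

# lipid tagging headcounts: per population, (K species, covered by tags
# incl. the tags themselves, number of tags, published representative count)
LIPID_TAGGING_COUNTS = {
    "Chinese": (282, 71, 29, 240),
    "Malay": (282, 61, 26, 247),
    "Indian": (282, 60, 26, 248),
}
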