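"""Gene panels and subtype universe used throughout the package.

Gene symbols follow the legacy nomenclature of the classic 50-gene
intrinsic-subtype panel (e.g. ``KNTC2``/``CDCA1`` rather than the current
``NDC80``/``NUF2``); :func:`pam50kit.io_formats.harmonize_gene_ids` maps
between the two when matching external annotation.
"""

#: Intrinsic subtype universe, in canonical (tie-break) order.
SUBTYPES = ("Basal", "Her2", "LumA", "LumB", "Normal")

#: The 50 genes of the intrinsic-subtype signature (legacy symbols).
PAM50_GENES = (
    "ACTR3B", "ANLN", "BAG1", "BCL2", "BIRC5", "BLVRA", "CCNB1", "CCNE1",
    "CDC20", "CDC6", "CDCA1", "CDH3", "CENPF", "CEP55", "CXXC5", "EGFR",
    "ERBB2", "ESR1", "EXO1", "FGFR4", "FOXA1", "FOXC1", "GPR160", "GRB7",
    "KIF2C", "KNTC2", "KRT14", "KRT17", "KRT5", "MAPT", "MDM2", "MELK",
    "MIA", "MKI67", "MLPH", "MMP11", "MYBL2", "MYC", "NAT1", "ORC6L",
    "PGR", "PHGDH", "PTTG1", "RRM2", "SFRP1", "SLC39A6", "TMEM45B", "TYMS",
    "UBE2C", "UBE2T",
)

#: The 11 proliferation genes whose mean log2 expression is the
#: Proliferation Score.
PROLIFERATION_GENES = (
    "CCNB1", "UBE2C", "BIRC5", "KNTC2", "CDC20", "PTTG1", "RRM2", "MKI67",
    "TYMS", "CEP55", "CDCA1",
)

#: Default housekeeper panel for digital-count normalization.  The
#: housekeeper set is always config-supplied; this default is only used by
#: the synthetic-data generator and the CLI when no set is given.
DEFAULT_HOUSEKEEPERS = ("ACTB", "MRPL19", "PSMC4", "RPLP0", "SF3A1")

#: Legacy-symbol aliases for the panel genes.
DEFAULT_GENE_ALIASES = {
    "KNTC2": "NDC80",
    "CDCA1": "NUF2",
    "ORC6L": "ORC6",
}
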