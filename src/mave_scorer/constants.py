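"""Pipeline-wide constants.

Every assay-defined threshold lives here exactly once so that configuration,
scoring, and calibration agree on the same numbers.  All are overridable
through function arguments or the run configuration; these are the defaults
used for the KCNQ1 maps.
"""

# --- library geometry -------------------------------------------------------
PROTEIN_LENGTH = 676            # residues in KCNQ1 (NM_000218)
BARCODE_LENGTH = 18             # random N18 tag per plasmid
BARCODES_PER_VARIANT_MEAN = 19.5

# Mutagenesis zones (residue ranges, inclusive).  Zone boundaries follow the
# restriction sites used to split the cDNA; a residue belongs to one zone.
ZONES = {1: (1, 236), 2: (237, 394), 3: (395, 676)}

# --- read-count filters (reads per million) ---------------------------------
ABUNDANCE_MIN_MEAN_RPM = 25.0   # variant dropped from a replicate when the
                                # mean RPM across the four bins is below this
FUNCTION_MIN_DAY0_RPM = 15.0    # variant dropped from a replicate when the
                                # pre-selection (day 0) RPM is below this
FUNCTION_PSEUDOCOUNT = 10.0     # added to both terms of the log2 day ratio

# --- normalization anchors --------------------------------------------------
# Nonsense variants used as the zero anchor: residues 1-610 ("early"
# nonsense) for the abundance assays; the function assays additionally drop
# residues 239-307 from the anchor set.
EARLY_NONSENSE_RANGE = (1, 610)
LATE_NONSENSE_RANGE = (611, 676)
FUNCTION_NONSENSE_EXCLUDED_RANGE = (239, 307)

# --- categorization ---------------------------------------------------------
LOSS_CUTOFF = 0.25              # score < 0.25 -> complete loss
SYNONYMOUS_CI = (2.5, 97.5)     # percentiles of the synonymous distribution
                                # bounding the "normal" category
SEM_NOISE_CUTOFF = 0.5          # replicate-SEM filter on the normalized scale
MIN_SYNONYMOUS_FOR_PERCENTILES = 20

# --- drug-binding residues --------------------------------------------------
# Residues critical for ML277 / R-L3 responsiveness; missense variants here
# are excluded from the final function score sets (abundance sets keep them).
DRUG_BINDING_RESIDUES = frozenset({248, 251, 255, 267, 335, 339})

# --- dominant-negative calling ----------------------------------------------
# Per-assay score cutoffs for counting an assay as "reduced":
# (abundance, function, het_abundance, het_function)
DN_CUTOFFS = {
    "abundance": 0.25,
    "function": 0.25,
    "het_abundance": 0.25,
    "het_function": 0.0,
}
ASSAYS = ("abundance", "function", "het_abundance", "het_function")

# --- calibration ------------------------------------------------------------
# Allele-frequency cutoffs for the frequency-based benign rules (maximum
# filtering allele frequency across five gnomAD ancestry groups).
BA1_MAF = 0.004
BS1_MAF = 0.0004
SEMIRARE_MAF = 0.000134         # 2x the MAF of the most common P/LP missense

LLR_BANDWIDTH = 0.2             # Gaussian kernel bandwidth on the score scale
LLR_TRIM_RANGE = (-0.3, 1.5)    # scores outside this range are excluded
LLR_GRID_STEP = 0.001
LLR_DENSITY_FLOOR = 1e-12

# Evidence-strength thresholds on the odds-of-pathogenicity scale
# (points-based ACMG framework: strong/moderate/supporting).
ODDS_STRONG = 18.7
ODDS_MODERATE = 4.33
ODDS_SUPPORTING = 2.08
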