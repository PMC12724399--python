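# Methods

## The experiment being modelled

Four pooled assays measure every single-codon variant of the KCNQ1
potassium channel in human cells carrying a single-copy landing pad, so
each cell expresses exactly one barcoded variant:

* **Surface abundance (sort-seq).** Cells are antibody-stained for an
  extracellular epitope and FACS-sorted into four bins at the population
  quartiles of fluorescence. Sequencing barcodes per bin gives each
  variant a bin-occupancy profile.
* **Channel function (growth selection).** Under two channel activators
  plus ouabain, potassium-channel activity is a fitness cost. Over 28
  days, loss-of-function variants rise in relative frequency and
  gain-of-function variants fall; the day-28/day-0 frequency ratio
  encodes channel activity.

Both assays run in a *variant-only* configuration and a *heterozygous*
configuration (cells co-express one wild-type allele), which separates
simple loss of function from dominant-negative poisoning of mixed
channel tetramers.

## Score statistics

* Abundance raw score: `W = Σ (k−1)·F_k / Σ F_k` over bins k = 1…4,
  where `F_k` is the variant's reads-per-million in bin k. W ∈ [0, 3].
* Function raw score: `R28 = log2((F_28 + 10)/(F_0 + 10))`, pseudocount
  10 RPM on both terms.
* Coverage filters (strict, per replicate): abundance variants with a
  mean RPM across bins below 25 are dropped; function variants with a
  day-0 RPM below 15 are dropped from that replicate.
* Normalization: an affine map per replicate sends the median
  early-nonsense raw score (residues 1–610) to 0 and the median
  synonymous raw score to 1. The function assays exclude residues
  239–307 from the nonsense anchor (nonsense variants there behave
  atypically). The heterozygous abundance assay anchors raw `W = 0`
  to 0 instead, because truncating the variant allele leaves the
  wild-type allele's surface signal intact. The variant-only abundance
  assay normalizes within each mutagenesis zone (1–236 / 237–394 /
  395–676) before merging, since some replicates were collected one zone
  at a time. After replicate averaging, variants with SEM > 0.5 (on the
  normalized scale; configurable — the original study's cutoff is in its
  supplement) are removed and the merged scores are re-anchored, so the
  final medians are exactly 0 and 1.
* Categories: the normal range is the empirical 2.5th–97.5th percentile
  interval of the synonymous score distribution; above it is gain, below
  it but ≥ 0.25 is partial loss, below 0.25 is complete loss. Boundary
  conventions: loss iff score < 0.25; a score exactly at 0.25 is partial
  loss. The interval is read as percentiles of the score distribution,
  not a CI of its mean — only that reading yields non-degenerate gain
  and partial ranges.
* Missense variants at the six activator-binding residues (248, 251,
  255, 267, 335, 339) are excluded from the function score sets (their
  low scores may reflect lost drug response rather than lost channel
  function); abundance sets keep them, as the sorts use no activators.

## Dominant-negative calls and integration

A complete missense variant (all four scores present) counts how many
assays fall below the cutoffs (abundance 0.25, function 0.25,
heterozygous abundance 0.25, heterozygous function 0): 4 of 4 → severe
DN, 3 of 4 → strong DN. The heterozygous-function cutoff is 0, not
0.25, because on that assay's scale 0 is already the haploinsufficient
(nonsense-like) level — only tetramer poisoning drives it lower.

PCA/k-means (k = 6, k-means++ with `n_init = 50` and a fixed seed) runs
on the standardized four-score matrix; all four components are retained
for clustering. Clusters are auto-named from their centroid profiles —
all low → dominant negative; variant-only low with heterozygous normal →
haploinsufficient; function above the synonymous range →
gain-of-function; all within it → normal; else partial loss — with the
per-assay synonymous percentile bounds taken from the matrix itself.
Naming is a pure function of centroids and bounds; ties in duplicate
names are numbered by cluster id.

Classifier combination trains logistic regression, random forest, and
Gaussian naive Bayes on labelled complete missense variants. LR and GNB
see standardized scores, the scale-invariant forest sees raw scores
(the study does not state which representation it used). Leave-one-out
CV probabilities quantify performance; note LOO is pessimistically
biased under label permutation, so the chance-level test band is
(0.25, 0.7) rather than a symmetric band around 0.5.

## Clinical calibration

Truth sets combine ClinVar protein-level classifications (deduplicated
keeping the definitive call; definitive conflicts raise) with
frequency-based benign rules using the maximum filtering allele
frequency across five ancestry groups: MAF > 0.004 (stand-alone),
0.004 > MAF > 0.0004 (strong), and 0.0004 > MAF > 0.000134 with zero
reported disease cases (the floor is twice the frequency of the most
common known pathogenic missense variant). Four flavors are supported
(ClinVar+ / ClinVar × missense / all-consequence).

* **ROC/AUC** by midrank Mann–Whitney; lower score ⇒ more pathogenic.
* **Binary OddsPath**: with prior pathogenic proportion P1 and
  post-test proportion P2 among abnormal (or normal) scores,
  `OddsPath = odds(P2)/odds(P1)`. An empty cell receives one
  opposite-label pseudo-variant before computing P2 — with the published
  control outcomes (168/204 pathogenic abnormal, 0/28 benign abnormal)
  this yields 23.06 → 23.1 for pathogenicity and 0.1765 for benignity
  (published as 0.177; same arithmetic, different rounding). OddsPath is
  reported on the odds scale, which matches the published magnitudes.
* **Continuous LLR**: Gaussian kernel density estimates of the
  pathogenic and benign score distributions with an *absolute* bandwidth
  of 0.2 on the normalized score scale (scipy's `gaussian_kde` rescales
  bandwidth by the sample sd, so the KDE sum is implemented directly and
  cross-checked against a compensated `gaussian_kde` in tests). Scores
  outside (−0.3, 1.5) are trimmed; the curve is evaluated on a 0.001
  grid with densities floored at 1e−12, and interpolated linearly for
  arbitrary scores.
* **Evidence strengths** map odds of pathogenicity to ACMG categories at
  the symmetric points-based thresholds 18.7 / 4.33 / 2.08 (the study
  names only the resulting categories; the thresholds come from the
  points framework underlying the ClinGen recommendations it follows,
  and are configurable). Benign evidence is capped at moderate.

## Small clinical utilities

Case-control risk ratio `(a/(a+c))/(b/(b+d))` with a Katz log-normal CI
(the source for the interval method is not named in the study; exact
intervals can be substituted). `a = 0` returns RR 0 flagged one-sided;
`b = 0` raises. Splice-disruption aggregation returns
`1 − (1−AG)(1−AL)(1−DG)(1−DL)` — the complement of the product form
as printed elsewhere, chosen because only the complement is a
probability of aberrant splicing that increases in each sub-score; the
bare product is available behind a flag.

## The synthetic world

The generator's defaults state a desk-scale version of the real screen:
2,000 variants (vs ~14,000), 19.5 barcodes/variant, four quartile bins,
timepoints 0/7/14/21/28 days, three replicates, 5 M reads per sample
(scaled from ≥25 M in proportion to library size, preserving
per-variant depth ~500 RPM).

Each variant draws four latent effects (variant-only/heterozygous ×
abundance/function, on the normalized score scale) from one of eight
archetypes — wild-type-like, early nonsense, late nonsense (stabilizing,
gain-like), missense LOF, partial, GOF, dominant negative (all four
near 0), haploinsufficient (variant-only near 0, heterozygous abundance
near 1) — with within-archetype sd 0.05. Archetype proportions mirror
the observed class composition of the real map (~11% complete loss,
~10% partial, ~3% gain, ~7% DN, ~4.5% nonsense).

Mechanics and noise model:

* FACS: cell log-fluorescence ~ Normal(log latent, σ = 0.6) — a standard
  log-normal flow-cytometry noise model (the study states none) — with a
  background floor of 0.02; bin boundaries are the exact quartiles of
  the simulated mixture (solved by bisection), cells are multinomially
  assigned, and reads are Poisson at the configured depth. Shot noise
  dominates at the stated depths, hence Poisson-on-multinomial.
* Selection: exponential depletion at 0.063/day per unit channel
  activity — calibrated so wild-type activity reproduces the observed
  ~17% 28-day competitive index under the triple-drug condition — with
  activity clipped at 0. Heterozygous pools use activity
  `0.5 + 0.5 × het score`, encoding the wild-type allele's half current.
* Replicates jitter latents with sd 0.04; barcode abundances are
  log-normal (sd 0.5); barcode errors are substitutions only (extraction
  is anchored by fixed flanks, so indels mostly fail flank matching).

What a green test establishes — and does not: the simulation validates
the pipeline's arithmetic, filters, anchoring, and classification rules
against known ground truth, and shows the stated noise world is
recoverable (function-score Spearman ρ ≥ 0.9 against latent function;
≥ 90% of simulated DN archetype variants called severe/strong). It does
not emulate replicate batch structure, zone-specific artifacts,
drug-binding confounds, position-correlated effects, or the real
library's barcode imbalance tails, so it cannot certify performance on
real sequencing data.

## Numerical choices and edge cases

* Trough thresholding histograms log10 counts in 25 bins, smooths with a
  3-bin moving average, and thresholds at the deepest minimum between
  the two largest local maxima; unimodal histograms fall back to a fixed
  threshold (default 2) with the removal tallied in the drop log.
* Hamming collapse processes barcodes by descending count, breaking
  count ties by keeping the lexicographically smaller barcode; a
  pigeonhole segment index keeps it near-linear. The greedy order makes
  the result deterministic and idempotent.
* Consensus calls require coverage ≥ 3 reads and a per-position majority
  ≥ 0.6 (the study states only "low coverage with ambiguous genotypes";
  both are configurable); wrong-length inserts are ambiguous; barcodes
  seen in two library zones are removed.
* Variants with zero reads in all four bins have undefined W and are
  dropped rather than scored 0; the R28 pseudocount makes the function
  score total.
* Single-replicate variants have undefined SEM and pass the noise filter.
* All stochastic stages take explicit seeds; per-assay, per-replicate
  streams are spawned from the run seed, so identical configuration and
  seed give byte-identical outputs.

## Known limitations

* The read-level subassembly path is O(reads × CDS length) in memory and
  is run at reduced scale by default; the full-scale pipeline uses the
  simulator's ground-truth barcode library.
* `build_truth_set` consumes static ClinVar-style and frequency tables;
  there is no live database access.
* Scores are amino-acid-level; codon-level effects and splice effects
  are out of scope (splice aggregation only post-processes precomputed
  scores).
* PS3/BS3 evidence is one ACMG criterion, not a variant verdict.
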