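"""Per-variant score calculation for the four pooled assays.

Raw statistics
--------------
* Surface abundance (sort-seq): the weighted-bin average
  ``W = (0*F1 + 1*F2 + 2*F3 + 3*F4) / (F1 + F2 + F3 + F4)``
  where ``F_k`` is the variant's read frequency in bin k.  W ranges from 0
  (all reads in the dimmest bin) to 3 (all in the brightest).
* Channel function (drug selection): the log-ratio of endpoint to
  pre-selection frequency with a pseudocount of 10 RPM,
  ``R28 = log2((F_day28 + 10) / (F_day0 + 10))``.
  Because channel activity is a fitness cost under selection, loss-of-
  function variants have high R28 and wild-type-like variants low R28.

Normalization
-------------
Raw scores are affinely rescaled per replicate so that the median
synonymous variant scores 1 and the null anchor scores 0.  The null anchor
is the median early-nonsense variant (residues 1-610; the function assays
further exclude residues 239-307 from the anchor set), except in the
heterozygous abundance assay where truncating the variant allele leaves the
wild-type allele's surface signal intact — there the anchor is the lowest
possible raw score (all reads in bin 1, W = 0).  Replicates are averaged,
noisy variants (high SEM) removed, and the merged scores re-anchored once
more, so the final scale has synonymous median exactly 1 and anchor median
exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C
from .variants import MISSENSE, NONSENSE, SYNONYMOUS, Variant

__all__ = [
    "annotate_variants",
    "zone_of",
    "aggregate_to_variants",
    "abundance_raw",
    "function_raw",
    "filter_low_coverage",
    "normalize_replicate",
    "merge_replicates",
    "categorize",
    "exclude_drug_residues",
    "competitive_index",
    "score_assay",
]

BIN_SAMPLES = ("bin1", "bin2", "bin3", "bin4")


def annotate_variants(df: pd.DataFrame, column: str = "variant") -> pd.DataFrame:
    """Add position / wt_aa / alt_aa / consequence columns parsed from ids."""
    parsed = [Variant.parse(s) for s in df[column]]
    out = df.copy()
    out["position"] = [v.position for v in parsed]
    out["wt_aa"] = [v.wt for v in parsed]
    out["alt_aa"] = [v.alt for v in parsed]
    out["consequence"] = [v.consequence for v in parsed]
    return out


def zone_of(position: int | np.ndarray, zones=None):
    """Mutagenesis zone of a residue position (vectorized)."""
    zones = zones or C.ZONES
    pos = np.asarray(position)
    out = np.zeros(pos.shape, dtype=int)
    for z, (lo, hi) in zones.items():
        out = np.where((pos >= lo) & (pos <= hi), z, out)
    if np.any(out == 0):
        bad = np.asarray(pos)[out == 0]
        raise ValueError(f"positions outside all zones: {bad[:5]}")
    return out if out.shape else int(out)


# ---------------------------------------------------------------------------
# Counts -> raw scores
# ---------------------------------------------------------------------------

def aggregate_to_variants(
    counts: pd.DataFrame, barcode_map: pd.DataFrame
) -> pd.DataFrame:
    """Pool barcode-level RPM into variant-level RPM.

    ``counts`` is a long table (entity_id, sample, replicate, rpm) keyed by
    barcode; ``barcode_map`` maps accepted barcodes to variants.  Barcodes
    absent from the map are dropped; the pooled values are renormalized to
    RPM within each (sample, replicate).
    """
    mapping = barcode_map.set_index("barcode")["variant"]
    matched = counts[counts["entity_id"].isin(mapping.index)].copy()
    if matched.empty:
        raise ValueError("no counted barcode appears in the barcode map")
    matched["variant"] = mapping[matched["entity_id"]].to_numpy()
    out = (
        matched.groupby(["variant", "sample", "replicate"], as_index=False)["rpm"]
        .sum()
        .rename(columns={"variant": "entity_id"})
    )
    totals = out.groupby(["sample", "replicate"])["rpm"].transform("sum")
    out["rpm"] = 1e6 * out["rpm"] / totals
    return out


def _pivot(counts: pd.DataFrame, samples) -> pd.DataFrame:
    wide = counts.pivot_table(
        index=["entity_id", "replicate"],
        columns="sample",
        values="rpm",
        aggfunc="sum",
        fill_value=0.0,
    )
    missing = [s for s in samples if s not in wide.columns]
    if missing:
        raise ValueError(f"count table lacks samples: {missing}")
    return wide


def abundance_raw(counts: pd.DataFrame) -> pd.DataFrame:
    """Weighted-bin score W per (variant, replicate).

    Returns columns (variant, replicate, raw, mean_rpm) with
    ``mean_rpm`` = mean RPM across the four bins.  Variants with zero reads
    in all four bins within a replicate are dropped (W undefined).
    """
    wide = _pivot(counts, BIN_SAMPLES)
    f = wide[list(BIN_SAMPLES)].to_numpy(dtype=float)
    if (f < 0).any():
        raise ValueError("negative counts in abundance table")
    total = f.sum(axis=1)
    keep = total > 0
    weights = np.arange(4.0)
    w = (f[keep] * weights).sum(axis=1) / total[keep]
    idx = wide.index[keep]
    return pd.DataFrame(
        {
            "variant": idx.get_level_values("entity_id"),
            "replicate": idx.get_level_values("replicate"),
            "raw": w,
            "mean_rpm": total[keep] / 4.0,
        }
    )


def function_raw(
    counts: pd.DataFrame,
    day0: str = "day0",
    day_final: str = "day28",
    pseudocount: float = C.FUNCTION_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Selection score R28 per (variant, replicate); mean_rpm is day-0 RPM."""
    wide = _pivot(counts, (day0, day_final))
    f0 = wide[day0].to_numpy(dtype=float)
    f1 = wide[day_final].to_numpy(dtype=float)
    if (f0 < 0).any() or (f1 < 0).any():
        raise ValueError("negative counts in function table")
    raw = np.log2((f1 + pseudocount) / (f0 + pseudocount))
    return pd.DataFrame(
        {
            "variant": wide.index.get_level_values("entity_id"),
            "replicate": wide.index.get_level_values("replicate"),
            "raw": raw,
            "mean_rpm": f0,
        }
    )


# ---------------------------------------------------------------------------
# Filters and normalization
# ---------------------------------------------------------------------------

def filter_low_coverage(
    raw: pd.DataFrame, assay: str, threshold: float | None = None
) -> pd.DataFrame:
    """Drop under-sequenced variants per replicate (strict inequality).

    Abundance assays: mean RPM across the four bins below 25; function
    assays: day-0 RPM less than 15.
    """
    if threshold is None:
        threshold = (
            C.ABUNDANCE_MIN_MEAN_RPM
            if assay in ("abundance", "het_abundance")
            else C.FUNCTION_MIN_DAY0_RPM
        )
    return raw[raw["mean_rpm"] >= threshold].reset_index(drop=True)


def _anchor_nonsense_mask(info: pd.DataFrame, assay: str) -> pd.Series:
    """Nonsense variants eligible as the zero anchor for this assay."""
    lo, hi = C.EARLY_NONSENSE_RANGE
    mask = (
        (info["consequence"] == NONSENSE)
        & (info["position"] >= lo)
        & (info["position"] <= hi)
    )
    if assay in ("function", "het_function"):
        xlo, xhi = C.FUNCTION_NONSENSE_EXCLUDED_RANGE
        mask &= ~((info["position"] >= xlo) & (info["position"] <= xhi))
    return mask


def _affine_params(
    scores: pd.Series, info: pd.DataFrame, assay: str
) -> tuple[float, float]:
    """(anchor0, anchor1): raw values mapped to 0 and 1."""
    syn = scores[info.loc[scores.index, "consequence"] == SYNONYMOUS]
    if syn.empty:
        raise ValueError(f"{assay}: no synonymous variants available as anchor")
    anchor1 = float(syn.median())
    if assay == "het_abundance":
        anchor0 = 0.0
    else:
        nons = scores[_anchor_nonsense_mask(info.loc[scores.index], assay)]
        if nons.empty:
            raise ValueError(f"{assay}: no anchor nonsense variants available")
        anchor0 = float(nons.median())
    if anchor1 == anchor0:
        raise ValueError(f"{assay}: degenerate anchors (synonymous == nonsense)")
    return anchor0, anchor1


def normalize_replicate(
    raw: pd.DataFrame,
    assay: str,
    by_zone: bool = False,
) -> pd.DataFrame:
    """Anchor raw scores per replicate: nonsense median -> 0, synonymous
    median -> 1 (heterozygous abundance anchors raw 0 -> 0 instead).

    With ``by_zone`` (variant-only abundance, where some replicates were
    run one mutagenesis zone at a time) the affine map is fit within each
    (replicate, zone) before the merged table is re-anchored downstream.
    """
    info = annotate_variants(raw).set_index(raw.index)
    out = raw.copy()
    out["score"] = np.nan
    groups = ["replicate", "zone"] if by_zone else ["replicate"]
    if by_zone:
        info["zone"] = zone_of(info["position"].to_numpy())
        out["zone"] = info["zone"]
    for _, idx in out.groupby(groups).groups.items():
        sub = out.loc[idx, "raw"]
        a0, a1 = _affine_params(sub, info, assay)
        out.loc[idx, "score"] = (sub - a0) / (a1 - a0)
    return out.drop(columns=["zone"], errors="ignore")


def merge_replicates(
    norm: pd.DataFrame,
    assay: str,
    sem_cutoff: float | None = C.SEM_NOISE_CUTOFF,
) -> pd.DataFrame:
    """Average normalized scores across replicates and re-anchor.

    Variants whose standard error of the mean exceeds ``sem_cutoff`` are
    removed (single-replicate variants have undefined SEM and are kept).
    The merged scores get one final affine re-anchoring so the medians sit
    exactly at (0, 1).
    """
    g = norm.groupby("variant")["score"]
    merged = pd.DataFrame(
        {"score": g.mean(), "sem": g.sem(ddof=1), "n_reps": g.count()}
    )
    if sem_cutoff is not None:
        merged = merged[~(merged["sem"] > sem_cutoff)]
    info = annotate_variants(merged.reset_index()).set_index("variant")
    a0, a1 = _affine_params(merged["score"], info, assay)
    scale = a1 - a0
    merged["score"] = (merged["score"] - a0) / scale
    merged["sem"] = merged["sem"] / abs(scale)
    out = merged.reset_index()
    out["assay"] = assay
    return annotate_variants(out)


# ---------------------------------------------------------------------------
# Categories
# ---------------------------------------------------------------------------

def categorize(
    scores: pd.DataFrame,
    loss_cutoff: float = C.LOSS_CUTOFF,
    ci_percentiles: tuple[float, float] = C.SYNONYMOUS_CI,
    min_synonymous: int = C.MIN_SYNONYMOUS_FOR_PERCENTILES,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Assign loss / partial_loss / normal / gain categories.

    The normal range is the empirical [2.5th, 97.5th] percentile interval
    of the synonymous score distribution.  Scores above it are gain; below
    it but at or above 0.25 partial loss; below 0.25 complete loss.
    Returns the categorized table and the (lower, upper) bounds.
    """
    if "consequence" not in scores.columns:
        scores = annotate_variants(scores)
    syn = scores.loc[scores["consequence"] == SYNONYMOUS, "score"]
    if len(syn) < min_synonymous:
        raise ValueError(
            f"need >= {min_synonymous} synonymous variants for stable "
            f"percentiles, got {len(syn)}"
        )
    lower, upper = np.percentile(syn, ci_percentiles)
    if lower <= loss_cutoff:
        raise ValueError(
            f"synonymous lower bound {lower:.3f} <= loss cutoff {loss_cutoff}; "
            "category scheme degenerate"
        )
    s = scores["score"]
    out = scores.copy()
    out["category"] = np.select(
        [s > upper, s >= lower, s >= loss_cutoff],
        ["gain", "normal", "partial_loss"],
        default="loss",
    )
    return out, (float(lower), float(upper))


def exclude_drug_residues(
    scores: pd.DataFrame,
    assay: str,
    residues=C.DRUG_BINDING_RESIDUES,
) -> pd.DataFrame:
    """Remove missense variants at activator-binding residues.

    Applies only to the function assays (the activators are absent from the
    abundance sorts); synonymous and nonsense changes at those positions
    are kept.
    """
    if assay not in ("function", "het_function"):
        return scores
    if "consequence" not in scores.columns:
        scores = annotate_variants(scores)
    drop = (scores["consequence"] == MISSENSE) & scores["position"].isin(residues)
    return scores[~drop].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def competitive_index(
    a_wt_day0: float, a_wt_dayy: float, a_empty_day0: float, a_empty_dayy: float
) -> float:
    """Percentage growth of WT-channel cells relative to empty-vector cells.

    ``100 * (A_WT,y / A_WT,0) / (A_empty,y / A_empty,0)``.
    """
    if a_wt_day0 <= 0 or a_empty_day0 <= 0:
        raise ValueError("day-0 abundances must be positive")
    if a_empty_dayy <= 0:
        raise ValueError("empty-vector abundance at day y must be positive")
    return 100.0 * (a_wt_dayy / a_wt_day0) / (a_empty_dayy / a_empty_day0)


@dataclass
class ScoreResult:
    """Final per-assay score set plus the synonymous normal range."""

    scores: pd.DataFrame
    syn_bounds: tuple[float, float]


def score_assay(
    counts: pd.DataFrame,
    assay: str,
    barcode_map: pd.DataFrame | None = None,
    by_zone: bool | None = None,
    sem_cutoff: float | None = C.SEM_NOISE_CUTOFF,
    rpm_threshold: float | None = None,
) -> ScoreResult:
    """Full chain: (aggregate ->) raw -> filter -> normalize -> merge ->
    categorize -> drug-residue exclusion, for one assay.

    ``counts`` may be barcode-level (supply ``barcode_map``) or already
    variant-level.  ``by_zone`` defaults to True for the variant-only
    abundance assay, which was partly run one mutagenesis zone at a time.
    """
    if assay not in C.ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {C.ASSAYS}")
    if barcode_map is not None:
        counts = aggregate_to_variants(counts, barcode_map)
    if by_zone is None:
        by_zone = assay == "abundance"
    raw = (
        abundance_raw(counts)
        if assay in ("abundance", "het_abundance")
        else function_raw(counts)
    )
    raw = filter_low_coverage(raw, assay, threshold=rpm_threshold)
    norm = normalize_replicate(raw, assay, by_zone=by_zone)
    merged = merge_replicates(norm, assay, sem_cutoff=sem_cutoff)
    categorized, bounds = categorize(merged)
    final = exclude_drug_residues(categorized, assay)
    cols = [
        "variant", "position", "wt_aa", "alt_aa", "consequence",
        "assay", "score", "sem", "n_reps", "category",
    ]
    return ScoreResult(scores=final[cols], syn_bounds=bounds)
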