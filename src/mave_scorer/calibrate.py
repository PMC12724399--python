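"""ACMG functional-evidence calibration of assay scores.

Three calibration routes against a benign/pathogenic truth set:

* **ROC/AUC** — rank-based (Mann-Whitney with midranks); by default a
  *lower* score means more pathogenic, matching the normalized assay scale
  where 1 is wild-type-like and 0 is null.
* **Binary OddsPath** — with prior pathogenic proportion ``P1`` and
  post-test proportion ``P2`` (among variants on the abnormal side of a
  score cutoff), ``OddsPath = [P2/(1-P2)] / [P1/(1-P1)]``.  An empty
  contingency cell receives one pseudo-variant of the opposite label
  before ``P2`` is computed, keeping the odds finite.
* **Continuous kernel LLR** — Gaussian kernel density estimates of the
  pathogenic and benign score distributions (bandwidth 0.2 on the
  normalized score scale, scores trimmed to (-0.3, 1.5)); the evidence for
  a score s is ``llr(s) = ln fP(s)/fB(s)``.

Odds of pathogenicity map onto ACMG evidence strengths at the symmetric
points-based thresholds 18.7 / 4.33 / 2.08 (strong / moderate /
supporting), with benign evidence capped at moderate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from . import constants as C

__all__ = [
    "build_truth_set",
    "roc_auc",
    "roc_auc_from_arrays",
    "oddspath_from_contingency",
    "oddspath_binary",
    "LLRCurve",
    "llr_kernel",
    "evidence_from_odds",
    "assign_evidence",
    "TRUTH_FLAVORS",
]

P_LP = "P_LP"
B_LB = "B_LB"

TRUTH_FLAVORS = (
    "clinvar_plus_missense",
    "clinvar_plus_all",
    "clinvar_missense",
    "clinvar_all",
)

# ClinVar classification strings -> canonical label (None = not definitive)
_CLASSIFICATION_MAP = {
    "pathogenic": P_LP,
    "likely pathogenic": P_LP,
    "pathogenic/likely pathogenic": P_LP,
    "p/lp": P_LP,
    "p": P_LP,
    "lp": P_LP,
    "benign": B_LB,
    "likely benign": B_LB,
    "benign/likely benign": B_LB,
    "b/lb": B_LB,
    "b": B_LB,
    "lb": B_LB,
}


def _canonical_label(classification: str) -> str | None:
    return _CLASSIFICATION_MAP.get(str(classification).strip().lower())


def build_truth_set(
    clinvar: pd.DataFrame,
    freq: pd.DataFrame | None = None,
    cases: pd.DataFrame | None = None,
    flavor: str = "clinvar_plus_missense",
    ba1_maf: float = C.BA1_MAF,
    bs1_maf: float = C.BS1_MAF,
    semirare_maf: float = C.SEMIRARE_MAF,
) -> pd.DataFrame:
    """Assemble a benign/pathogenic truth set.

    ``clinvar``: columns (variant, classification) — protein-level records;
    duplicate protein variants are deduplicated keeping the more definitive
    classification (P/LP or B/LB beats VUS/conflicting).
    ``freq``: columns (variant, max_faf) — maximum filtering allele
    frequency across the five major gnomAD ancestry groups.
    ``cases``: columns (variant, n_cases) — reported disease-case counts
    from the literature curation.

    Benign rules beyond ClinVar B/LB (the "+" in ClinVar+): stand-alone
    frequency (MAF > 0.004), strong frequency (0.004 > MAF > 0.0004), and
    semi-rare with no reported cases (0.0004 > MAF > 0.000134, zero cases).
    Missense-only flavors keep only missense variants.  A variant landing
    in both label sets raises.
    """
    if flavor not in TRUTH_FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; expected one of {TRUTH_FLAVORS}")

    labels: dict[str, tuple[str, str]] = {}  # variant -> (label, source)
    conflicts: set[str] = set()
    for variant, group in clinvar.groupby("variant"):
        cls = {_canonical_label(c) for c in group["classification"]}
        cls.discard(None)
        if len(cls) == 2:
            conflicts.add(variant)
        elif len(cls) == 1:
            labels[variant] = (cls.pop(), "clinvar")
    if conflicts:
        raise ValueError(
            f"variants with conflicting definitive classifications: {sorted(conflicts)[:10]}"
        )

    if flavor.startswith("clinvar_plus") and freq is not None:
        case_counts = (
            cases.set_index("variant")["n_cases"] if cases is not None else pd.Series(dtype=int)
        )
        freq_conflicts = []
        for row in freq.itertuples(index=False):
            variant, maf = row.variant, row.max_faf
            if maf > ba1_maf:
                source = "BA1_freq"
            elif maf > bs1_maf:
                source = "BS1_freq"
            elif maf > semirare_maf and int(case_counts.get(variant, 0)) == 0:
                source = "semirare_no_cases"
            else:
                continue
            existing = labels.get(variant)
            if existing is not None:
                if existing[0] == P_LP:
                    freq_conflicts.append(variant)
                continue  # already benign via ClinVar
            labels[variant] = (B_LB, source)
        if freq_conflicts:
            raise ValueError(
                "variants both pathogenic (ClinVar) and benign (frequency): "
                f"{sorted(freq_conflicts)[:10]}"
            )

    out = pd.DataFrame(
        [(v, lab, src) for v, (lab, src) in labels.items()],
        columns=["variant", "label", "source"],
    ).sort_values("variant", ignore_index=True)
    if flavor.endswith("missense"):
        from .scoring import annotate_variants

        out = annotate_variants(out)
        out = out[out["consequence"] == "missense"]
        out = out[["variant", "label", "source"]].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_auc_from_arrays(
    scores: np.ndarray,
    is_pathogenic: np.ndarray,
    higher_is_pathogenic: bool = False,
) -> tuple[float, pd.DataFrame]:
    """AUC by the midrank Mann-Whitney statistic, plus ROC curve points.

    By default lower scores indicate pathogenicity (assay orientation).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(is_pathogenic, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both labels must be represented")
    s = scores if higher_is_pathogenic else -scores
    ranks = rankdata(s)  # midranks for ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    thresholds, tpr, fpr = [], [0.0], [0.0]
    tp = fp = 0
    prev = None
    for i in order:
        if prev is not None and s[i] != prev:
            tpr.append(tp / n_pos)
            fpr.append(fp / n_neg)
        if y[i]:
            tp += 1
        else:
            fp += 1
        prev = s[i]
    tpr.append(1.0)
    fpr.append(1.0)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return float(auc), curve


def roc_auc(
    scores: pd.DataFrame, truth: pd.DataFrame, score_col: str = "score"
) -> tuple[float, pd.DataFrame]:
    """AUC of an assay score table against a truth set (join on variant)."""
    merged = scores.merge(truth, on="variant", how="inner")
    return roc_auc_from_arrays(
        merged[score_col].to_numpy(), (merged["label"] == P_LP).to_numpy()
    )


# ---------------------------------------------------------------------------
# OddsPath
# ---------------------------------------------------------------------------

@dataclass
class OddsPathResult:
    contingency: dict
    prior_p1: float
    oddspath_pathogenic: float
    oddspath_benign: float
    cutoff: float | None = None
    corrections: dict = field(default_factory=dict)


def _odds(p: float) -> float:
    return p / (1.0 - p)


def oddspath_from_contingency(
    path_abnormal: int,
    path_total: int,
    benign_abnormal: int,
    benign_total: int,
    zero_cell_correction: bool = True,
) -> OddsPathResult:
    """OddsPath for pathogenicity and benignity from a 2x2 table.

    ``P1`` is the truth-set pathogenic proportion; for pathogenic evidence
    ``P2`` is the pathogenic proportion among abnormal-score variants, for
    benign evidence among normal-score variants.  With
    ``zero_cell_correction`` an empty cell gains one opposite-label
    pseudo-variant before the proportion is formed, so a perfectly clean
    stratum still yields finite odds.
    """
    if path_total <= 0 or benign_total <= 0:
        raise ValueError("both truth-set classes must be non-empty")
    if not 0 <= path_abnormal <= path_total or not 0 <= benign_abnormal <= benign_total:
        raise ValueError("abnormal counts exceed totals")
    path_normal = path_total - path_abnormal
    benign_normal = benign_total - benign_abnormal
    if (path_abnormal + benign_abnormal) == 0 or (path_normal + benign_normal) == 0:
        raise ValueError("empty abnormal or normal stratum")

    p1 = path_total / (path_total + benign_total)
    corrections = {}

    pa, ba = path_abnormal, benign_abnormal
    if zero_cell_correction and ba == 0:
        ba, corrections["abnormal_benign"] = 1, 1
    if zero_cell_correction and pa == 0:
        pa, corrections["abnormal_pathogenic"] = 1, 1
    p2_path = pa / (pa + ba)

    pn, bn = path_normal, benign_normal
    if zero_cell_correction and pn == 0:
        pn, corrections["normal_pathogenic"] = 1, 1
    if zero_cell_correction and bn == 0:
        bn, corrections["normal_benign"] = 1, 1
    p2_benign = pn / (pn + bn)

    return OddsPathResult(
        contingency={
            "abnormal_pathogenic": path_abnormal,
            "abnormal_benign": benign_abnormal,
            "normal_pathogenic": path_normal,
            "normal_benign": benign_normal,
        },
        prior_p1=p1,
        oddspath_pathogenic=_odds(p2_path) / _odds(p1),
        oddspath_benign=_odds(p2_benign) / _odds(p1),
        corrections=corrections,
    )


def oddspath_binary(
    scores: pd.DataFrame,
    truth: pd.DataFrame,
    cutoff: float,
    score_col: str = "score",
) -> OddsPathResult:
    """Binary OddsPath of a score table: abnormal means score < cutoff."""
    merged = scores.merge(truth, on="variant", how="inner")
    s = merged[score_col].to_numpy(dtype=float)
    if not (s.min() <= cutoff <= s.max()):
        raise ValueError(f"cutoff {cutoff} outside score range [{s.min()}, {s.max()}]")
    path = merged["label"] == P_LP
    abnormal = merged[score_col] < cutoff
    res = oddspath_from_contingency(
        int((path & abnormal).sum()),
        int(path.sum()),
        int((~path & abnormal).sum()),
        int((~path).sum()),
    )
    res.cutoff = cutoff
    return res


# ---------------------------------------------------------------------------
# Continuous kernel LLR
# ---------------------------------------------------------------------------

@dataclass
class LLRCurve:
    """Natural-log likelihood ratio of pathogenicity over a score grid."""

    grid: np.ndarray
    llr: np.ndarray
    density_pathogenic: np.ndarray
    density_benign: np.ndarray
    bandwidth: float
    trim: tuple[float, float]

    def __call__(self, scores) -> np.ndarray:
        """LLR at arbitrary scores by linear interpolation on the grid."""
        return np.interp(np.asarray(scores, dtype=float), self.grid, self.llr)

    def odds(self, scores) -> np.ndarray:
        return np.exp(self(scores))


def _gaussian_kde_fixed_bw(
    samples: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Gaussian KDE with an absolute (not data-scaled) bandwidth."""
    z = (grid[:, None] - samples[None, :]) / bandwidth
    return norm.pdf(z).sum(axis=1) / (len(samples) * bandwidth)


def llr_kernel(
    scores: pd.DataFrame,
    truth: pd.DataFrame,
    bandwidth: float = C.LLR_BANDWIDTH,
    trim: tuple[float, float] = C.LLR_TRIM_RANGE,
    grid_step: float = C.LLR_GRID_STEP,
    density_floor: float = C.LLR_DENSITY_FLOOR,
    min_per_label: int = 5,
    score_col: str = "score",
) -> LLRCurve:
    """Continuous evidence curve from kernel density estimates.

    Scores of truth-set variants are trimmed to ``trim``; Gaussian kernels
    of fixed ``bandwidth`` estimate the pathogenic and benign score
    densities on a regular grid over the trimmed range, and their floored
    log ratio is the evidence curve.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    merged = scores.merge(truth, on="variant", how="inner")
    lo, hi = trim
    merged = merged[(merged[score_col] >= lo) & (merged[score_col] <= hi)]
    sp = merged.loc[merged["label"] == P_LP, score_col].to_numpy(dtype=float)
    sb = merged.loc[merged["label"] == B_LB, score_col].to_numpy(dtype=float)
    if len(sp) < min_per_label or len(sb) < min_per_label:
        raise ValueError(
            f"need >= {min_per_label} variants per label after trimming "
            f"(got {len(sp)} pathogenic, {len(sb)} benign)"
        )
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    fp = np.maximum(_gaussian_kde_fixed_bw(sp, grid, bandwidth), density_floor)
    fb = np.maximum(_gaussian_kde_fixed_bw(sb, grid, bandwidth), density_floor)
    return LLRCurve(
        grid=grid,
        llr=np.log(fp) - np.log(fb),
        density_pathogenic=fp,
        density_benign=fb,
        bandwidth=bandwidth,
        trim=trim,
    )


# ---------------------------------------------------------------------------
# Evidence strengths
# ---------------------------------------------------------------------------

EVIDENCE_LEVELS = (
    "PS3_strong",
    "PS3_moderate",
    "PS3_supporting",
    "none",
    "BS3_supporting",
    "BS3_moderate",
)


def evidence_from_odds(
    odds,
    strong: float = C.ODDS_STRONG,
    moderate: float = C.ODDS_MODERATE,
    supporting: float = C.ODDS_SUPPORTING,
    cap_benign_at_moderate: bool = True,
) -> np.ndarray:
    """Map odds of pathogenicity to ACMG evidence strength labels.

    Pathogenic thresholds 18.7 / 4.33 / 2.08 (strong / moderate /
    supporting); benign evidence at the reciprocal thresholds, capped at
    moderate (no stand-alone/strong benign from a single assay).
    """
    odds = np.asarray(odds, dtype=float)
    conditions = [
        odds >= strong,
        odds >= moderate,
        odds >= supporting,
        odds <= 1.0 / moderate,
        odds <= 1.0 / supporting,
    ]
    choices = [
        "PS3_strong",
        "PS3_moderate",
        "PS3_supporting",
        "BS3_moderate" if cap_benign_at_moderate else "BS3_strong",
        "BS3_supporting",
    ]
    return np.select(conditions, choices, default="none")


def assign_evidence(
    curve: LLRCurve,
    scores: pd.DataFrame,
    score_col: str = "score",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-variant evidence labels from an LLR curve, plus category tallies.

    Scores outside the curve's trimmed range receive no evidence.
    """
    out = scores.copy()
    s = out[score_col].to_numpy(dtype=float)
    odds = curve.odds(s)
    labels = evidence_from_odds(odds)
    lo, hi = curve.trim
    labels = np.where((s < lo) | (s > hi), "none", labels)
    out["odds_path"] = odds
    out["evidence"] = labels
    tallies = {
        level: int((labels == level).sum()) for level in EVIDENCE_LEVELS
    }
    return out, tallies
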