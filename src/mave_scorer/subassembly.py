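"""Barcode -> variant map construction from linking reads.

The subassembly stage turns raw barcode-bearing reads into a validated
barcode-to-variant map:

1. ``extract_barcodes`` pulls the fixed-length barcode out of each read
   using exact 5-6 nt flanking anchors.
2. ``threshold_barcodes`` separates genuine barcodes from sequencing-error
   artifacts at the trough of the bimodal log-frequency histogram.
3. ``collapse_barcodes`` removes the lower-frequency member of any barcode
   pair within Hamming distance 2 (substitution errors of a real barcode).
4. ``call_consensus`` computes a per-position majority consensus of the
   reads attached to each barcode, compares it codon-wise to the reference
   coding sequence, and accepts barcodes whose consensus carries exactly one
   codon change (missense, nonsense, or synonymous).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import Read, translate_codon
from .variants import Variant

__all__ = [
    "DropLog",
    "extract_barcodes",
    "group_reads_by_barcode",
    "threshold_barcodes",
    "collapse_barcodes",
    "call_consensus",
    "accepted_map",
    "STATUS_ACCEPTED",
    "STATUS_WT",
    "STATUS_MULTI",
    "STATUS_AMBIGUOUS",
]

STATUS_ACCEPTED = "accepted"
STATUS_WT = "rejected_wt"
STATUS_MULTI = "rejected_multi"
STATUS_AMBIGUOUS = "rejected_ambiguous"


@dataclass
class DropLog:
    """Bookkeeping for reads and barcodes removed along the way."""

    reads_total: int = 0
    reads_missing_flank: int = 0
    barcodes_below_threshold: int = 0
    barcodes_collapsed: int = 0
    barcodes_multi_zone: int = 0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "reads_total": self.reads_total,
            "reads_missing_flank": self.reads_missing_flank,
            "barcodes_below_threshold": self.barcodes_below_threshold,
            "barcodes_collapsed": self.barcodes_collapsed,
            "barcodes_multi_zone": self.barcodes_multi_zone,
        }
        d.update(self.extra)
        return d


def _check_flanks(prefix: str, suffix: str) -> None:
    for name, flank in (("prefix", prefix), ("suffix", suffix)):
        if not 5 <= len(flank) <= 6:
            raise ValueError(f"{name} must be 5-6 nt, got {len(flank)}")


def extract_barcodes(
    reads: Iterable[Read | str],
    prefix: str,
    suffix: str,
    barcode_length: int = 18,
    log: DropLog | None = None,
) -> pd.Series:
    """Count barcodes delimited by exact prefix/suffix matches.

    Reads whose flanks do not match exactly at the expected positions are
    dropped and tallied in ``log``.  Returns counts indexed by barcode,
    sorted by descending count then barcode.
    """
    _check_flanks(prefix, suffix)
    log = log if log is not None else DropLog()
    p, b = len(prefix), barcode_length
    counts: dict[str, int] = defaultdict(int)
    for read in reads:
        seq = read.sequence if isinstance(read, Read) else read
        log.reads_total += 1
        if seq[:p] == prefix and seq[p + b : p + b + len(suffix)] == suffix:
            counts[seq[p : p + b]] += 1
        else:
            log.reads_missing_flank += 1
    ser = pd.Series(counts, dtype=int, name="count")
    ser.index.name = "barcode"
    return ser.sort_values(ascending=False).sort_index(kind="stable").sort_values(
        ascending=False, kind="stable"
    )


def group_reads_by_barcode(
    reads: Iterable[Read | str],
    prefix: str,
    suffix: str,
    barcode_length: int = 18,
    keep: Iterable[str] | None = None,
) -> dict[str, list[str]]:
    """Group the insert (sequence after the suffix) of each read by barcode.

    ``keep`` restricts grouping to a whitelist of barcodes (e.g. the
    thresholded, collapsed set).
    """
    _check_flanks(prefix, suffix)
    p, b, s = len(prefix), barcode_length, len(suffix)
    keep_set = set(keep) if keep is not None else None
    groups: dict[str, list[str]] = defaultdict(list)
    for read in reads:
        seq = read.sequence if isinstance(read, Read) else read
        if seq[:p] != prefix or seq[p + b : p + b + s] != suffix:
            continue
        bc = seq[p : p + b]
        if keep_set is None or bc in keep_set:
            groups[bc].append(seq[p + b + s :])
    return dict(groups)


def threshold_barcodes(
    counts: pd.Series,
    n_bins: int = 25,
    smooth_window: int = 3,
    fallback_threshold: int = 2,
    log: DropLog | None = None,
) -> tuple[pd.Series, float]:
    """Split the bimodal barcode-frequency distribution at its trough.

    Builds a histogram of log10(count), smooths it with a moving average,
    locates the two largest local maxima, and thresholds at the deepest
    minimum between them.  A unimodal histogram falls back to
    ``fallback_threshold``.

    Returns (surviving counts, threshold on the count scale).
    """
    if counts.empty:
        return counts, float(fallback_threshold)
    if counts.nunique() < 2:
        kept = counts[counts >= fallback_threshold]
        if log is not None:
            log.barcodes_below_threshold += len(counts) - len(kept)
        return kept, float(fallback_threshold)

    logc = np.log10(counts.to_numpy(dtype=float))
    hist, edges = np.histogram(logc, bins=n_bins)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smooth = np.convolve(hist, kernel, mode="same")
    else:
        smooth = hist.astype(float)

    # local maxima (plateau-tolerant at the ends)
    peaks = [
        i
        for i in range(len(smooth))
        if (i == 0 or smooth[i] > smooth[i - 1])
        and (i == len(smooth) - 1 or smooth[i] >= smooth[i + 1])
    ]
    if len(peaks) < 2:
        threshold = float(fallback_threshold)
    else:
        top_two = sorted(sorted(peaks, key=lambda i: smooth[i])[-2:])
        lo, hi = top_two
        trough = lo + int(np.argmin(smooth[lo : hi + 1]))
        threshold = float(10 ** edges[trough + 1])  # right edge of trough bin

    kept = counts[counts >= threshold]
    if log is not None:
        log.barcodes_below_threshold += len(counts) - len(kept)
    return kept, threshold


def _hamming_leq(a: str, b: str, k: int) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > k:
                return False
    return True


def collapse_barcodes(
    counts: pd.Series,
    max_distance: int = 2,
    log: DropLog | None = None,
) -> pd.Series:
    """Greedy error-collapse: drop the lower-count member of close pairs.

    Barcodes are processed in descending count order (count ties broken by
    keeping the lexicographically smaller barcode); a barcode within
    ``max_distance`` substitutions of an already-kept barcode is removed.
    Idempotent: the surviving set contains no pair within the distance in
    the removed-versus-kept direction.
    """
    if counts.empty:
        return counts
    lengths = {len(b) for b in counts.index}
    if len(lengths) != 1:
        raise ValueError("barcodes must be equal length")
    (length,) = lengths

    order = sorted(counts.index, key=lambda b: (-counts[b], b))
    # Pigeonhole index: two barcodes within Hamming distance <= max_distance
    # share at least one of (max_distance + 1) equal-size segments exactly.
    n_seg = max_distance + 1
    cuts = np.linspace(0, length, n_seg + 1, dtype=int)
    seg_index: list[dict[str, list[str]]] = [defaultdict(list) for _ in range(n_seg)]

    kept: list[str] = []
    for bc in order:
        candidates: set[str] = set()
        for s in range(n_seg):
            candidates.update(seg_index[s].get(bc[cuts[s] : cuts[s + 1]], ()))
        if any(_hamming_leq(bc, other, max_distance) for other in candidates):
            if log is not None:
                log.barcodes_collapsed += 1
            continue
        kept.append(bc)
        for s in range(n_seg):
            seg_index[s][bc[cuts[s] : cuts[s + 1]]].append(bc)
    return counts.loc[kept]


def _consensus_insert(
    inserts: Sequence[str], majority_frac: float
) -> str | None:
    """Per-position majority consensus; None when any position is ambiguous."""
    arr = np.frombuffer("".join(inserts).encode("ascii"), dtype=np.uint8).reshape(
        len(inserts), -1
    )
    n = arr.shape[0]
    consensus = np.empty(arr.shape[1], dtype=np.uint8)
    for j in range(arr.shape[1]):
        vals, cnts = np.unique(arr[:, j], return_counts=True)
        k = int(np.argmax(cnts))
        if cnts[k] / n < majority_frac:
            return None
        consensus[j] = vals[k]
    return consensus.tobytes().decode("ascii")


def call_consensus(
    reads_by_barcode: Mapping[str, Sequence[str]],
    reference_cds: str,
    min_coverage: int = 3,
    majority_frac: float = 0.6,
    zones: Mapping[str, Iterable] | None = None,
    log: DropLog | None = None,
) -> pd.DataFrame:
    """Call one consensus variant per barcode against the reference CDS.

    Inserts are positionally aligned fixed-length amplicons (reads of a
    length different from the reference are ambiguous).  The consensus is
    compared codon by codon: zero differing codons -> ``rejected_wt``; more
    than one -> ``rejected_multi``; coverage below ``min_coverage`` or an
    ambiguous majority -> ``rejected_ambiguous``.  A barcode observed in
    more than one library zone is dropped entirely.

    Returns the barcode map: columns ``barcode``, ``variant`` (one-letter
    HGVS-like string or empty), ``support`` (read count), ``status``.
    """
    if len(reference_cds) % 3:
        raise ValueError("reference CDS length must be a multiple of 3")
    rows = []
    for bc in sorted(reads_by_barcode):
        inserts = reads_by_barcode[bc]
        support = len(inserts)
        if zones is not None and len(set(zones.get(bc, ()))) > 1:
            if log is not None:
                log.barcodes_multi_zone += 1
            continue
        status, variant = STATUS_AMBIGUOUS, ""
        usable = [s for s in inserts if len(s) == len(reference_cds)]
        if len(usable) >= min_coverage:
            consensus = _consensus_insert(usable, majority_frac)
            if consensus is not None:
                status, variant = _classify_consensus(consensus, reference_cds)
        rows.append(
            {"barcode": bc, "variant": variant, "support": support, "status": status}
        )
    return pd.DataFrame(rows, columns=["barcode", "variant", "support", "status"])


def _classify_consensus(consensus: str, reference_cds: str) -> tuple[str, str]:
    diff_codons = [
        i
        for i in range(0, len(reference_cds), 3)
        if consensus[i : i + 3] != reference_cds[i : i + 3]
    ]
    if not diff_codons:
        return STATUS_WT, ""
    if len(diff_codons) > 1:
        return STATUS_MULTI, ""
    i = diff_codons[0]
    wt_aa = translate_codon(reference_cds[i : i + 3])
    alt_aa = translate_codon(consensus[i : i + 3])
    if wt_aa == "*":  # mutated stop codon: not a single-residue change
        return STATUS_AMBIGUOUS, ""
    alt = "=" if alt_aa == wt_aa else alt_aa
    var = Variant(position=i // 3 + 1, wt=wt_aa, alt=alt)
    return STATUS_ACCEPTED, var.hgvs_p


def accepted_map(barcode_map: pd.DataFrame) -> pd.DataFrame:
    """Accepted rows of a barcode map (barcode, variant, support)."""
    out = barcode_map.loc[
        barcode_map["status"] == STATUS_ACCEPTED, ["barcode", "variant", "support"]
    ]
    return out.reset_index(drop=True)
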