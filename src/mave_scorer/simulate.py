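"""Synthetic data generator for the four pooled variant-effect assays.

The generator produces every raw input the pipeline consumes, from the
ground truth down:

1. ``simulate_truth`` draws a library of single-codon variants, each with
   four latent effects (variant-only and heterozygous surface abundance and
   channel activity) determined by a functional archetype.
2. ``simulate_barcode_library`` tags each variant with ~19.5 random 18-nt
   barcodes of log-normally dispersed abundance.
3. ``simulate_subassembly_reads`` emits FASTQ-like reads linking each
   barcode to its variant's mutated coding sequence, with per-base
   substitution errors.
4. ``simulate_facs`` sorts cells into four fluorescence bins (population
   quartiles) and reports per-bin read counts; ``simulate_selection``
   propagates the pool through a 28-day drug selection in which channel
   activity is a fitness cost, so loss-of-function variants enrich and
   gain-of-function variants deplete.

All randomness flows from explicit seeds; identical configuration and seed
give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

from .variants import AA_ALPHABET, Variant

__all__ = [
    "SimConfig",
    "ARCHETYPE_LATENTS",
    "DEFAULT_ARCHETYPE_PROPORTIONS",
    "simulate_truth",
    "simulate_barcode_library",
    "simulate_subassembly_reads",
    "simulate_facs",
    "simulate_selection",
    "simulate_counts",
    "reference_protein",
    "reference_cds",
    "variant_cds",
    "write_fastq",
    "Read",
]

# Standard genetic code, grouped by amino acid (stop codons under "*").
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TABLE.items()):
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)

#: Amino acids encoded by a single codon; synonymous changes are impossible.
SINGLE_CODON_AAS = frozenset(aa for aa, cs in CODONS_BY_AA.items() if len(cs) == 1)


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon.upper()]


# ---------------------------------------------------------------------------
# Archetypes
# ---------------------------------------------------------------------------
# Latent effect means on the normalized score scale:
# (abundance, function, het_abundance, het_function), where 1 = wild-type
# behaviour and 0 = the assay's null anchor (nonsense median, or zero signal
# for heterozygous abundance).  Heterozygous function may go below 0: a
# dominant-negative subunit leaves the cell with less current than losing the
# variant allele outright.
ARCHETYPE_LATENTS: dict[str, tuple[float, float, float, float]] = {
    "synonymous-like": (1.00, 1.00, 1.00, 1.00),
    "early-nonsense": (0.03, 0.02, 1.00, 0.00),
    "late-nonsense-GOF": (1.35, 1.25, 1.00, 1.15),
    "missense-LOF": (0.35, 0.08, 0.95, 0.15),
    "missense-partial": (0.70, 0.55, 1.00, 0.70),
    "missense-GOF": (1.10, 1.35, 1.00, 1.20),
    "dominant-negative": (0.05, 0.03, 0.08, -0.05),
    "haploinsufficient": (0.06, 0.04, 1.00, 0.02),
}

# Library composition: roughly the observed class proportions of the real
# variant map (~11% complete loss, ~10% partial, ~3% gain, ~7% dominant
# negative, ~4.5% nonsense), with the remainder behaving like wild type.
DEFAULT_ARCHETYPE_PROPORTIONS: dict[str, float] = {
    "synonymous-like": 0.572,
    "early-nonsense": 0.045,
    "late-nonsense-GOF": 0.005,
    "missense-LOF": 0.110,
    "missense-partial": 0.100,
    "missense-GOF": 0.028,
    "dominant-negative": 0.070,
    "haploinsufficient": 0.070,
}


class Read(NamedTuple):
    """A minimal FASTQ record (fixed quality)."""

    name: str
    sequence: str


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated experiment.

    Defaults correspond to a desk-scale version of the real screen: 2,000
    variants (vs ~14,000), a mean of 19.5 barcodes per variant, four
    quartile FACS bins, a 28-day selection sampled weekly, and three
    replicates.  ``reads_per_sample`` is scaled down from the >=25 M reads
    per sequencing sample of the full experiment in proportion to library
    size, keeping per-variant depth comparable.
    """

    n_variants: int = 2000
    barcodes_per_variant_mean: float = 19.5
    reads_per_barcode_mean: float = 20.0
    barcode_length: int = 18
    seq_error_rate: float = 0.005
    n_bins: int = 4
    n_cells: int = 2_000_000
    reads_per_sample: int = 5_000_000
    selection_strength: float = 0.063  # fitness cost / day / unit activity
    timepoints: tuple[int, ...] = (0, 7, 14, 21, 28)
    n_replicates: int = 3
    seed: int = 0

    # Noise model
    sigma_cell: float = 0.6        # sd of log fluorescence across cells
    fluor_floor: float = 0.02      # background staining (relative to WT)
    replicate_noise_sd: float = 0.04  # per-replicate latent jitter
    latent_sd: float = 0.05        # within-archetype spread of latent effects
    barcode_weight_sigma: float = 0.5  # log-normal dispersion of barcode abundance

    # Library identity
    protein_length: int = 676
    synonymous_fraction: float = 0.10  # of synonymous-like variants
    archetype_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_PROPORTIONS)
    )
    flank_prefix: str = "ACTGG"
    flank_suffix: str = "CAGTC"

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        for name in (
            "barcodes_per_variant_mean",
            "reads_per_barcode_mean",
            "sigma_cell",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        tp = tuple(self.timepoints)
        if tp[0] != 0 or list(tp) != sorted(tp):
            raise ValueError("timepoints must be sorted ascending and start at 0")
        if not 0 <= self.seq_error_rate < 1:
            raise ValueError("seq_error_rate must be in [0, 1)")
        total = sum(self.archetype_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"archetype proportions sum to {total}, expected 1")
        unknown = set(self.archetype_proportions) - set(ARCHETYPE_LATENTS)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def reference_protein(length: int = 676, seed: int = 20_260_101) -> str:
    """Deterministic synthetic wild-type protein (Met start)."""
    rng = np.random.default_rng(seed)
    aas = rng.choice(list(AA_ALPHABET), size=length)
    aas[0] = "M"
    return "".join(aas)


@lru_cache(maxsize=8)
def reference_cds(length: int = 676, seed: int = 20_260_101) -> str:
    """Coding sequence for :func:`reference_protein` (deterministic codons)."""
    protein = reference_protein(length, seed)
    rng = np.random.default_rng(seed + 1)
    codons = [
        CODONS_BY_AA[aa][rng.integers(len(CODONS_BY_AA[aa]))] for aa in protein
    ]
    return "".join(codons)


def variant_cds(ref_cds: str, variant: Variant) -> str:
    """Reference CDS with the variant's codon substituted.

    Missense/nonsense changes use the first codon of the target residue;
    synonymous changes use the first alternative codon of the wild-type
    residue (single-codon residues cannot host a synonymous change).
    """
    i = (variant.position - 1) * 3
    wt_codon = ref_cds[i : i + 3]
    if translate_codon(wt_codon) != variant.wt:
        raise ValueError(
            f"reference codon {wt_codon} at position {variant.position} encodes "
            f"{translate_codon(wt_codon)}, not {variant.wt}"
        )
    if variant.alt == "=":
        options = [c for c in CODONS_BY_AA[variant.wt] if c != wt_codon]
        if not options:
            raise ValueError(f"{variant.hgvs_p}: no synonymous codon exists")
        new = options[0]
    else:
        new = CODONS_BY_AA[variant.alt][0]
    return ref_cds[:i] + new + ref_cds[i + 3 :]


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

def simulate_truth(config: SimConfig) -> pd.DataFrame:
    """Draw the ground-truth variant library.

    Returns a DataFrame with one row per variant: identity (``variant``,
    ``position``, ``wt_aa``, ``alt_aa``, ``consequence``), ``archetype``,
    and the four latent effects ``latent_abundance``, ``latent_function``,
    ``het_abundance``, ``het_function``.
    """
    rng = np.random.default_rng(config.seed)
    protein = reference_protein(config.protein_length)
    names = sorted(config.archetype_proportions)
    probs = np.array([config.archetype_proportions[n] for n in names])
    arch_idx = rng.choice(len(names), size=config.n_variants, p=probs)

    early_hi = min(670, config.protein_length - 6)  # early-truncation range
    rows: list[dict] = []
    seen: set[str] = set()
    for ai in arch_idx:
        arch = names[ai]
        for _ in range(1000):
            if arch == "early-nonsense":
                pos = int(rng.integers(2, min(610, early_hi) + 1))
                alt = "*"
            elif arch == "late-nonsense-GOF":
                lo = min(611, config.protein_length)
                pos = int(rng.integers(lo, config.protein_length + 1))
                alt = "*"
            else:
                pos = int(rng.integers(2, config.protein_length + 1))
                if (
                    arch == "synonymous-like"
                    and rng.random() < config.synonymous_fraction
                    and protein[pos - 1] not in SINGLE_CODON_AAS
                ):
                    alt = "="
                else:
                    alt = protein[pos - 1]
                    while alt == protein[pos - 1] or alt in "*=":
                        alt = AA_ALPHABET[rng.integers(len(AA_ALPHABET))]
            var = Variant(position=pos, wt=protein[pos - 1], alt=alt)
            if var.hgvs_p not in seen:
                seen.add(var.hgvs_p)
                break
        else:  # pragma: no cover - only at saturating library sizes
            raise RuntimeError("could not draw a unique variant; library saturated")
        means = np.array(ARCHETYPE_LATENTS[arch])
        latents = means + rng.normal(0.0, config.latent_sd, size=4)
        # Only heterozygous function can meaningfully dip below zero.
        latents[:3] = np.clip(latents[:3], 0.0, None)
        rows.append(
            {
                "variant": var.hgvs_p,
                "position": var.position,
                "wt_aa": var.wt,
                "alt_aa": var.alt,
                "consequence": var.consequence,
                "archetype": arch,
                "latent_abundance": latents[0],
                "latent_function": latents[1],
                "het_abundance": latents[2],
                "het_function": latents[3],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Barcode library
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    arr = _BASES[rng.integers(0, 4, size=(n, length))]
    codes = [row.tobytes().decode("ascii") for row in arr]
    # Collisions are vanishingly rare at 18 nt but must not silently merge
    # two variants; redraw duplicates.
    while len(set(codes)) < n:
        seen: set[str] = set()
        for i, c in enumerate(codes):
            if c in seen:
                codes[i] = (
                    _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
                )
            seen.add(codes[i])
    return codes


def simulate_barcode_library(
    truth: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Tag each variant with Poisson(~19.5) random barcodes.

    Returns columns ``barcode``, ``variant``, ``weight`` — the weight is the
    barcode's relative cell/plasmid abundance (log-normal, normalized to sum
    to 1 over the library).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n_bc = rng.poisson(config.barcodes_per_variant_mean, size=len(truth))
    n_bc = np.maximum(n_bc, 1)
    total = int(n_bc.sum())
    barcodes = _random_barcodes(rng, total, config.barcode_length)
    weights = rng.lognormal(0.0, config.barcode_weight_sigma, size=total)
    weights /= weights.sum()
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "variant": np.repeat(truth["variant"].to_numpy(), n_bc),
            "weight": weights,
        }
    )


# ---------------------------------------------------------------------------
# Subassembly reads
# ---------------------------------------------------------------------------

_BASE_INDEX = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _apply_errors(
    reads: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute bases in-place at the given per-base rate."""
    if rate <= 0:
        return reads
    mask = rng.random(reads.shape) < rate
    if mask.any():
        idx = _BASE_INDEX[reads[mask]]
        shift = rng.integers(1, 4, size=idx.shape)
        reads[mask] = _BASES[(idx + shift) % 4]
    return reads


def simulate_subassembly_reads(
    truth: pd.DataFrame,
    config: SimConfig,
    barcodes: pd.DataFrame,
    seed: int | None = None,
) -> list[Read]:
    """Emit barcode-linking reads: ``prefix + barcode + suffix + variant CDS``.

    Per-barcode read depth is log-normal around ``reads_per_barcode_mean``;
    every base (flanks, barcode, and insert) is substituted independently at
    ``seq_error_rate``, so low-frequency spurious barcodes arise exactly as
    sequencing errors of genuine ones.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    ref = reference_cds(config.protein_length)
    cds_by_variant = {
        v.hgvs_p: variant_cds(ref, v)
        for v in (Variant.parse(s) for s in truth["variant"])
    }
    m = config.reads_per_barcode_mean
    lam = rng.lognormal(np.log(m) - 0.125, 0.5, size=len(barcodes))
    n_reads = np.maximum(rng.poisson(lam), 1)

    templates = np.empty(
        (len(barcodes), len(config.flank_prefix) + config.barcode_length
         + len(config.flank_suffix) + len(ref)),
        dtype=np.uint8,
    )
    for i, (bc, var) in enumerate(zip(barcodes["barcode"], barcodes["variant"])):
        seq = config.flank_prefix + bc + config.flank_suffix + cds_by_variant[var]
        templates[i] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)

    reads_arr = np.repeat(templates, n_reads, axis=0)
    reads_arr = _apply_errors(reads_arr, config.seq_error_rate, rng)
    order = rng.permutation(len(reads_arr))
    return [
        Read(f"read_{i}", reads_arr[j].tobytes().decode("ascii"))
        for i, j in enumerate(order)
    ]


def write_fastq(reads: Iterable[Read], path, quality_char: str = "I") -> None:
    """Write reads as FASTQ with a fixed phred-33 quality."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# Sorting and selection
# ---------------------------------------------------------------------------

def _entity_layout(
    truth: pd.DataFrame,
    barcodes: pd.DataFrame | None,
    rng: np.random.Generator,
    weight_sigma: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Entity ids, per-entity truth row indices, and library weights."""
    if barcodes is None:
        ids = truth["variant"].to_numpy()
        tidx = np.arange(len(truth))
        w = rng.lognormal(0.0, weight_sigma, size=len(truth))
    else:
        ids = barcodes["barcode"].to_numpy()
        row_of = pd.Series(np.arange(len(truth)), index=truth["variant"])
        tidx = row_of[barcodes["variant"]].to_numpy()
        w = barcodes["weight"].to_numpy().astype(float).copy()
    return ids, tidx, w / w.sum()


def _population_quantiles(
    mu: np.ndarray, sigma: float, w: np.ndarray, qs: Sequence[float]
) -> list[float]:
    """Quantiles of a weighted log-normal mixture (fluorescence boundaries)."""
    lo, hi = mu.min() - 10 * sigma, mu.max() + 10 * sigma

    def cdf(x: float) -> float:
        return float(w @ ndtr((x - mu) / sigma))

    return [brentq(lambda x, q=q: cdf(x) - q, lo, hi, xtol=1e-10) for q in qs]


def simulate_facs(
    truth: pd.DataFrame,
    config: SimConfig,
    replicate_seed: int,
    assay: str = "abundance",
    barcodes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One replicate of the four-bin sort; returns RPM per entity per bin.

    Cell fluorescence is log-normal around the entity's latent surface
    abundance (floored at background staining); bin boundaries are the
    population quartiles, so each bin captures ~25% of sorted cells.  Read
    counts are Poisson around the sorted cell counts at the configured
    sequencing depth, reported as reads per million within each bin sample.
    """
    if assay not in ("abundance", "het_abundance"):
        raise ValueError(f"unknown FACS assay {assay!r}")
    col = "latent_abundance" if assay == "abundance" else "het_abundance"
    rng = np.random.default_rng(replicate_seed)

    ids, tidx, w = _entity_layout(truth, barcodes, rng, config.barcode_weight_sigma)
    latent = truth[col].to_numpy()[tidx]
    latent = latent + rng.normal(0.0, config.replicate_noise_sd, size=latent.size)
    mu = np.log(np.clip(latent, config.fluor_floor, None))

    qs = [(k + 1) / config.n_bins for k in range(config.n_bins - 1)]
    bounds = _population_quantiles(mu, config.sigma_cell, w, qs)
    edges = np.array([-np.inf, *bounds, np.inf])
    # per-entity probability of landing in each bin
    z = (edges[None, :] - mu[:, None]) / config.sigma_cell
    probs = np.diff(ndtr(z), axis=1)
    probs /= probs.sum(axis=1, keepdims=True)

    cells = rng.multinomial(config.n_cells, w)
    bin_cells = rng.multinomial(cells, probs)
    col_totals = bin_cells.sum(axis=0)
    col_totals = np.where(col_totals == 0, 1, col_totals)
    reads = rng.poisson(config.reads_per_sample * bin_cells / col_totals)
    read_totals = reads.sum(axis=0)
    read_totals = np.where(read_totals == 0, 1, read_totals)
    rpm = 1e6 * reads / read_totals

    frames = []
    for k in range(config.n_bins):
        frames.append(
            pd.DataFrame({"entity_id": ids, "sample": f"bin{k + 1}", "rpm": rpm[:, k]})
        )
    return pd.concat(frames, ignore_index=True)


def _activity(truth: pd.DataFrame, assay: str) -> np.ndarray:
    """Channel activity per variant driving the fitness cost.

    Variant-only pools: activity is the latent channel function directly.
    Heterozygous pools carry one wild-type allele, so a null variant still
    leaves half the current: activity = 0.5 + 0.5 * het score (a
    dominant-negative score below 0 drags activity under one half).
    """
    if assay == "function":
        a = truth["latent_function"].to_numpy()
    elif assay == "het_function":
        a = 0.5 + 0.5 * truth["het_function"].to_numpy()
    else:
        raise ValueError(f"unknown selection assay {assay!r}")
    return np.clip(a, 0.0, None)


def simulate_selection(
    truth: pd.DataFrame,
    config: SimConfig,
    replicate_seed: int,
    assay: str = "function",
    barcodes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One replicate of the drug-selection timecourse; RPM per timepoint.

    Growth rate decreases linearly with channel activity (exponential
    depletion at ``selection_strength`` per day per unit activity), so
    wild-type-like variants deplete and loss-of-function variants enrich in
    relative frequency.  Counts are Poisson at the configured depth.
    """
    rng = np.random.default_rng(replicate_seed)
    ids, tidx, w0 = _entity_layout(truth, barcodes, rng, config.barcode_weight_sigma)
    act = _activity(truth, assay)[tidx]
    act = act + rng.normal(0.0, config.replicate_noise_sd, size=act.size)
    act = np.clip(act, 0.0, None)

    frames = []
    for day in config.timepoints:
        f = w0 * np.exp(-config.selection_strength * act * day)
        f = f / f.sum()
        reads = rng.poisson(config.reads_per_sample * f)
        total = reads.sum() or 1
        frames.append(
            pd.DataFrame(
                {"entity_id": ids, "sample": f"day{day}", "rpm": 1e6 * reads / total}
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_counts(
    truth: pd.DataFrame,
    config: SimConfig,
    assay: str,
    barcodes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All replicates of one assay, with a ``replicate`` column (1-based)."""
    sims = {
        "abundance": simulate_facs,
        "het_abundance": simulate_facs,
        "function": simulate_selection,
        "het_function": simulate_selection,
    }
    if assay not in sims:
        raise ValueError(f"unknown assay {assay!r}")
    base = np.random.SeedSequence([config.seed, _assay_tag(assay)])
    frames = []
    for rep, ss in enumerate(base.spawn(config.n_replicates), start=1):
        rep_seed = int(ss.generate_state(1)[0])
        df = sims[assay](truth, config, rep_seed, assay=assay, barcodes=barcodes)
        df["replicate"] = rep
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _assay_tag(assay: str) -> int:
    return {"abundance": 1, "function": 2, "het_abundance": 3, "het_function": 4}[
        assay
    ]
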