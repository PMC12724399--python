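"""End-to-end orchestration: simulate -> subassemble -> score -> integrate
-> calibrate, with a reproducible manifest.

Each stage writes plain TSV/JSON artifacts into the run directory and the
manifest records paths, SHA-256 checksums, and the full parameter echo, so
a run can be reproduced or resumed from intermediate files.  Stages can be
toggled off; the subassembly stage runs on simulated linking reads when
read simulation is enabled and otherwise falls back to the simulator's
ground-truth barcode library (recorded in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .calibrate import (
    assign_evidence,
    llr_kernel,
    oddspath_binary,
    roc_auc,
)
from .integrate import assemble_matrix, call_dominant_negative, pca_kmeans
from .scoring import score_assay
from .simulate import (
    SimConfig,
    simulate_barcode_library,
    simulate_counts,
    simulate_subassembly_reads,
    simulate_truth,
    reference_cds,
    write_fastq,
)
from .subassembly import (
    DropLog,
    accepted_map,
    call_consensus,
    collapse_barcodes,
    extract_barcodes,
    group_reads_by_barcode,
    threshold_barcodes,
)

logger = logging.getLogger("mave_scorer")

__all__ = ["RunConfig", "run_pipeline", "build_synthetic_truth_labels"]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    simulate_reads: bool = False      # read-level subassembly is the slow path
    run_subassembly: bool = True
    run_scoring: bool = True
    run_integration: bool = True
    run_calibration: bool = True
    kmeans_k: int = 6
    kmeans_n_init: int = 50
    truth_labels_per_class: int = 60  # synthetic control variants per label

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = SimConfig(**data.pop("sim", {}))
        return cls(sim=sim, **data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["archetype_proportions"] = dict(self.sim.archetype_proportions)
        d["sim"]["timepoints"] = list(self.sim.timepoints)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def build_synthetic_truth_labels(
    truth: pd.DataFrame, n_per_class: int, seed: int
) -> pd.DataFrame:
    """Benign/pathogenic control labels drawn from simulation archetypes.

    Pathogenic controls are sampled from the clearly deleterious missense
    archetypes (dominant-negative, haploinsufficient, complete loss);
    benign controls from wild-type-like missense variants — mimicking how
    clinical truth sets pair known disease variants with frequency-based
    benign controls.
    """
    rng = np.random.default_rng(seed)
    miss = truth[truth["consequence"] == "missense"]
    path_pool = miss[
        miss["archetype"].isin(
            ["dominant-negative", "haploinsufficient", "missense-LOF"]
        )
    ]["variant"].to_numpy()
    benign_pool = miss[miss["archetype"] == "synonymous-like"]["variant"].to_numpy()
    n_p = min(n_per_class, len(path_pool))
    n_b = min(n_per_class, len(benign_pool))
    rows = [
        *(
            {"variant": v, "label": "P_LP", "source": "clinvar"}
            for v in rng.choice(path_pool, size=n_p, replace=False)
        ),
        *(
            {"variant": v, "label": "B_LB", "source": "clinvar"}
            for v in rng.choice(benign_pool, size=n_b, replace=False)
        ),
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stages": {},
        "files": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    # --- simulate ---------------------------------------------------------
    logger.info("simulating truth and counts (n=%d)", config.sim.n_variants)
    truth = simulate_truth(config.sim)
    barcodes = simulate_barcode_library(truth, config.sim)
    record("truth", _write_tsv(truth, outdir / "truth.tsv"))
    record("barcode_library", _write_tsv(barcodes, outdir / "barcode_library.tsv"))
    counts = {}
    for assay in C.ASSAYS:
        counts[assay] = simulate_counts(truth, config.sim, assay, barcodes=barcodes)
        record(f"counts_{assay}", _write_tsv(counts[assay], outdir / f"counts_{assay}.tsv"))
    manifest["stages"]["simulate"] = {"status": "completed", "seed": config.sim.seed}

    # --- subassembly ------------------------------------------------------
    if config.run_subassembly and config.simulate_reads:
        log = DropLog()
        reads = simulate_subassembly_reads(truth, config.sim, barcodes)
        fastq = outdir / "subassembly_reads.fastq"
        write_fastq(reads, fastq)
        record("subassembly_reads", fastq)
        bc_counts = extract_barcodes(
            reads, config.sim.flank_prefix, config.sim.flank_suffix,
            config.sim.barcode_length, log=log,
        )
        bc_counts, threshold = threshold_barcodes(bc_counts, log=log)
        bc_counts = collapse_barcodes(bc_counts, log=log)
        groups = group_reads_by_barcode(
            reads, config.sim.flank_prefix, config.sim.flank_suffix,
            config.sim.barcode_length, keep=bc_counts.index,
        )
        bc_map_full = call_consensus(
            groups, reference_cds(config.sim.protein_length), log=log
        )
        barcode_map = accepted_map(bc_map_full)
        record("barcode_map", _write_tsv(bc_map_full, outdir / "barcode_map.tsv"))
        with open(outdir / "subassembly_droplog.json", "w") as fh:
            json.dump({**log.as_dict(), "threshold": threshold}, fh, indent=1)
        record("subassembly_droplog", outdir / "subassembly_droplog.json")
        manifest["stages"]["subassembly"] = {
            "status": "completed",
            "threshold": threshold,
            "accepted_barcodes": int(len(barcode_map)),
        }
    elif config.run_subassembly:
        # barcode map taken from the simulator's ground truth library
        barcode_map = barcodes.rename(columns={"weight": "support"})
        manifest["stages"]["subassembly"] = {
            "status": "completed",
            "source": "simulated_truth_library",
        }
    else:
        barcode_map = barcodes.rename(columns={"weight": "support"})
        manifest["stages"]["subassembly"] = {"status": "skipped"}

    if not config.run_scoring:
        manifest["stages"]["scoring"] = {"status": "skipped"}
        _finish(manifest, outdir)
        return manifest

    # --- scoring ----------------------------------------------------------
    scoresets = {}
    syn_bounds = {}
    for assay in C.ASSAYS:
        result = score_assay(counts[assay], assay, barcode_map=barcode_map)
        scoresets[assay] = result.scores
        syn_bounds[assay] = result.syn_bounds
        record(f"scores_{assay}", _write_tsv(result.scores, outdir / f"scores_{assay}.tsv"))
    manifest["stages"]["scoring"] = {
        "status": "completed",
        "synonymous_bounds": {a: list(b) for a, b in syn_bounds.items()},
    }

    # --- integration ------------------------------------------------------
    if config.run_integration:
        matrix = assemble_matrix(scoresets)
        dn = call_dominant_negative(matrix)
        record("assay_matrix", _write_tsv(matrix, outdir / "assay_matrix.tsv"))
        record("dn_calls", _write_tsv(
            dn[["variant", "n_assays_below_cutoff", "dn_label", "missing_data"]],
            outdir / "dn_calls.tsv",
        ))
        clusters = pca_kmeans(
            matrix, k=config.kmeans_k, seed=config.sim.seed,
            n_init=config.kmeans_n_init,
        )
        record("clusters", _write_tsv(clusters.assignments, outdir / "clusters.tsv"))
        manifest["stages"]["integration"] = {
            "status": "completed",
            "n_complete": int(matrix["complete"].sum()),
            "n_severe_dn": int((dn["dn_label"] == "severe_dn").sum()),
            "n_strong_dn": int((dn["dn_label"] == "strong_dn").sum()),
            "cluster_names": {
                int(k): v
                for k, v in clusters.assignments.groupby("cluster")["cluster_name"]
                .first()
                .items()
            },
        }
    else:
        manifest["stages"]["integration"] = {"status": "skipped"}

    # --- calibration ------------------------------------------------------
    if config.run_calibration:
        labels = build_synthetic_truth_labels(
            truth, config.truth_labels_per_class, seed=config.sim.seed + 7
        )
        record("truth_labels", _write_tsv(labels, outdir / "truth_labels.tsv"))
        fn_scores = scoresets["function"]
        auc, curve = roc_auc(fn_scores, labels)
        cutoff = syn_bounds["function"][0]
        odds = oddspath_binary(fn_scores, labels, cutoff=cutoff)
        llr = llr_kernel(fn_scores, labels)
        evidence, tallies = assign_evidence(llr, fn_scores)
        record("evidence", _write_tsv(
            evidence[["variant", "score", "odds_path", "evidence"]],
            outdir / "evidence.tsv",
        ))
        record("llr_curve", _write_tsv(
            pd.DataFrame({"score": llr.grid, "llr": llr.llr}),
            outdir / "llr_curve.tsv",
        ))
        calib = {
            "assay": "function",
            "roc_auc": auc,
            "cutoff": cutoff,
            "contingency": odds.contingency,
            "prior_p1": odds.prior_p1,
            "oddspath_pathogenic": odds.oddspath_pathogenic,
            "oddspath_benign": odds.oddspath_benign,
            "evidence_tallies": tallies,
        }
        with open(outdir / "calibration.json", "w") as fh:
            json.dump(calib, fh, indent=1)
        record("calibration", outdir / "calibration.json")
        manifest["stages"]["calibration"] = {"status": "completed", "roc_auc": auc}
    else:
        manifest["stages"]["calibration"] = {"status": "skipped"}

    _finish(manifest, outdir)
    return manifest


def _finish(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
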