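"""Four-assay integration: dominant-negative calls, clustering, classifiers.

A variant measured in all four assays (variant-only and heterozygous
abundance and function) gets a combined mechanistic readout.  A variant
scoring below the per-assay cutoff (0.25, 0.25, 0.25, and 0 for the
heterozygous function assay) in all four assays is a *severe* dominant
negative; below cutoff in exactly three of four, a *strong* dominant
negative.  The heterozygous cutoffs are the crux: a variant that drags the
wild-type allele's surface abundance and the cell's residual current down
is poisoning mixed tetramers, not merely losing its own function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler

from . import constants as C
from .calibrate import roc_auc_from_arrays
from .variants import MISSENSE

__all__ = [
    "assemble_matrix",
    "call_dominant_negative",
    "pca_kmeans",
    "name_clusters",
    "combine_classifiers",
]

SEVERE_DN = "severe_dn"
STRONG_DN = "strong_dn"
NO_DN = "none"


def assemble_matrix(scoresets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Outer-join the four score sets into a wide per-variant matrix.

    ``scoresets`` maps assay name -> score table (must contain ``variant``
    and ``score``).  Returns one row per variant with one score column per
    assay, variant annotation, and a ``complete`` flag.
    """
    unknown = set(scoresets) - set(C.ASSAYS)
    if unknown:
        raise ValueError(f"unknown assays: {sorted(unknown)}")
    pieces = []
    for assay in C.ASSAYS:
        if assay not in scoresets:
            continue
        df = scoresets[assay]
        if df["variant"].duplicated().any():
            dups = df.loc[df["variant"].duplicated(), "variant"].head().tolist()
            raise ValueError(f"duplicate variants in {assay} score set: {dups}")
        pieces.append(df.set_index("variant")["score"].rename(assay))
    wide = pd.concat(pieces, axis=1, join="outer")
    present = [a for a in C.ASSAYS if a in wide.columns]
    wide["complete"] = wide[present].notna().all(axis=1) & (len(present) == 4)
    out = wide.reset_index().rename(columns={"index": "variant"})
    from .scoring import annotate_variants

    return annotate_variants(out)


def call_dominant_negative(
    matrix: pd.DataFrame, cutoffs: dict[str, float] | None = None
) -> pd.DataFrame:
    """Label severe (4/4 assays reduced) and strong (3/4) dominant negatives.

    Applied to complete missense variants; incomplete rows are labelled
    ``none`` with ``missing_data=True``.  Row order does not matter and the
    call is idempotent.
    """
    cutoffs = cutoffs or C.DN_CUTOFFS
    out = matrix.copy()
    below = np.zeros(len(out), dtype=int)
    for assay, cut in cutoffs.items():
        below += (out[assay] < cut).fillna(False).to_numpy()
    eligible = out["complete"] & (out["consequence"] == MISSENSE)
    out["n_assays_below_cutoff"] = np.where(eligible, below, 0)
    out["missing_data"] = ~out["complete"]
    out["dn_label"] = np.select(
        [eligible & (below == 4), eligible & (below == 3)],
        [SEVERE_DN, STRONG_DN],
        default=NO_DN,
    )
    return out


# ---------------------------------------------------------------------------
# PCA + k-means
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    assignments: pd.DataFrame  # variant, cluster, cluster_name, PC1, PC2
    centroids: pd.DataFrame    # per-cluster mean score in each assay
    explained_variance: np.ndarray


def name_clusters(
    centroids: pd.DataFrame,
    syn_bounds: dict[str, tuple[float, float]] | tuple[float, float] = (0.6, 1.4),
    low_cutoff: float = C.LOSS_CUTOFF,
) -> dict[int, str]:
    """Name clusters from their centroid score profiles (pure function).

    Rules: all four assays low -> dominant negative; variant-only assays
    low with heterozygous assays normal -> haploinsufficient; function
    above the synonymous range -> gain-of-function; everything within the
    synonymous range -> normal (numbered when several clusters qualify);
    otherwise partial loss-of-function.  ``syn_bounds`` may be one
    (lower, upper) pair or a per-assay dict of pairs.
    """
    if isinstance(syn_bounds, dict):
        bounds = {a: syn_bounds[a] for a in C.ASSAYS}
    else:
        bounds = {a: syn_bounds for a in C.ASSAYS}
    names: dict[int, str] = {}
    for k, row in centroids.iterrows():
        low = {a: row[a] < low_cutoff for a in C.ASSAYS}
        normal = {a: bounds[a][0] <= row[a] <= bounds[a][1] for a in C.ASSAYS}
        if all(low.values()):
            name = "dominant negative"
        elif (
            low["abundance"]
            and low["function"]
            and not low["het_abundance"]
            and row["het_abundance"] >= bounds["het_abundance"][0]
        ):
            name = "haploinsufficient"
        elif row["function"] > bounds["function"][1]:
            name = "gain-of-function"
        elif all(normal.values()):
            name = "normal"
        else:
            name = "partial loss-of-function"
        names[k] = name
    # number duplicates deterministically by cluster id
    counts: dict[str, int] = {}
    for base in names.values():
        counts[base] = counts.get(base, 0) + 1
    seen: dict[str, int] = {}
    for k in sorted(names):
        base = names[k]
        if counts[base] > 1:
            seen[base] = seen.get(base, 0) + 1
            names[k] = f"{base} {seen[base]}"
    return names


def pca_kmeans(
    matrix: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    n_init: int = 50,
    syn_bounds: dict[str, tuple[float, float]] | tuple[float, float] | None = None,
) -> ClusterResult:
    """Standardize the four scores, project with PCA, cluster with k-means.

    Only complete rows enter.  All four principal components are retained
    for clustering; PC1/PC2 are reported for plotting.  Clusters are named
    automatically from their centroid profiles (see :func:`name_clusters`);
    when ``syn_bounds`` is None the per-assay normal range is taken from
    the 2.5th/97.5th percentiles of the matrix's own synonymous variants
    (falling back to (0.6, 1.4) if there are too few).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rows = matrix[matrix["complete"]].reset_index(drop=True)
    if syn_bounds is None:
        syn_rows = rows[rows["consequence"] == "synonymous"]
        if len(syn_rows) >= C.MIN_SYNONYMOUS_FOR_PERCENTILES:
            syn_bounds = {
                a: tuple(np.percentile(syn_rows[a], C.SYNONYMOUS_CI))
                for a in C.ASSAYS
            }
        else:
            syn_bounds = (0.6, 1.4)
    X = rows[list(C.ASSAYS)].to_numpy(dtype=float)
    Xs = StandardScaler().fit_transform(X)
    pca = PCA(n_components=4, random_state=seed)
    proj = pca.fit_transform(Xs)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(proj)

    centroids = (
        pd.DataFrame(X, columns=list(C.ASSAYS)).groupby(labels).mean()
    )
    cluster_names = name_clusters(centroids, syn_bounds=syn_bounds)
    assignments = pd.DataFrame(
        {
            "variant": rows["variant"],
            "cluster": labels,
            "cluster_name": [cluster_names[c] for c in labels],
            "PC1": proj[:, 0],
            "PC2": proj[:, 1],
        }
    )
    return ClusterResult(
        assignments=assignments,
        centroids=centroids,
        explained_variance=pca.explained_variance_,
    )


# ---------------------------------------------------------------------------
# Classifier combination
# ---------------------------------------------------------------------------

def combine_classifiers(
    matrix: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    min_labeled: int = 20,
) -> dict:
    """Train three classifiers on the four scores of labelled variants.

    ``labels`` maps variant -> 1 (pathogenic) / 0 (benign).  Logistic
    regression and Gaussian naive Bayes see standardized scores; the random
    forest sees raw scores (scale invariant).  Leave-one-out
    cross-validated positive-class probabilities and their AUC are reported
    per model, and a final model refit on all labels scores the unlabelled
    complete missense variants.
    """
    rows = matrix[matrix["complete"] & (matrix["consequence"] == MISSENSE)]
    rows = rows.set_index("variant")
    labeled = rows.index.intersection(labels.index)
    y = labels.loc[labeled].astype(int).to_numpy()
    if len(labeled) < min_labeled:
        raise ValueError(f"need >= {min_labeled} labelled variants, got {len(labeled)}")
    if len(np.unique(y)) < 2:
        raise ValueError("truth set has a single class")
    X = rows.loc[labeled, list(C.ASSAYS)].to_numpy(dtype=float)
    unlabeled = rows.index.difference(labels.index)
    X_new = rows.loc[unlabeled, list(C.ASSAYS)].to_numpy(dtype=float)

    models = {
        "logistic_regression": (LogisticRegression(max_iter=1000, random_state=seed), True),
        "random_forest": (RandomForestClassifier(random_state=seed), False),
        "gaussian_nb": (GaussianNB(), True),
    }
    results: dict = {"labeled_variants": list(labeled), "models": {}}
    for name, (model, standardize) in models.items():
        Xm = StandardScaler().fit_transform(X) if standardize else X
        loo_probs = np.empty(len(y))
        for train, test in LeaveOneOut().split(Xm):
            m = model.__class__(**model.get_params())
            m.fit(Xm[train], y[train])
            loo_probs[test] = m.predict_proba(Xm[test])[:, 1]
        auc, _ = roc_auc_from_arrays(loo_probs, y, higher_is_pathogenic=True)
        final = model.__class__(**model.get_params())
        final.fit(Xm, y)
        if standardize and len(X_new):
            scaler = StandardScaler().fit(X)
            probs_new = final.predict_proba(scaler.transform(X_new))[:, 1]
        elif len(X_new):
            probs_new = final.predict_proba(X_new)[:, 1]
        else:
            probs_new = np.array([])
        results["models"][name] = {
            "loo_probabilities": pd.Series(loo_probs, index=labeled),
            "loo_auc": auc,
            "unlabeled_probabilities": pd.Series(probs_new, index=unlabeled),
        }
    return results
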