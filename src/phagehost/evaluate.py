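"""Evaluation protocol: rank-level accuracy, cluster cross-validation,
leakage filtering and recall-accuracy curves.

Plain random CV splits leak information because many interactions involve
compositionally similar viruses and hosts. The protocol therefore partitions
interactions by K-means clustering of their difference vectors into
``n_clusters`` folds (default ten), trains on all but one cluster, and
predicts each held-out virus against the *full* host catalog — not only
hosts seen in training pairs. A prediction is correct at a taxonomic level
if the predicted host shares a known taxon at that level with any recorded
true host of the virus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import InvalidInputError, InvalidParameterError, InvalidPartitionError
from .features import build_training_matrix, validate_interactions
from .kmers import ProfileStore
from .model import VirusHostGaussian
from .predict import HostCatalog, PredictionResult, rank_hosts, threshold_predict, top1
from .taxonomy import RANKS, Lineage, match_at_level


@dataclass
class CvConfig:
    """Knobs of the cluster cross-validation protocol."""

    n_clusters: int = 10
    kmeans_seed: int = 0
    reg_covar: float = 1e-6
    k: int = 4


def accuracy(predictions: list[tuple[Lineage, object]], level: str) -> float:
    """Fraction of predictions matching truth at one taxonomic level.

    Each item pairs a predicted lineage with either one true lineage or a
    sequence of true lineages (multi-host viruses match if any agrees).
    """
    if not predictions:
        raise InvalidInputError("accuracy of an empty prediction list is undefined")
    if level not in RANKS:
        raise InvalidParameterError(f"invalid level {level!r}")
    n_ok = 0
    for predicted, truth in predictions:
        truths = truth if isinstance(truth, (list, tuple, set)) else [truth]
        if any(match_at_level(predicted, t, level) for t in truths):
            n_ok += 1
    return n_ok / len(predictions)


def kmeans_partition(training_matrix: np.ndarray, config: CvConfig) -> np.ndarray:
    """Cluster interaction feature vectors into CV folds.

    Lloyd's algorithm with k-means++ initialization on the raw (unscaled)
    difference vectors, Euclidean distance, seeded for determinism.
    """
    X = np.asarray(training_matrix, dtype=np.float64)
    if config.n_clusters < 2:
        raise InvalidParameterError(f"n_clusters must be >= 2, got {config.n_clusters}")
    if X.shape[0] < config.n_clusters:
        raise InvalidInputError(
            f"{X.shape[0]} interactions cannot form {config.n_clusters} clusters"
        )
    km = KMeans(
        n_clusters=config.n_clusters,
        init="k-means++",
        n_init=10,
        random_state=config.kmeans_seed,
    )
    with warnings.catch_warnings():
        # tiny benchmarks routinely have fewer distinct points than clusters
        warnings.simplefilter("ignore", category=UserWarning)
        return km.fit_predict(X)


@dataclass
class CvResult:
    """Pooled cluster-CV outcome: per-level accuracies plus per-virus detail."""

    accuracies: dict[str, float]
    detail: pd.DataFrame
    n: int
    fold_sizes: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"level": lvl, "accuracy": acc, "n": self.n} for lvl, acc in self.accuracies.items()]
        )


def cluster_cv(
    interactions: pd.DataFrame,
    virus_profiles: ProfileStore,
    catalog: HostCatalog,
    config: CvConfig,
    test_virus_profiles: ProfileStore | None = None,
) -> CvResult:
    """Ten-fold (by default) cluster cross-validation of the Gaussian model.

    For each fold the model is fitted on every interaction outside the fold
    and each held-out virus is ranked against the complete catalog. Pooled
    accuracy at a level is the fraction of correctly predicted interactions
    over all folds.

    ``test_virus_profiles`` optionally substitutes different query profiles
    (e.g. profiles built from simulated contigs) at prediction time while
    folds and training still use ``virus_profiles`` — unless the two stores
    are the same object, in which case everything is consistent by default.
    """
    validate_interactions(interactions)
    X, index = build_training_matrix(interactions, virus_profiles, catalog.profiles)
    # canonical (row-order independent) clustering: sort rows by pair key,
    # cluster, then scatter labels back
    order = sorted(range(len(index)), key=lambda i: index[i])
    labels = np.empty(len(index), dtype=int)
    labels[order] = kmeans_partition(X[order], config)

    test_virus_profiles = test_virus_profiles or virus_profiles
    truth_map: dict[str, list[Lineage]] = {}
    for virus_id, host_id in index:
        truth_map.setdefault(virus_id, []).append(catalog.lineage(host_id))

    rows = []
    fold_sizes = []
    for fold in sorted(set(labels.tolist())):
        test_mask = labels == fold
        train_mask = ~test_mask
        if not train_mask.any():
            raise InvalidPartitionError(
                f"fold {fold} contains every interaction; nothing left to train on"
            )
        fold_sizes.append(int(test_mask.sum()))
        results = VirusHostGaussian(
            X[train_mask], k=virus_profiles.k
        ).fit(reg_covar=config.reg_covar)
        for i in np.flatnonzero(test_mask):
            virus_id, host_id = index[i]
            ranking = rank_hosts(results, test_virus_profiles[virus_id], catalog)
            predicted = top1(ranking, catalog)
            row = {
                "fold": fold,
                "virus_id": virus_id,
                "host_genome_id": host_id,
                "predicted_genome_id": ranking.top_genome,
                "top_score": ranking.top_score,
            }
            for lvl in RANKS:
                row[f"correct_{lvl}"] = any(
                    match_at_level(predicted, t, lvl) for t in truth_map[virus_id]
                )
            rows.append(row)
    detail = pd.DataFrame(rows)
    accuracies = {lvl: float(detail[f"correct_{lvl}"].mean()) for lvl in RANKS}
    return CvResult(accuracies=accuracies, detail=detail, n=len(detail), fold_sizes=fold_sizes)


def leakage_filtered_retrain(
    interactions: pd.DataFrame,
    query_virus_genus: str,
    query_host_genus: str,
    mode: str = "and",
) -> pd.DataFrame:
    """Drop training interactions sharing genus annotations with a query pair.

    ``interactions`` must carry ``virus_genus`` and ``host_genus`` columns.
    Mode ``"and"`` (the default, literal reading) removes pairs matching
    BOTH the query's viral genus AND its host genus; mode ``"or"`` removes
    pairs matching either, which is strictly more aggressive.
    """
    for col in ("virus_genus", "host_genus"):
        if col not in interactions.columns:
            raise InvalidInputError(f"interaction table lacks the {col!r} column")
    same_v = interactions["virus_genus"] == query_virus_genus
    same_h = interactions["host_genus"] == query_host_genus
    if mode == "and":
        drop = same_v & same_h
    elif mode == "or":
        drop = same_v | same_h
    else:
        raise InvalidParameterError(f"mode must be 'and' or 'or', got {mode!r}")
    return interactions.loc[~drop].reset_index(drop=True)


def recall_accuracy_curve(
    results: list[PredictionResult],
    truths: dict[str, list[Lineage]],
    thresholds: list[float],
    level: str,
    catalog: HostCatalog,
) -> pd.DataFrame:
    """Accuracy over the predicted subset as the score threshold rises.

    Thresholds must be sorted ascending; recall is then non-increasing. When
    no virus clears a threshold, accuracy is reported as NaN with n = 0.
    """
    if list(thresholds) != sorted(thresholds):
        raise InvalidInputError("thresholds must be sorted ascending")
    rows = []
    for thr in thresholds:
        predicted, recall = threshold_predict(results, thr)
        if predicted:
            pairs = [(top1(r, catalog), truths[r.virus_id]) for r in predicted]
            acc = accuracy(pairs, level)
        else:
            acc = float("nan")
        rows.append(
            {"threshold": thr, "recall": recall, "accuracy": acc, "n_predicted": len(predicted)}
        )
    return pd.DataFrame(rows)
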