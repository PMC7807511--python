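"""Feature space: virus-minus-host k-mer frequency difference vectors.

The model's feature for a (virus, host) pair is the elementwise difference
of their k-mer frequency vectors, virus minus host (fixed sign convention,
consistent between training and scoring). Because both inputs sum to one,
every feature vector sums to zero — the feature space lives on a hyperplane,
which is why covariance regularization is mandatory downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DuplicateInteractionError, InvalidInputError
from .kmers import KmerProfile, ProfileStore


@dataclass
class FeatureVector:
    """Difference of k-mer frequencies for one (virus, host) pair."""

    virus_id: str
    host_genome_id: str
    values: np.ndarray


def difference_vector(virus: KmerProfile, host: KmerProfile) -> FeatureVector:
    """Virus frequencies minus host frequencies, in fixed feature order."""
    if virus.k != host.k:
        raise InvalidInputError(
            f"k mismatch: virus {virus.genome_id!r} has k={virus.k}, "
            f"host {host.genome_id!r} has k={host.k}"
        )
    return FeatureVector(
        virus_id=virus.genome_id,
        host_genome_id=host.genome_id,
        values=virus.frequencies - host.frequencies,
    )


def validate_interactions(interactions: pd.DataFrame) -> pd.DataFrame:
    required = {"virus_id", "host_genome_id"}
    if not required.issubset(interactions.columns):
        raise InvalidInputError(
            f"interaction table needs columns {sorted(required)}, "
            f"got {list(interactions.columns)}"
        )
    dup = interactions.duplicated(subset=["virus_id", "host_genome_id"])
    if dup.any():
        pairs = interactions.loc[dup, ["virus_id", "host_genome_id"]].values.tolist()
        raise DuplicateInteractionError(
            f"duplicate interaction rows (would silently reweight the fit): {pairs}"
        )
    return interactions


def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read a TSV with header ``virus_id<TAB>host_genome_id``; duplicates are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_interactions(df)


def build_training_matrix(
    interactions: pd.DataFrame,
    virus_profiles: ProfileStore,
    host_profiles: ProfileStore,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Stack one difference vector per interaction row.

    Row i of the returned matrix is the feature vector of interaction i, in
    the interaction table's row order. The second return value indexes rows
    by (virus_id, host_genome_id).
    """
    validate_interactions(interactions)
    rows, index = [], []
    for virus_id, host_id in zip(
        interactions["virus_id"], interactions["host_genome_id"]
    ):
        fv = difference_vector(virus_profiles[virus_id], host_profiles[host_id])
        rows.append(fv.values)
        index.append((virus_id, host_id))
    if not rows:
        return np.empty((0, 4 ** virus_profiles.k)), index
    return np.stack(rows), index
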