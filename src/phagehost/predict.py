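"""Host ranking and derived prediction modes.

For a query virus every catalog host receives the log-density of the
virus-minus-host difference vector under the fitted Gaussian; hosts are
ranked by descending score (ties broken by ascending genome_id, so rankings
are deterministic). Three call modes are derived from a ranking:

* top-1 — the lineage of the highest-scoring genome;
* consensus — the most frequent taxon at a chosen rank among the top N
  genomes (unknown labels abstain; frequency ties go to the taxon holding
  the best-scoring genome);
* thresholded — a prediction is issued only when the top score is at least
  a given threshold; the fraction of viruses predicted is the recall rate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError, UnknownIdError
from .features import difference_vector
from .kmers import KmerProfile, ProfileStore
from .taxonomy import RANKS, UNKNOWN, UNKNOWN_LINEAGE, Lineage


class HostCatalog:
    """Candidate hosts: k-mer profiles plus six-rank lineages.

    Genomes without a taxonomy row get an all-unknown lineage. Ranking is
    per genome; genomes of the same species are not merged.
    """

    def __init__(self, profiles: ProfileStore, lineages: dict[str, Lineage] | None = None):
        if len(profiles) == 0:
            raise InvalidInputError("host catalog must contain at least one genome")
        self.profiles = profiles
        lineages = lineages or {}
        self.lineages = {gid: lineages.get(gid, UNKNOWN_LINEAGE) for gid in profiles.ids}
        self.genome_ids = list(profiles.ids)
        self._matrix = profiles.matrix(self.genome_ids)

    @property
    def k(self) -> int:
        return self.profiles.k

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    def __len__(self) -> int:
        return len(self.genome_ids)

    def lineage(self, genome_id: str) -> Lineage:
        try:
            return self.lineages[genome_id]
        except KeyError:
            raise UnknownIdError(f"genome_id {genome_id!r} not in catalog") from None


@dataclass
class PredictionResult:
    """Per-virus ranking of every catalog host by log-density score."""

    virus_id: str
    ranked: list[tuple[str, float]] = field(default_factory=list)

    @property
    def top_genome(self) -> str:
        return self.ranked[0][0]

    @property
    def top_score(self) -> float:
        return self.ranked[0][1]


def rank_hosts(results, virus: KmerProfile, catalog: HostCatalog) -> PredictionResult:
    """Score and rank every catalog host for one query virus.

    Sorted by score descending, ties by ascending genome_id.
    """
    if len(catalog) == 0:
        raise InvalidInputError("cannot rank against an empty catalog")
    if virus.k != catalog.k:
        raise InvalidInputError(
            f"virus {virus.genome_id!r} has k={virus.k}, catalog has k={catalog.k}"
        )
    diffs = virus.frequencies[None, :] - catalog.matrix
    scores = results.log_score_batch(diffs)
    ranked = sorted(
        zip(catalog.genome_ids, scores.tolist()), key=lambda t: (-t[1], t[0])
    )
    return PredictionResult(virus_id=virus.genome_id, ranked=ranked)


def top1(result: PredictionResult, catalog: HostCatalog) -> Lineage:
    """Lineage of the rank-1 genome."""
    if not result.ranked:
        raise InvalidInputError(f"empty ranking for virus {result.virus_id!r}")
    return catalog.lineage(result.top_genome)


def consensus(result: PredictionResult, N: int, level: str, catalog: HostCatalog) -> str:
    """Most frequent taxon at ``level`` among the top-N ranked genomes.

    Genomes with an unknown label at that rank abstain; if all abstain the
    result is ``"unknown"``. Frequency ties are broken in favor of the taxon
    containing the highest-scoring genome.
    """
    if level not in RANKS:
        raise InvalidParameterError(f"invalid level {level!r}; expected one of {RANKS}")
    if N < 1:
        raise InvalidParameterError(f"N must be >= 1, got {N}")
    if not result.ranked:
        raise InvalidInputError(f"empty ranking for virus {result.virus_id!r}")
    top = result.ranked[: min(N, len(result.ranked))]
    votes = Counter()
    best_rank: dict[str, int] = {}
    for pos, (gid, _score) in enumerate(top):
        taxon = catalog.lineage(gid).at(level)
        if taxon == UNKNOWN:
            continue
        votes[taxon] += 1
        best_rank.setdefault(taxon, pos)
    if not votes:
        return UNKNOWN
    return min(votes, key=lambda t: (-votes[t], best_rank[t]))


def threshold_predict(
    results: list[PredictionResult], threshold: float
) -> tuple[list[PredictionResult], float]:
    """Keep only viruses whose top score is >= threshold; report recall.

    Recall is the fraction of input viruses for which a prediction is made;
    downstream accuracy is computed over the predicted subset only.
    """
    if not results:
        raise InvalidInputError("threshold_predict needs at least one ranking")
    predicted = [r for r in results if r.top_score >= threshold]
    return predicted, len(predicted) / len(results)


def predictions_to_frame(
    results: list[PredictionResult], catalog: HostCatalog, top: int | None = None
) -> pd.DataFrame:
    """Tabulate rankings: virus_id, rank, genome_id, score, species..phylum."""
    rows = []
    for res in results:
        ranked = res.ranked if top is None else res.ranked[:top]
        for pos, (gid, score) in enumerate(ranked, start=1):
            lin = catalog.lineage(gid)
            row = {"virus_id": res.virus_id, "rank": pos, "genome_id": gid, "score": score}
            row.update({r: lin.at(r) for r in RANKS})
            rows.append(row)
    columns = ["virus_id", "rank", "genome_id", "score", *RANKS]
    return pd.DataFrame(rows, columns=columns)


def consensus_to_frame(
    results: list[PredictionResult], catalog: HostCatalog, N: int
) -> pd.DataFrame:
    """Consensus taxon per virus and level: virus_id, level, taxon, N."""
    rows = [
        {"virus_id": res.virus_id, "level": lvl, "taxon": consensus(res, N, lvl, catalog), "N": N}
        for res in results
        for lvl in RANKS
    ]
    return pd.DataFrame(rows, columns=["virus_id", "level", "taxon", "N"])
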