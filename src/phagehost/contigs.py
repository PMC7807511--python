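"""Simulated metagenomic viral contigs.

Metagenomic assembly yields partial virus genomes, so host prediction must
work on fragments. Contigs are exact contiguous substrings of fixed length L
subsampled uniformly from the viral genome: the source record is chosen with
probability proportional to its number of valid start positions and the
start is uniform, which makes every genomic window equally likely. Host
genomes are never fragmented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GenomeTooShortError, InvalidParameterError
from .evaluate import CvConfig, cluster_cv
from .kmers import GenomeRecord, ProfileStore, profile_from_genome
from .predict import HostCatalog

logger = logging.getLogger(__name__)


@dataclass
class ContigSpec:
    """Fragment length, per-virus count and the seed that fixes the draws."""

    length: int
    seed: int = 0
    n_per_virus: int = 1

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InvalidParameterError(f"contig length must be >= 1, got {self.length}")
        if self.n_per_virus < 1:
            raise InvalidParameterError(
                f"n_per_virus must be >= 1, got {self.n_per_virus}"
            )


def subsample_contig(
    genome: GenomeRecord, length: int, rng: np.random.Generator
) -> str:
    """Draw one contig of exactly ``length`` bp from one record of a genome."""
    starts = np.array([len(s) - length + 1 for s in genome.sequences], dtype=np.int64)
    starts = np.clip(starts, 0, None)
    total = int(starts.sum())
    if total == 0:
        raise GenomeTooShortError(
            f"genome {genome.genome_id!r}: no record is >= {length} bp"
        )
    rec = int(rng.choice(len(genome.sequences), p=starts / total))
    start = int(rng.integers(starts[rec]))
    return genome.sequences[rec][start : start + length]


def contig_profiles(
    virus_genomes: dict[str, GenomeRecord],
    spec: ContigSpec,
    k: int,
    rng: np.random.Generator | None = None,
) -> tuple[ProfileStore, list[str]]:
    """Profile each virus from freshly subsampled contig(s).

    Viruses with no record long enough are skipped with a logged warning;
    their ids are returned so callers can drop the matching interactions.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    store = ProfileStore()
    skipped = []
    for vid in sorted(virus_genomes):
        genome = virus_genomes[vid]
        try:
            frags = [subsample_contig(genome, spec.length, rng) for _ in range(spec.n_per_virus)]
        except GenomeTooShortError:
            logger.warning(
                "skipping virus %s: shorter than contig length %d", vid, spec.length
            )
            skipped.append(vid)
            continue
        store.add(profile_from_genome(GenomeRecord(vid, frags), k))
    return store, skipped


def contig_experiment(
    interactions: pd.DataFrame,
    virus_genomes: dict[str, GenomeRecord],
    catalog: HostCatalog,
    lengths: list[int],
    cv_config: CvConfig,
    seed: int = 0,
    n_per_virus: int = 1,
    whole_genome_profiles: ProfileStore | None = None,
) -> pd.DataFrame:
    """Cluster-CV accuracy as a function of simulated contig length.

    By default a separate model is retrained per contig length (folds,
    training features and query profiles all use the contig profiles).
    Passing ``whole_genome_profiles`` instead trains each fold on
    whole-genome features and only the held-out queries use contigs.

    Returns a tidy table with columns length, level, accuracy, n.
    """
    frames = []
    for length in lengths:
        spec = ContigSpec(length=length, seed=seed, n_per_virus=n_per_virus)
        store, skipped = contig_profiles(virus_genomes, spec, catalog.k)
        kept = interactions[~interactions["virus_id"].isin(skipped)].reset_index(drop=True)
        if whole_genome_profiles is None:
            res = cluster_cv(kept, store, catalog, cv_config)
        else:
            res = cluster_cv(
                kept, whole_genome_profiles, catalog, cv_config, test_virus_profiles=store
            )
        frame = res.to_frame()
        frame.insert(0, "length", length)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
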