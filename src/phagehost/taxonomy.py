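"""Six-rank host lineages (species .. phylum) and rank-level matching.

An ``"unknown"`` label means absence of information: it never matches
anything, and consensus voting excludes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import InvalidParameterError, LineageConsistencyError

#: rank names, most specific first; these are the valid ``level`` arguments
RANKS = ("species", "genus", "family", "order", "class", "phylum")

UNKNOWN = "unknown"


@dataclass(frozen=True)
class Lineage:
    """Taxonomic labels of one host genome at the six standard ranks."""

    species: str = UNKNOWN
    genus: str = UNKNOWN
    family: str = UNKNOWN
    order: str = UNKNOWN
    class_: str = UNKNOWN
    phylum: str = UNKNOWN

    def at(self, level: str) -> str:
        if level not in RANKS:
            raise InvalidParameterError(
                f"invalid taxonomic level {level!r}; expected one of {RANKS}"
            )
        return getattr(self, "class_" if level == "class" else level)

    @classmethod
    def from_mapping(cls, mapping) -> "Lineage":
        def get(rank):
            v = mapping.get(rank, UNKNOWN)
            v = "" if v is None or (isinstance(v, float) and pd.isna(v)) else str(v).strip()
            return v or UNKNOWN

        return cls(*(get(r) for r in RANKS))


UNKNOWN_LINEAGE = Lineage()


def match_at_level(predicted: Lineage, truth: Lineage, level: str) -> bool:
    """True iff both lineages carry the same *known* taxon at ``level``."""
    p, t = predicted.at(level), truth.at(level)
    return p != UNKNOWN and t != UNKNOWN and p == t


def read_taxonomy(path: str | Path, validate: bool = True) -> dict[str, Lineage]:
    """Read a taxonomy TSV (genome_id + the six ranks; empty cell -> unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "genome_id" not in df.columns:
        raise InvalidParameterError(f"taxonomy file {path} lacks a genome_id column")
    lineages = {
        str(row["genome_id"]): Lineage.from_mapping(row) for _, row in df.iterrows()
    }
    if validate:
        validate_lineage_consistency(lineages.values())
    return lineages


def validate_lineage_consistency(lineages) -> None:
    """Hard-fail if a shared known taxon has diverging higher ranks.

    Within one catalog, two genomes in the same genus must agree on family,
    order, class and phylum (and analogously for family through class).
    """
    lineages = list(lineages)
    for i, rank in enumerate(RANKS[1:-1], start=1):  # genus .. class
        seen: dict[str, tuple] = {}
        for lin in lineages:
            label = lin.at(rank)
            if label == UNKNOWN:
                continue
            higher = tuple(lin.at(r) for r in RANKS[i + 1 :])
            if label in seen and seen[label] != higher:
                raise LineageConsistencyError(
                    f"{rank} {label!r} maps to conflicting higher ranks "
                    f"{seen[label]} vs {higher}"
                )
            seen.setdefault(label, higher)
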