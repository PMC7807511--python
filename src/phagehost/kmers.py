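"""Genome signatures: normalized k-mer frequency profiles.

A genome's *signature* is the vector of frequencies of all overlapping
k-mers (tetranucleotides for k=4, giving 4**4 = 256 features). Viruses and
their prokaryotic hosts tend to share similar signatures, which is the
compositional signal the Gaussian host model exploits.

Conventions (fixed across the whole package):

* feature order is lexicographic over A < C < G < T; ``enumerate_kmers``
  defines the indexing used by every profile, feature vector and model;
* counting is on the forward strand of the given sequence only, unless
  ``add_reverse_complement=True`` adds the reverse-complement counts;
* any window containing a non-ACGT character (N or another IUPAC ambiguity
  code) is skipped entirely — no fractional counts;
* sequences are uppercased and U is mapped to T before counting;
* multi-record genomes sum counts across records; windows never span a
  record boundary (contigs are not physically adjacent).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    DegenerateGenomeError,
    InvalidInputError,
    InvalidParameterError,
    UnknownIdError,
)

#: characters accepted in a normalized sequence (IUPAC nucleotide codes,
#: gap and period tolerated as "not ACGT" so their windows are skipped)
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN.-")

_BASES = "ACGT"

# byte -> 2-bit code; 255 marks "not a concrete base"
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN.-",
    "TGCAYRSWMKVHDBN.-",
)


def normalize_sequence(sequence: str) -> str:
    """Uppercase a nucleotide sequence and map RNA U to T."""
    return sequence.upper().replace("U", "T")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a normalized (uppercase) DNA sequence."""
    return sequence.translate(_COMPLEMENT)[::-1]


def enumerate_kmers(k: int) -> list[str]:
    """Return all 4**k k-mers in lexicographic order over A < C < G < T.

    This ordering defines the feature indexing used everywhere: profiles,
    difference vectors, model mean/covariance, and tabular output columns.

    Parameters
    ----------
    k : int
        k-mer length; must satisfy 1 <= k <= 8.
    """
    if not isinstance(k, (int, np.integer)) or not 1 <= int(k) <= 8:
        raise InvalidParameterError(f"k must be an integer in [1, 8], got {k!r}")
    return ["".join(p) for p in itertools.product(_BASES, repeat=int(k))]


def count_kmers(
    sequence: str, k: int, *, add_reverse_complement: bool = False
) -> np.ndarray:
    """Count every overlapping k-mer window of a single sequence.

    Windows containing any character outside {A, C, G, T} contribute
    nothing. A sequence shorter than k yields the zero vector. Counting is
    strand-specific unless ``add_reverse_complement`` is set, in which case
    the counts of the reverse-complement strand are added.

    Returns
    -------
    numpy.ndarray of shape (4**k,), dtype int64
        Counts in lexicographic feature order.
    """
    if not isinstance(k, (int, np.integer)) or not 1 <= int(k) <= 8:
        raise InvalidParameterError(f"k must be an integer in [1, 8], got {k!r}")
    k = int(k)
    n_feat = 4**k
    counts = np.zeros(n_feat, dtype=np.int64)
    seq = normalize_sequence(sequence)
    if len(seq) >= k:
        codes = _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (windows != 255).all(axis=1)
        if valid.any():
            powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
            vals = windows[valid].astype(np.int64) @ powers
            counts += np.bincount(vals, minlength=n_feat)
    if add_reverse_complement:
        counts += count_kmers(reverse_complement(seq), k)
    return counts


@dataclass
class GenomeRecord:
    """One genome: an identifier plus one normalized sequence per FASTA record.

    Sequences are uppercased with U mapped to T on construction; characters
    outside the IUPAC nucleotide alphabet are rejected.
    """

    genome_id: str
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise InvalidInputError("genome_id must be a nonempty string")
        self.sequences = [normalize_sequence(s) for s in self.sequences]
        for i, seq in enumerate(self.sequences):
            bad = set(seq) - IUPAC_CHARS
            if bad:
                raise InvalidInputError(
                    f"genome {self.genome_id!r}, record {i}: non-IUPAC "
                    f"characters {sorted(bad)!r}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)


@dataclass
class KmerProfile:
    """Normalized k-mer frequency vector of one genome.

    ``frequencies`` has length 4**k, entries in [0, 1] summing to 1 (within
    1e-12) whenever ``n_valid_windows > 0``; feature order is lexicographic
    (see :func:`enumerate_kmers`).
    """

    genome_id: str
    k: int
    frequencies: np.ndarray
    n_valid_windows: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if self.frequencies.shape != (4**self.k,):
            raise InvalidInputError(
                f"profile {self.genome_id!r}: expected {4 ** self.k} "
                f"frequencies for k={self.k}, got {self.frequencies.shape}"
            )


def profile_from_genome(
    genome: GenomeRecord, k: int, *, add_reverse_complement: bool = False
) -> KmerProfile:
    """Build the k-mer frequency profile of a (possibly multi-record) genome.

    Counts are summed over records — never across record boundaries — and
    normalized to frequencies summing to one.

    Raises
    ------
    DegenerateGenomeError
        If no record contributes a single valid window.
    """
    counts = np.zeros(4 ** int(k), dtype=np.int64)
    for seq in genome.sequences:
        counts += count_kmers(seq, k, add_reverse_complement=add_reverse_complement)
    total = int(counts.sum())
    if total == 0:
        raise DegenerateGenomeError(
            f"genome {genome.genome_id!r} has zero valid {k}-mer windows"
        )
    return KmerProfile(
        genome_id=genome.genome_id,
        k=int(k),
        frequencies=counts / total,
        n_valid_windows=total,
    )


def read_genome_fasta(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Read one genome from a (multi-record) FASTA file.

    The genome identifier defaults to the file name without extension; a
    manifest (see :func:`read_manifest`) can override it.
    """
    path = Path(path)
    records = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InvalidInputError(f"no FASTA records in {path}")
    return GenomeRecord(genome_id=genome_id or path.stem, sequences=records)


def read_manifest(path: str | Path) -> list[tuple[str, Path]]:
    """Read a genome manifest TSV with header ``genome_id<TAB>fasta_path``.

    Relative FASTA paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "fasta_path"}
    if not required.issubset(df.columns):
        raise InvalidInputError(
            f"manifest {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    out = []
    for gid, fp in zip(df["genome_id"], df["fasta_path"]):
        p = Path(fp)
        if not p.is_absolute():
            p = path.parent / p
        out.append((gid, p))
    return out


class ProfileStore:
    """In-memory collection of :class:`KmerProfile` objects sharing one k.

    Persisted as a TSV (one row per genome: genome_id, k, n_valid_windows,
    then one column per k-mer in lexicographic order) so model training
    never has to re-read FASTA files.
    """

    def __init__(self, profiles: list[KmerProfile] | None = None):
        self._profiles: dict[str, KmerProfile] = {}
        for p in profiles or []:
            self.add(p)

    def add(self, profile: KmerProfile) -> None:
        if self._profiles:
            k0 = next(iter(self._profiles.values())).k
            if profile.k != k0:
                raise InvalidInputError(
                    f"profile {profile.genome_id!r} has k={profile.k}, store has k={k0}"
                )
        if profile.genome_id in self._profiles:
            raise InvalidInputError(f"duplicate genome_id {profile.genome_id!r}")
        self._profiles[profile.genome_id] = profile

    @property
    def k(self) -> int:
        if not self._profiles:
            raise InvalidInputError("empty profile store has no k")
        return next(iter(self._profiles.values())).k

    @property
    def ids(self) -> list[str]:
        return list(self._profiles)

    def __len__(self) -> int:
        return len(self._profiles)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._profiles

    def __iter__(self):
        return iter(self._profiles.values())

    def __getitem__(self, genome_id: str) -> KmerProfile:
        try:
            return self._profiles[genome_id]
        except KeyError:
            raise UnknownIdError(
                f"genome_id {genome_id!r} not found in profile store"
            ) from None

    def matrix(self, ids: list[str] | None = None) -> np.ndarray:
        """Stack frequency vectors into an (n_genomes, 4**k) matrix."""
        ids = self.ids if ids is None else ids
        return np.stack([self[g].frequencies for g in ids])

    @classmethod
    def from_genomes(
        cls,
        genomes: list[GenomeRecord],
        k: int,
        *,
        add_reverse_complement: bool = False,
    ) -> "ProfileStore":
        return cls(
            [
                profile_from_genome(g, k, add_reverse_complement=add_reverse_complement)
                for g in genomes
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        kmers = enumerate_kmers(self.k)
        rows = []
        for p in self:
            row = {"genome_id": p.genome_id, "k": p.k, "n_valid_windows": p.n_valid_windows}
            row.update(zip(kmers, p.frequencies))
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileStore":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        meta = ["genome_id", "k", "n_valid_windows"]
        if df.empty or not set(meta).issubset(df.columns):
            raise InvalidInputError(f"malformed profile store {path}")
        k = int(df["k"].iloc[0])
        kmers = enumerate_kmers(k)
        if list(df.columns[3:]) != kmers:
            raise InvalidInputError(
                f"profile store {path}: feature columns are not the "
                f"lexicographic {4 ** k} {k}-mers"
            )
        store = cls()
        for _, row in df.iterrows():
            store.add(
                KmerProfile(
                    genome_id=str(row["genome_id"]),
                    k=int(row["k"]),
                    frequencies=row[kmers].to_numpy(dtype=np.float64),
                    n_valid_windows=int(row["n_valid_windows"]),
                )
            )
        return store
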