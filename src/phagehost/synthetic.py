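"""Self-contained synthetic benchmarks for the virus-host predictor.

Real virus-host catalogs are tens of gigabytes of downloaded genomes; the
generator instead builds miniature worlds with the statistical structure the
model assumes: each host genus has its own compositional signature (an
order-1 Markov transition matrix over A/C/G/T), hosts within a genus share
it up to a small jitter, and each virus is sampled from its true host's
(noise-perturbed) composition. Difference vectors between a virus and its
true host are then approximately normal with mean near zero, and clearly
distinguishable from virus/non-host differences — exactly the contrast the
Gaussian score exploits.

Order-1 chains (not order-3) are used deliberately: they already induce
distinctive 4-mer signatures at a fraction of the cost, and the model only
ever observes 4-mer frequencies.

Default configuration: 20 genera x 2 hosts x 2 viruses per host, 50 kb
hosts, 10 kb viruses, composition divergence 0.5, virus noise 0.05, seed 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .kmers import GenomeRecord, ProfileStore
from .predict import HostCatalog
from .taxonomy import RANKS, Lineage

_BASES = "ACGT"


@dataclass
class SyntheticConfig:
    """Stated world of the synthetic benchmark; defaults are the reference setup."""

    n_genera: int = 20
    hosts_per_genus: int = 2
    viruses_per_host: int = 2
    host_length: int = 50_000
    virus_length: int = 10_000
    composition_divergence: float = 0.5
    virus_noise: float = 0.05
    host_jitter: float = 0.02
    genera_per_family: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.composition_divergence <= 1.0:
            raise InvalidParameterError("composition_divergence must be in [0, 1]")
        if self.virus_noise < 0:
            raise InvalidParameterError("virus_noise must be >= 0")
        if min(self.n_genera, self.hosts_per_genus, self.viruses_per_host) < 1:
            raise InvalidParameterError("all counts must be >= 1")


@dataclass
class SyntheticDataset:
    """Generated benchmark: genomes, lineages and the true interaction table."""

    hosts: list[GenomeRecord]
    host_lineages: dict[str, Lineage]
    viruses: list[GenomeRecord]
    interactions: pd.DataFrame
    config: SyntheticConfig = field(repr=False, default=None)

    def host_profiles(self, k: int = 4) -> ProfileStore:
        return ProfileStore.from_genomes(self.hosts, k)

    def virus_profiles(self, k: int = 4) -> ProfileStore:
        return ProfileStore.from_genomes(self.viruses, k)

    def catalog(self, k: int = 4) -> HostCatalog:
        return HostCatalog(self.host_profiles(k), self.host_lineages)

    def virus_genomes(self) -> dict[str, GenomeRecord]:
        return {v.genome_id: v for v in self.viruses}

    def write(self, outdir: str | Path) -> None:
        """Emit the benchmark in the exact dialects the tool consumes.

        One FASTA per genome under hosts/ and viruses/, plus
        host_manifest.tsv, virus_manifest.tsv, taxonomy.tsv and
        interactions.tsv. Byte-identical for a fixed config.
        """
        outdir = Path(outdir)
        manifests = {}
        for sub, genomes in (("hosts", self.hosts), ("viruses", self.viruses)):
            d = outdir / sub
            d.mkdir(parents=True, exist_ok=True)
            rows = []
            for g in genomes:
                fp = d / f"{g.genome_id}.fasta"
                with open(fp, "w") as fh:
                    for i, seq in enumerate(g.sequences):
                        fh.write(f">{g.genome_id}|record_{i}\n")
                        for j in range(0, len(seq), 80):
                            fh.write(seq[j : j + 80] + "\n")
                rows.append({"genome_id": g.genome_id, "fasta_path": f"{sub}/{g.genome_id}.fasta"})
            manifests[sub] = pd.DataFrame(rows)
        manifests["hosts"].to_csv(outdir / "host_manifest.tsv", sep="\t", index=False)
        manifests["viruses"].to_csv(outdir / "virus_manifest.tsv", sep="\t", index=False)
        tax = pd.DataFrame(
            [
                {"genome_id": gid, **{r: lin.at(r) for r in RANKS}}
                for gid, lin in self.host_lineages.items()
            ]
        )
        tax.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        self.interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)


def sample_composition_model(rng: np.random.Generator, divergence: float) -> np.ndarray:
    """Draw an order-1 Markov transition matrix over {A, C, G, T}.

    ``divergence`` interpolates each row between the uniform distribution
    (divergence 0 gives exactly 0.25 everywhere) and an independent
    symmetric-Dirichlet draw, so larger values yield compositions further
    apart on average.
    """
    if not 0.0 <= divergence <= 1.0:
        raise InvalidParameterError(f"divergence must be in [0, 1], got {divergence}")
    uniform = np.full((4, 4), 0.25)
    random_rows = rng.dirichlet(np.ones(4), size=4)
    matrix = (1.0 - divergence) * uniform + divergence * random_rows
    return matrix / matrix.sum(axis=1, keepdims=True)


def perturb_composition(
    transition: np.ndarray, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Mix each row with an independent random row: (1-noise)*row + noise*random."""
    if noise < 0:
        raise InvalidParameterError(f"noise must be >= 0, got {noise}")
    if noise == 0:
        return np.array(transition, dtype=np.float64)
    random_rows = rng.dirichlet(np.ones(4), size=4)
    mixed = (1.0 - noise) * np.asarray(transition, float) + noise * random_rows
    return mixed / mixed.sum(axis=1, keepdims=True)


def _markov_string(
    rng: np.random.Generator,
    transition: np.ndarray,
    length: int,
    start_base: str | None = None,
) -> str:
    """Sample a DNA string from an order-1 chain (first base uniform)."""
    cum = np.cumsum(np.asarray(transition, float), axis=1)
    cum[:, -1] = 1.0
    rows = cum.tolist()
    out = bytearray(length)
    bases = b"ACGT"
    state = _BASES.index(start_base) if start_base else int(rng.integers(4))
    out[0] = bases[state]
    u = rng.random(length).tolist()
    for i in range(1, length):
        r = u[i]
        row = rows[state]
        if r < row[0]:
            state = 0
        elif r < row[1]:
            state = 1
        elif r < row[2]:
            state = 2
        else:
            state = 3
        out[i] = bases[state]
    return out.decode("ascii")


def generate_host(
    rng: np.random.Generator,
    transition_matrix: np.ndarray,
    length: int,
    start_base: str | None = None,
) -> str:
    """Sample one host genome sequence from its composition model."""
    if length < 2:
        raise InvalidParameterError(f"length must be >= 2, got {length}")
    return _markov_string(rng, transition_matrix, length, start_base)


def generate_virus(
    rng: np.random.Generator,
    host_transition_matrix: np.ndarray,
    virus_noise: float,
    length: int,
) -> str:
    """Sample a virus genome from the host's noise-perturbed composition.

    At noise 0 the virus 4-mer profile converges to the host's as length
    grows; at noise 1 it is compositionally independent of the host.
    """
    perturbed = perturb_composition(host_transition_matrix, virus_noise, rng)
    return _markov_string(rng, perturbed, length)


def generate_benchmark(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a full benchmark, deterministically from ``config.seed``.

    One composition model per genus; hosts of a genus share it up to
    ``host_jitter``; each virus is tied to exactly one true host. Genera are
    grouped into higher ranks in fixed-size blocks (``genera_per_family``
    genera per family, then two families per order, two orders per class,
    two classes per phylum), so lineage consistency holds by construction.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    hosts, viruses, host_lineages, inter_rows = [], [], {}, []
    gpf = config.genera_per_family
    for g in range(config.n_genera):
        genus_model = sample_composition_model(rng, config.composition_divergence)
        lineage_tail = dict(
            genus=f"genus_{g:03d}",
            family=f"family_{g // gpf:03d}",
            order=f"order_{g // (gpf * 2):03d}",
            class_=f"class_{g // (gpf * 4):03d}",
            phylum=f"phylum_{g // (gpf * 8):03d}",
        )
        for h in range(config.hosts_per_genus):
            host_model = perturb_composition(genus_model, config.host_jitter, rng)
            host_id = f"host_{g:03d}_{h:02d}"
            hosts.append(
                GenomeRecord(host_id, [generate_host(rng, host_model, config.host_length)])
            )
            host_lineages[host_id] = Lineage(species=f"species_{g:03d}_{h:02d}", **lineage_tail)
            for v in range(config.viruses_per_host):
                virus_id = f"virus_{g:03d}_{h:02d}_{v:02d}"
                viruses.append(
                    GenomeRecord(
                        virus_id,
                        [generate_virus(rng, host_model, config.virus_noise, config.virus_length)],
                    )
                )
                inter_rows.append({"virus_id": virus_id, "host_genome_id": host_id})
    return SyntheticDataset(
        hosts=hosts,
        host_lineages=host_lineages,
        viruses=viruses,
        interactions=pd.DataFrame(inter_rows),
        config=config,
    )
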