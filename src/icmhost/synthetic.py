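"""Synthetic bacterial communities with host-mimicking phages.

The generator materializes the premise that makes composition-based host
prediction possible: phage genomes drift toward ("ameliorate to") the
polynucleotide composition of their hosts.  Each genus receives its own
order-m Markov transition table drawn per context from a Dirichlet with a
small concentration (lower = more distinct genera); species inherit a
lightly perturbed copy of their genus table; phages are sampled from their
host's *genus* table with an independent per-position probability ε of a
uniform background draw instead.  ε is the single knob controlling host
signal strength: ε = 0 gives a pure host mimic, ε = 1 severs the phage
from its host entirely.

Cellular-fraction scaffolds are verbatim contiguous chunks cut from the
generated genomes, which makes the transitive assignment route exactly
consistent with the direct route by construction.

The taxonomy generated is a minimal canonical ladder — species under
genus under family under order under phylum under an unranked root, with
one family per order and one order per phylum — just enough structure for
the order-or-coarser rejection rule to be exercisable.

Everything is reproducible from the spec's seed alone.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError
from .seq_io import SequenceRecord, write_fasta
from .taxonomy import NO_RANK, TaxonNode, TaxonomyTree, write_taxonomy_tsv

__all__ = [
    "CommunitySpec",
    "SyntheticCommunity",
    "generate_community",
    "sample_phages",
    "fragment",
    "stationary_base_frequencies",
    "write_community",
]

_BASES = "ACGT"
_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunitySpec:
    """Study conditions for one synthetic community."""

    n_phyla: int = 5
    genera_per_phylum: int = 4
    species_per_genus: int = 2
    genome_length: int = 200_000
    composition_order: int = 2  # m: Markov order of the genus tables
    divergence: float = 0.5  # Dirichlet concentration; lower = more distinct
    phage_length: int = 40_000
    epsilon: float = 0.1  # per-position uniform-background probability
    n_phages: int = 200
    scaffolds_per_genome: int = 1
    scaffold_length: int = 150_000
    species_concentration: float = 500.0  # per-species table perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_phyla", "genera_per_phylum", "species_per_genus",
                     "genome_length", "phage_length", "n_phages"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if self.composition_order < 1:
            raise ValueError("composition_order must be >= 1")

    @property
    def n_genera(self) -> int:
        return self.n_phyla * self.genera_per_phylum

    @property
    def n_species(self) -> int:
        return self.n_genera * self.species_per_genus


@dataclass
class SyntheticCommunity:
    spec: CommunitySpec
    taxonomy: TaxonomyTree
    genomes: list[SequenceRecord]
    genome_taxids: dict[str, int]  # genome id → species taxid
    phages: list[SequenceRecord]
    phage_hosts: dict[str, int]  # phage id → host species taxid
    scaffolds: list[SequenceRecord]
    scaffold_sources: dict[str, int]  # scaffold id → source species taxid
    genus_tables: dict[int, np.ndarray]  # genus taxid → (4^m, 4) table


def _sample_markov(
    length: int,
    table: np.ndarray,
    m: int,
    rng: np.random.Generator,
    epsilon: float = 0.0,
) -> str:
    """Sample a sequence from an order-m Markov chain given per-context
    next-base probabilities, mixing in a uniform background draw with
    probability *epsilon* at each position.  The first m bases are uniform."""
    n_states = 4**m
    mask = n_states - 1 if n_states & (n_states - 1) == 0 else None
    cum = np.cumsum(table, axis=1)
    cum3 = [tuple(row[:3]) for row in cum]
    out = np.empty(length, dtype=np.int64)
    head = min(m, length)
    out[:head] = rng.integers(0, 4, size=head)
    if length > m:
        u = rng.random(length - m).tolist()
        if epsilon > 0:
            bg = (rng.random(length - m) < epsilon).tolist()
            bgb = rng.integers(0, 4, size=length - m).tolist()
        state = 0
        for b in out[:m]:
            state = state * 4 + int(b)
        body = out[m:]
        for i in range(length - m):
            if epsilon > 0 and bg[i]:
                b = bgb[i]
            else:
                c0, c1, c2 = cum3[state]
                ui = u[i]
                b = 0 if ui < c0 else 1 if ui < c1 else 2 if ui < c2 else 3
            body[i] = b
            state = ((state << 2) | b) & mask
    return _LUT[out].tobytes().decode("ascii")


def _draw_tables(spec: CommunitySpec, rng: np.random.Generator) -> list[np.ndarray]:
    """One transition table per genus: each context row ~ Dirichlet(divergence)."""
    n_ctx = 4**spec.composition_order
    return [
        rng.dirichlet([spec.divergence] * 4, size=n_ctx)
        for _ in range(spec.n_genera)
    ]


def _perturb(table: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Species-level copy of a genus table: each row redrawn from a tight
    Dirichlet centred on the genus row (larger kappa = smaller perturbation)."""
    out = np.empty_like(table)
    for i, row in enumerate(table):
        out[i] = rng.dirichlet(np.maximum(row * kappa, 1e-3))
    return out


def _build_taxonomy(spec: CommunitySpec) -> tuple[TaxonomyTree, list[int], list[int]]:
    """Ladder taxonomy; returns (tree, genus taxids, species taxids) in
    generation order."""
    nodes = [TaxonNode(taxid=1, parent=1, rank=NO_RANK, name="root")]
    next_id = 2
    genus_ids: list[int] = []
    species_ids: list[int] = []
    for p in range(spec.n_phyla):
        phy = next_id
        nodes.append(TaxonNode(phy, 1, "phylum", f"Phylum_{p + 1}"))
        next_id += 1
        order = next_id
        nodes.append(TaxonNode(order, phy, "order", f"Order_{p + 1}"))
        next_id += 1
        fam = next_id
        nodes.append(TaxonNode(fam, order, "family", f"Family_{p + 1}"))
        next_id += 1
        for g in range(spec.genera_per_phylum):
            gen = next_id
            nodes.append(TaxonNode(gen, fam, "genus", f"Genus_{p + 1}_{g + 1}"))
            genus_ids.append(gen)
            next_id += 1
            for s in range(spec.species_per_genus):
                sp = next_id
                nodes.append(
                    TaxonNode(sp, gen, "species", f"Species_{p + 1}_{g + 1}_{s + 1}")
                )
                species_ids.append(sp)
                next_id += 1
    return TaxonomyTree(nodes), genus_ids, species_ids


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Generate taxonomy, genomes, phages and scaffolds from *spec.seed*."""
    if spec.scaffolds_per_genome > 0 and spec.scaffold_length > spec.genome_length:
        raise ConfigurationError(
            f"genome_length {spec.genome_length} too short to cut a "
            f"{spec.scaffold_length} bp scaffold"
        )
    rng = np.random.default_rng(spec.seed)
    tree, genus_ids, species_ids = _build_taxonomy(spec)
    m = spec.composition_order
    tables = _draw_tables(spec, rng)
    genus_tables = dict(zip(genus_ids, tables))

    genomes: list[SequenceRecord] = []
    genome_taxids: dict[str, int] = {}
    scaffolds: list[SequenceRecord] = []
    scaffold_sources: dict[str, int] = {}
    sp_iter = iter(species_ids)
    for gi, gtax in enumerate(genus_ids):
        for s in range(spec.species_per_genus):
            sp_tax = next(sp_iter)
            sp_table = _perturb(tables[gi], spec.species_concentration, rng)
            seq = _sample_markov(spec.genome_length, sp_table, m, rng)
            gid = f"genome_{sp_tax}"
            rec = SequenceRecord(id=gid, residues=seq,
                                 description=tree.name(sp_tax))
            genomes.append(rec)
            genome_taxids[gid] = sp_tax
            for c in range(spec.scaffolds_per_genome):
                hi = spec.genome_length - spec.scaffold_length
                off = int(rng.integers(0, hi + 1))
                sid = f"scaffold_{sp_tax}_{c}"
                scaffolds.append(
                    SequenceRecord(
                        id=sid,
                        residues=seq[off : off + spec.scaffold_length],
                        description=f"chunk of {gid} at {off}",
                    )
                )
                scaffold_sources[sid] = sp_tax

    phages, phage_hosts = sample_phages(
        genus_tables=genus_tables,
        tree=tree,
        species_ids=species_ids,
        n=spec.n_phages,
        length=spec.phage_length,
        epsilon=spec.epsilon,
        m=m,
        rng=rng,
    )
    return SyntheticCommunity(
        spec=spec,
        taxonomy=tree,
        genomes=genomes,
        genome_taxids=genome_taxids,
        phages=phages,
        phage_hosts=phage_hosts,
        scaffolds=scaffolds,
        scaffold_sources=scaffold_sources,
        genus_tables=genus_tables,
    )


def sample_phages(
    genus_tables: dict[int, np.ndarray],
    tree: TaxonomyTree,
    species_ids: list[int],
    n: int,
    length: int,
    epsilon: float,
    m: int,
    rng: np.random.Generator | int,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Sample *n* phages, each assigned a uniformly drawn host species and
    generated from the host's genus table with background rate ε."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    phages: list[SequenceRecord] = []
    hosts: dict[str, int] = {}
    for i in range(n):
        host = int(species_ids[rng.integers(0, len(species_ids))])
        genus = tree.lineage(host)[-2]  # immediate parent is the genus
        seq = _sample_markov(length, genus_tables[genus], m, rng, epsilon=epsilon)
        pid = f"phage_{i:04d}"
        phages.append(
            SequenceRecord(id=pid, residues=seq,
                           description=f"host {tree.name(host)}")
        )
        hosts[pid] = host
    return phages, hosts


def fragment(
    record: SequenceRecord, length: int, n: int, seed: int | np.random.Generator
) -> list[SequenceRecord]:
    """Cut *n* substrings of exactly *length* bases at uniform offsets."""
    if length > record.length:
        raise ValueError(
            f"fragment length {length} exceeds record length {record.length}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(n):
        off = int(rng.integers(0, record.length - length + 1))
        out.append(
            SequenceRecord(
                id=f"{record.id}|frag{i}|off{off}",
                residues=record.residues[off : off + length],
                description=f"fragment of {record.id}",
            )
        )
    return out


def stationary_base_frequencies(table: np.ndarray, m: int) -> np.ndarray:
    """Stationary single-base frequencies of an order-m chain.

    Builds the transition matrix on the 4^m context states, takes the
    left eigenvector at eigenvalue 1, and marginalizes to the last base.
    """
    n_states = 4**m
    T = np.zeros((n_states, n_states))
    for s in range(n_states):
        for b in range(4):
            T[s, (s * 4 + b) % n_states] += table[s, b]
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = pi / pi.sum()
    freq = np.zeros(4)
    for s in range(n_states):
        freq[s % 4] += pi[s]
    return freq


def write_community(community: SyntheticCommunity, out_dir: str | os.PathLike) -> None:
    """Emit FASTA + taxonomy TSV + truth tables + a spec echo for provenance."""
    os.makedirs(out_dir, exist_ok=True)
    write_fasta(community.genomes, os.path.join(out_dir, "genomes.fasta"))
    write_fasta(community.phages, os.path.join(out_dir, "phages.fasta"))
    if community.scaffolds:
        write_fasta(community.scaffolds, os.path.join(out_dir, "scaffolds.fasta"))
    write_taxonomy_tsv(community.taxonomy, os.path.join(out_dir, "taxonomy.tsv"))
    with open(os.path.join(out_dir, "genome_labels.tsv"), "w") as fh:
        fh.write("seq_id\ttaxid\n")
        for gid, taxid in community.genome_taxids.items():
            fh.write(f"{gid}\t{taxid}\n")
    with open(os.path.join(out_dir, "phage_hosts.tsv"), "w") as fh:
        fh.write("phage_id\thost_taxid\n")
        for pid, taxid in community.phage_hosts.items():
            fh.write(f"{pid}\t{taxid}\n")
    with open(os.path.join(out_dir, "scaffold_sources.tsv"), "w") as fh:
        fh.write("scaffold_id\tsource_taxid\n")
        for sid, taxid in community.scaffold_sources.items():
            fh.write(f"{sid}\t{taxid}\n")
    with open(os.path.join(out_dir, "community_spec.yaml"), "w") as fh:
        yaml.safe_dump(asdict(community.spec), fh, sort_keys=False)
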