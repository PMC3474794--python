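"""Rank-labelled taxonomy tree with lineage, LCA and ancestor-at-rank queries.

Two on-disk dialects are supported: the NCBI taxdump ``nodes.dmp`` /
``names.dmp`` layout (pipe-and-tab delimited) and a simple 4-column TSV
(``taxid  parent  rank  name``).

Canonical ranks form a fixed specificity ladder::

    superkingdom < phylum < class < order < family < genus < species

Nodes of any other rank are stored as ``no_rank`` and are *transparent*:
they may sit on a lineage but are never returned by
:meth:`TaxonomyTree.ancestor_at_rank`, and the assignment rejection rule
always compares the nearest canonically ranked ancestor.  Sub-species
ranks (subspecies, strain, varietas, ...) collapse to ``species``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import TaxonomyError, TaxonomyLookupError

__all__ = [
    "CANONICAL_RANKS",
    "RANK_INDEX",
    "TaxonNode",
    "TaxonomyTree",
    "load_taxonomy",
]

#: ascending specificity
CANONICAL_RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(CANONICAL_RANKS)}

NO_RANK = "no_rank"

_SUBSPECIES_RANKS = {
    "subspecies",
    "strain",
    "varietas",
    "forma",
    "forma specialis",
    "isolate",
    "serotype",
    "serovar",
    "biotype",
    "genotype",
    "pathogroup",
    "morph",
}
_RANK_ALIASES = {"domain": "superkingdom", "no rank": NO_RANK}


def canonical_rank(rank: str) -> str:
    """Map an arbitrary rank string onto the canonical ladder or ``no_rank``."""
    r = rank.strip().lower().replace("_", " ") if rank else NO_RANK
    r = _RANK_ALIASES.get(r, r)
    if r in _SUBSPECIES_RANKS:
        return "species"
    if r in RANK_INDEX:
        return r
    return NO_RANK


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str = ""


class TaxonomyTree:
    """Immutable view of a taxonomy as a parent-pointer forest with one root."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {}
        for n in nodes:
            if n.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {n.taxid}")
            self.nodes[n.taxid] = n
        self._validate()

    def _validate(self) -> None:
        if not self.nodes:
            raise TaxonomyError("taxonomy has no nodes")
        dangling = sorted(
            n.taxid for n in self.nodes.values() if n.parent not in self.nodes
        )
        if dangling:
            raise TaxonomyError(f"parent taxid missing for nodes: {dangling}")
        roots = [n.taxid for n in self.nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {sorted(roots)}")
        self.root = roots[0]
        # cycle check: every node must reach the root
        for start in self.nodes:
            seen = set()
            t = start
            while t != self.root:
                if t in seen:
                    raise TaxonomyError(f"cycle detected through taxid {t}")
                seen.add(t)
                t = self.nodes[t].parent

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def _node(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise TaxonomyLookupError(f"unknown taxid {taxid}") from None

    def name(self, taxid: int) -> str:
        return self._node(taxid).name

    def rank(self, taxid: int) -> str:
        return self._node(taxid).rank

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from the root down to *taxid* inclusive."""
        self._node(taxid)
        out = []
        t = taxid
        while True:
            out.append(t)
            node = self.nodes[t]
            if node.parent == t:
                break
            t = node.parent
        return out[::-1]

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of taxids."""
        taxids = list(taxids)
        if not taxids:
            raise ValueError("lca of an empty set is undefined")
        common: Optional[list[int]] = None
        for t in taxids:
            lin = self.lineage(t)
            if common is None:
                common = lin
            else:
                k = 0
                for a, b in zip(common, lin):
                    if a != b:
                        break
                    k += 1
                common = common[:k]
        assert common  # root is always shared
        return common[-1]

    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        """The unique ancestor-or-self of *taxid* with exactly canonical
        rank *rank*, or None if the lineage lacks that rank."""
        if rank not in RANK_INDEX:
            raise ValueError(f"not a canonical rank: {rank!r}")
        for t in reversed(self.lineage(taxid)):
            if self.nodes[t].rank == rank:
                return t
        return None

    def nearest_canonical_ancestor(self, taxid: int) -> tuple[Optional[int], Optional[str]]:
        """Walk up from *taxid* (inclusive) to the first canonically ranked
        node; (None, None) if even the root is unranked."""
        for t in reversed(self.lineage(taxid)):
            r = self.nodes[t].rank
            if r in RANK_INDEX:
                return t, r
        return None, None

    def taxids_at_rank(self, rank: str) -> list[int]:
        return [t for t, n in self.nodes.items() if n.rank == rank]


def _load_tsv(path: str | os.PathLike) -> list[TaxonNode]:
    nodes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].strip().lower() == "taxid":  # optional header
                continue
            if len(fields) < 3:
                raise TaxonomyError(
                    f"{path}:{lineno + 1}: expected taxid/parent/rank[/name] columns"
                )
            name = fields[3] if len(fields) > 3 else ""
            nodes.append(
                TaxonNode(
                    taxid=int(fields[0]),
                    parent=int(fields[1]),
                    rank=canonical_rank(fields[2]),
                    name=name,
                )
            )
    return nodes


def _load_ncbi_dump(nodes_path: str | os.PathLike,
                    names_path: str | os.PathLike | None = None) -> list[TaxonNode]:
    names: dict[int, str] = {}
    if names_path is not None and os.path.exists(names_path):
        with open(names_path) as fh:
            for line in fh:
                parts = [p.strip() for p in line.rstrip("\t|\n").split("\t|\t")]
                if len(parts) >= 4 and parts[3] == "scientific name":
                    names[int(parts[0])] = parts[1]
    nodes = []
    with open(nodes_path) as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\t|\n").split("\t|\t")]
            if len(parts) < 3:
                raise TaxonomyError(f"malformed nodes.dmp line: {line!r}")
            taxid, parent, rank = int(parts[0]), int(parts[1]), parts[2]
            nodes.append(
                TaxonNode(
                    taxid=taxid,
                    parent=parent,
                    rank=canonical_rank(rank),
                    name=names.get(taxid, ""),
                )
            )
    return nodes


def load_taxonomy(
    path: str | os.PathLike,
    dialect: str = "tsv",
    names_path: str | os.PathLike | None = None,
) -> TaxonomyTree:
    """Load a taxonomy from disk.

    Parameters
    ----------
    path:
        TSV file (dialect ``tsv``) or ``nodes.dmp`` (dialect ``ncbi_dump``).
    dialect:
        ``"tsv"`` or ``"ncbi_dump"``.
    names_path:
        Optional ``names.dmp`` companion for the NCBI dialect.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"taxonomy file not found: {path}")
    if dialect == "tsv":
        nodes = _load_tsv(path)
    elif dialect == "ncbi_dump":
        if names_path is None:
            guess = os.path.join(os.path.dirname(str(path)), "names.dmp")
            names_path = guess if os.path.exists(guess) else None
        nodes = _load_ncbi_dump(path, names_path)
    else:
        raise ValueError(f"unknown taxonomy dialect: {dialect!r}")
    return TaxonomyTree(nodes)


def write_taxonomy_tsv(tree: TaxonomyTree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("taxid\tparent\trank\tname\n")
        for taxid in sorted(tree.nodes):
            n = tree.nodes[taxid]
            fh.write(f"{n.taxid}\t{n.parent}\t{n.rank}\t{n.name}\n")
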