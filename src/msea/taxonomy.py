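"""Greengenes-style taxonomy trees and taxonomy-derived set libraries.

Lineage strings of the form ``k__Bacteria;p__Firmicutes;...;s__epithet``
are parsed into a rooted forest (one root per kingdom). Converting the tree
into a library — one set per node at a chosen rank, members = the leaf taxa
descending from it — yields a phylogeny-themed microbe-set library: sets at
one rank are disjoint by construction, encoding phylogenetic similarity.

Viral lineages (kingdoms Viruses and Viroids) are excluded because 16S
amplicon profiling, the typical upstream of this package, cannot observe
them. Strain-level tokens (below species) are discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InvalidNameError, InvalidRankError, MalformedLineageError, UnknownEntityError
from .libraries import MicrobeSet, MicrobeSetLibrary
from .names import normalize_taxon_name

__all__ = [
    "RANKS",
    "TaxonomyNode",
    "TaxonomyTree",
    "parse_greengenes_taxonomy",
    "taxonomy_library",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_INDEX = {rank: i for i, rank in enumerate(RANKS)}
_PREFIX_TO_RANK = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
                   "f": "family", "g": "genus", "s": "species"}
_EXCLUDED_KINGDOMS = {"viruses", "viroids"}
_TOKEN = re.compile(r"^([A-Za-z])__(.*)$")


@dataclass(frozen=True)
class TaxonomyNode:
    node_id: str
    name: str
    rank: str
    parent_id: str | None


class TaxonomyTree:
    """Rooted forest of taxonomic units, kingdom through species."""

    def __init__(self):
        self.nodes: dict[str, TaxonomyNode] = {}
        self._children: dict[str, set[str]] = {}

    def __len__(self) -> int:
        return len(self.nodes)

    def is_empty(self) -> bool:
        return not self.nodes

    def add_node(self, node: TaxonomyNode) -> None:
        existing = self.nodes.get(node.node_id)
        if existing is not None:
            if existing.parent_id != node.parent_id:
                raise MalformedLineageError(
                    f"node {node.node_id!r} would have two parents"
                )
            return
        if node.parent_id is not None and node.parent_id not in self.nodes:
            raise MalformedLineageError(f"parent of {node.node_id!r} not in tree")
        self.nodes[node.node_id] = node
        self._children.setdefault(node.node_id, set())
        if node.parent_id is not None:
            self._children.setdefault(node.parent_id, set()).add(node.node_id)

    def children(self, node_id: str) -> frozenset[str]:
        return frozenset(self._children.get(node_id, ()))

    @property
    def leaves(self) -> list[str]:
        """Node ids with no children, in insertion order."""
        return [nid for nid in self.nodes if not self._children.get(nid)]

    def nodes_at_rank(self, rank: str) -> list[TaxonomyNode]:
        if rank not in RANK_INDEX:
            raise InvalidRankError(f"unknown rank {rank!r}")
        return [n for n in self.nodes.values() if n.rank == rank]

    def leaf_descendants(self, node_id: str) -> list[TaxonomyNode]:
        """All leaves in the subtree rooted at ``node_id`` (a leaf is its own)."""
        out = []
        stack = [node_id]
        while stack:
            nid = stack.pop()
            kids = self._children.get(nid)
            if kids:
                stack.extend(kids)
            else:
                out.append(self.nodes[nid])
        return out

    def ancestors(self, node_id: str) -> list[TaxonomyNode]:
        """Path from root to the node, inclusive."""
        path = []
        nid: str | None = node_id
        while nid is not None:
            node = self.nodes[nid]
            path.append(node)
            nid = node.parent_id
        path.reverse()
        return path

    def depth(self, node_id: str) -> int:
        """Number of nodes on the root→node path (kingdom depth = 1)."""
        return len(self.ancestors(node_id))

    @property
    def max_depth(self) -> int:
        if not self.nodes:
            return 0
        return max(self.depth(nid) for nid in self.leaves)

    def leaf_index_by_name(self) -> dict[str, str]:
        """Case-insensitive map from leaf name to node id (first occurrence wins)."""
        index: dict[str, str] = {}
        for nid in self.leaves:
            index.setdefault(self.nodes[nid].name.casefold(), nid)
        return index

    def lineage_similarity(self, name_a: str, name_b: str) -> float:
        """Taxonomic similarity of two leaf taxa in [0, 1].

        Defined as the depth of the deepest shared ancestor divided by the
        maximum leaf depth of the tree: 0 for different kingdoms, 1 for the
        same full-depth leaf.
        """
        index = self.leaf_index_by_name()
        try:
            ida = index[normalize_taxon_name(name_a).casefold()]
            idb = index[normalize_taxon_name(name_b).casefold()]
        except KeyError as exc:
            raise UnknownEntityError(f"leaf not in tree: {exc}") from exc
        path_a = [n.node_id for n in self.ancestors(ida)]
        path_b = [n.node_id for n in self.ancestors(idb)]
        shared = 0
        for ea, eb in zip(path_a, path_b):
            if ea != eb:
                break
            shared += 1
        return shared / self.max_depth


def _parse_tokens(record: str, lineno: int | None) -> list[tuple[int, str]]:
    """Parse one lineage string into [(rank_index, normalized_name), ...]."""
    parsed: list[tuple[int, str]] = []
    genus_name: str | None = None
    last_rank = -1
    for pos, token in enumerate(record.split(";")):
        token = token.strip()
        if not token:
            continue
        m = _TOKEN.match(token)
        if m:
            letter = m.group(1).lower()
            rank = _PREFIX_TO_RANK.get(letter)
            if rank is None:
                # strain-level or unknown designator: discard
                continue
            rank_i = RANK_INDEX[rank]
            body = m.group(2).strip()
            if not body:
                continue
        else:
            if pos >= len(RANKS):
                continue  # positional strain-level token
            rank_i = pos
        try:
            name = normalize_taxon_name(token)
        except InvalidNameError:
            continue
        if rank_i <= last_rank:
            raise MalformedLineageError(
                f"rank order violation in lineage {record!r}"
                + (f" (record {lineno})" if lineno is not None else "")
            )
        last_rank = rank_i
        if rank_i == RANK_INDEX["genus"]:
            genus_name = name
        if rank_i == RANK_INDEX["species"] and genus_name:
            # Greengenes species tokens hold the epithet only; form the binomial.
            if not name.casefold().startswith(genus_name.casefold() + " ") \
                    and name.casefold() != genus_name.casefold():
                name = f"{genus_name} {name}"
        parsed.append((rank_i, name))
    return parsed


def parse_greengenes_taxonomy(records: Iterable[str]) -> TaxonomyTree:
    """Build a taxonomy tree from semicolon-delimited lineage strings.

    One node is created per distinct (rank, name, lineage-prefix); lineages
    sharing a prefix share nodes. Lineages under the Viruses or Viroids
    kingdoms are dropped entirely. Species names are formed as
    ``<genus> <epithet>`` when both tokens are present.

    Raises
    ------
    MalformedLineageError
        If ranks do not strictly deepen along a record.
    """
    tree = TaxonomyTree()
    for lineno, record in enumerate(records, start=1):
        parsed = _parse_tokens(record, lineno)
        if not parsed:
            continue
        first_rank, first_name = parsed[0]
        if first_rank == RANK_INDEX["kingdom"] and first_name.casefold() in _EXCLUDED_KINGDOMS:
            continue
        parent_id: str | None = None
        for rank_i, name in parsed:
            node_id = (f"{parent_id}|" if parent_id else "") + \
                f"{RANKS[rank_i][0]}__{name.casefold()}"
            tree.add_node(TaxonomyNode(node_id, name, RANKS[rank_i], parent_id))
            parent_id = node_id
    return tree


def read_lineages(path) -> TaxonomyTree:
    """Read a taxonomy table: one lineage string per line (TSV first column)."""
    with open(path, encoding="utf-8") as fh:
        records = [line.split("\t")[0].strip() for line in fh if line.strip()]
    return parse_greengenes_taxonomy(records)


def taxonomy_library(
    tree: TaxonomyTree,
    rank: str,
    name: str | None = None,
) -> MicrobeSetLibrary:
    """One microbe-set per node at ``rank``; members = its leaf descendants.

    ``rank`` must be strictly above species (species-level sets would be
    singletons of themselves). Nodes with no leaf descendants are omitted;
    term ids are the node names, disambiguated by full lineage path on
    collision.
    """
    if rank not in RANK_INDEX:
        raise InvalidRankError(f"unknown rank {rank!r}")
    if rank == "species":
        raise InvalidRankError("species-level sets would be singleton self-sets")
    library = MicrobeSetLibrary(name or f"taxonomy-{rank}", provenance="taxonomy")
    nodes = tree.nodes_at_rank(rank)
    label_counts: dict[str, int] = {}
    for node in nodes:
        label_counts[node.name] = label_counts.get(node.name, 0) + 1
    for node in sorted(nodes, key=lambda n: n.node_id):
        if not tree.children(node.node_id):
            continue  # truncated lineage: no taxa below this node
        members = [leaf.name for leaf in tree.leaf_descendants(node.node_id)]
        if not members:
            continue
        term_id = node.name if label_counts[node.name] == 1 else node.node_id
        library.add(MicrobeSet.from_names(term_id, members, term_label=node.name))
    return library
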