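"""Graph and embedding outputs for enrichment results.

Three report types mirror the standard presentations of set-enrichment
output for microbiome data:

* a bipartite graph connecting the top enriched terms (e.g. mammalian
  genes) to their shared microbes, edge weight = the term's combined score,
  node size = degree;
* an overlap network among enriched terms (e.g. pathways), with an edge
  wherever two terms share significantly many members by a one-sided Fisher
  test (BH-corrected p below alpha, default 0.01);
* a 2-D t-SNE embedding of the TF-IDF-weighted microbe × gene matrix, one
  point per microbe, optionally labelled by phylum for coloring.

Graphs are networkx objects exported as GraphML or flat TSV edge lists;
rendering is a thin optional matplotlib layer.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import ContingencyTable, EnrichmentResult, bh_qvalues, fisher_p
from .errors import EmptyResultError, InsufficientDataError, UniverseTooSmallError
from .taxonomy import TaxonomyTree

__all__ = [
    "bipartite_graph",
    "overlap_network",
    "embed_tsne",
    "write_edges_tsv",
    "read_edges_tsv",
    "write_graphml",
    "write_embedding_tsv",
    "plot_bipartite",
    "plot_embedding",
]

logger = logging.getLogger("msea")


def bipartite_graph(results: Sequence[EnrichmentResult], top_k: int = 10) -> nx.Graph:
    """Bipartite graph of the top ``top_k`` terms and their shared microbes.

    One edge per (term, shared member), weighted by the term's combined
    score (weight-0 edges are kept); node attribute ``bipartite`` is 0 for
    terms, 1 for microbes, and ``size`` holds the degree.
    """
    if top_k < 1:
        raise ValueError("top_k must be at least 1")
    if not results:
        raise EmptyResultError("no enrichment results to graph")
    graph = nx.Graph()
    for result in results[:top_k]:
        graph.add_node(result.term_id, bipartite=0)
        for member in sorted(result.shared_members):
            graph.add_node(member, bipartite=1)
            graph.add_edge(result.term_id, member, weight=float(result.combined_score))
    for node in graph.nodes:
        graph.nodes[node]["size"] = graph.degree(node)
    return graph


def overlap_network(
    term_sets: Mapping[str, frozenset[str] | set[str]],
    background_size: int,
    alpha: float = 0.01,
) -> nx.Graph:
    """Connect terms whose member overlap is significant under Fisher's test.

    For every unordered term pair a one-sided Fisher p is computed on the
    2×2 overlap table over a background population of ``background_size``
    members; BH correction runs over all pairs and an edge is drawn iff the
    corrected p < ``alpha``. Nodes carry ``n_members``; edges carry ``p``
    and ``q``.
    """
    terms = list(term_sets)
    if len(terms) < 2:
        raise ValueError("need at least two terms")
    union = set().union(*term_sets.values())
    if background_size < len(union):
        raise UniverseTooSmallError(
            f"background size {background_size} < union of members {len(union)}"
        )
    pairs = list(itertools.combinations(terms, 2))
    ps = []
    overlaps = []
    for t1, t2 in pairs:
        s1, s2 = set(term_sets[t1]), set(term_sets[t2])
        a = len(s1 & s2)
        table = ContingencyTable(
            a, len(s1) - a, len(s2) - a, background_size - len(s1 | s2)
        )
        ps.append(fisher_p(table))
        overlaps.append(a)
    qs = bh_qvalues(ps)
    graph = nx.Graph()
    for term in terms:
        graph.add_node(term, n_members=len(term_sets[term]),
                       members=";".join(sorted(term_sets[term])))
    for (t1, t2), p, q, a in zip(pairs, ps, qs, overlaps):
        if q < alpha:
            graph.add_edge(t1, t2, p=float(p), q=float(q), overlap=int(a))
    return graph


def embed_tsne(
    matrix: pd.DataFrame,
    seed: int,
    perplexity: float = 30.0,
) -> pd.DataFrame:
    """2-D t-SNE embedding of a weighted entity × feature matrix.

    Rows are the embedded entities (microbes); requires at least
    ``3 * perplexity`` rows. Deterministic for a fixed seed; the returned
    coordinates are mean-centered, one (x, y) per row entity.
    """
    from sklearn.manifold import TSNE

    if matrix.shape[0] < 3 * perplexity:
        raise InsufficientDataError(
            f"need at least {int(3 * perplexity)} rows for perplexity "
            f"{perplexity}, got {matrix.shape[0]}"
        )
    values = np.asarray(matrix, dtype=float)
    if not np.isfinite(values).all():
        raise InsufficientDataError("matrix contains non-finite values")
    if values.std() == 0:
        raise InsufficientDataError(
            "matrix has zero variance; nothing to embed"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    coords = np.asarray(tsne.fit_transform(values), dtype=float)
    coords = coords - coords.mean(axis=0, keepdims=True)
    return pd.DataFrame(coords, index=matrix.index, columns=["x", "y"])


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def write_edges_tsv(graph: nx.Graph, path: str | Path) -> None:
    """Flat edge list: source, target, then every edge attribute column."""
    attrs = sorted({k for _, _, d in graph.edges(data=True) for k in d})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["source", "target", *attrs]) + "\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fields = [str(u), str(v)] + [repr(float(data.get(k, float("nan"))))
                                         for k in attrs]
            fh.write("\t".join(fields) + "\n")


def read_edges_tsv(path: str | Path) -> nx.Graph:
    """Read a TSV edge list written by :func:`write_edges_tsv`."""
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        attrs = header[2:]
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            u, v = parts[0], parts[1]
            data = {k: float(x) for k, x in zip(attrs, parts[2:])}
            graph.add_edge(u, v, **data)
    return graph


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_embedding_tsv(
    coords: pd.DataFrame,
    path: str | Path,
    tree: TaxonomyTree | None = None,
) -> None:
    """Write the embedding as TSV (entity, x, y[, phylum]).

    When a taxonomy is supplied each entity is labelled with the phylum of
    its lineage (empty when the entity is not a leaf of the tree).
    """
    phylum_of: dict[str, str] = {}
    if tree is not None:
        index = tree.leaf_index_by_name()
        for entity in coords.index:
            nid = index.get(str(entity).casefold())
            label = ""
            if nid is not None:
                for node in tree.ancestors(nid):
                    if node.rank == "phylum":
                        label = node.name
                        break
            phylum_of[str(entity)] = label
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        columns = ["entity", "x", "y"] + (["phylum"] if tree is not None else [])
        fh.write("\t".join(columns) + "\n")
        for entity, row in coords.iterrows():
            fields = [str(entity), repr(float(row["x"])), repr(float(row["y"]))]
            if tree is not None:
                fields.append(phylum_of[str(entity)])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Optional matplotlib layer
# ---------------------------------------------------------------------------

def plot_bipartite(graph: nx.Graph, ax=None, seed: int = 0):
    """Draw a bipartite term-microbe graph.

    Terms are round blue nodes, microbes red squares; node sizes scale with
    degree and edge widths with |combined score|.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    terms = [n for n, d in graph.nodes(data=True) if d.get("bipartite") == 0]
    microbes = [n for n, d in graph.nodes(data=True) if d.get("bipartite") == 1]
    pos = nx.spring_layout(graph, seed=seed)
    sizes = {n: 100 + 60 * graph.degree(n) for n in graph.nodes}
    widths = [0.5 + abs(d.get("weight", 0.0)) for _, _, d in graph.edges(data=True)]
    nx.draw_networkx_edges(graph, pos, ax=ax, width=widths, alpha=0.4)
    nx.draw_networkx_nodes(graph, pos, nodelist=terms, node_color="tab:blue",
                           node_shape="o", node_size=[sizes[n] for n in terms], ax=ax)
    nx.draw_networkx_nodes(graph, pos, nodelist=microbes, node_color="tab:red",
                           node_shape="s", node_size=[sizes[n] for n in microbes], ax=ax)
    nx.draw_networkx_labels(graph, pos, font_size=7, ax=ax)
    ax.set_axis_off()
    return ax


def plot_embedding(coords: pd.DataFrame, labels: Mapping[str, str] | None = None, ax=None):
    """Scatter the 2-D embedding, colored by an optional label mapping."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    if labels:
        groups: dict[str, list[str]] = {}
        for entity in coords.index:
            groups.setdefault(labels.get(str(entity), ""), []).append(entity)
        for label, entities in sorted(groups.items()):
            sub = coords.loc[entities]
            ax.scatter(sub["x"], sub["y"], s=14, label=label or "unlabelled")
        ax.legend(fontsize=7)
    else:
        ax.scatter(coords["x"], coords["y"], s=14)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    return ax
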