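"""Literature co-mention mining: from a document-entity corpus to gene-centric
microbe-set libraries.

The corpus emulates the output of querying microbe names against abstract
databases with automatic gene-mention recognition: each document carries a
set of microbe mentions and a set of mammalian gene mentions. Association
strength between a microbe and a gene is the Jaccard index of their
mentioning-document sets,

    J(m, g) = |D_m ∩ D_g| / (|D_m| + |D_g| − |D_m ∩ D_g|),

which discounts co-mentions expected by chance for frequently discussed
entities. Thresholding the Jaccard scores at a top fraction of all possible
microbe × gene pairs binarizes the associations; grouping retained microbes
by shared gene yields a gene-centric microbe-set library. TF-IDF weighting
(microbes as documents, genes as terms) supports embedding and
visualization of the association spectrum.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import (
    EmptyCorpusError,
    FormatError,
    NoValidThresholdError,
    UnknownEntityError,
)
from .libraries import MicrobeSet, MicrobeSetLibrary
from .names import normalize_taxon_name
from .taxonomy import TaxonomyTree

__all__ = [
    "MentionCorpus",
    "AssociationMatrix",
    "BinaryAssociations",
    "count_cooccurrence",
    "jaccard_index",
    "jaccard_matrix",
    "threshold_by_top_fraction",
    "select_threshold_by_taxonomy",
    "associations_to_library",
    "tfidf_normalize",
]

logger = logging.getLogger("msea")

DEFAULT_TOP_FRACTION = 0.001  # top 0.1% of all possible microbe-gene pairs


@dataclass
class MentionCorpus:
    """Documents with per-document microbe and gene mention sets.

    Microbe names are normalized, gene symbols upper-cased, and mention
    sets deduplicated at construction.
    """

    documents: dict[str, tuple[frozenset[str], frozenset[str]]] = field(default_factory=dict)

    def add_document(self, doc_id: str, microbes: Iterable[str], genes: Iterable[str]) -> None:
        microbe_set = frozenset(normalize_taxon_name(m) for m in microbes)
        gene_set = frozenset(str(g).strip().upper() for g in genes if str(g).strip())
        self.documents[str(doc_id)] = (microbe_set, gene_set)

    def __len__(self) -> int:
        return len(self.documents)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "MentionCorpus":
        """Build from (document_id, entity_type, entity_name) rows.

        ``entity_type`` must be ``microbe`` or ``gene``.
        """
        microbes: dict[str, set[str]] = {}
        genes: dict[str, set[str]] = {}
        for doc_id, entity_type, entity_name in records:
            doc_id = str(doc_id)
            kind = str(entity_type).strip().lower()
            if kind == "microbe":
                microbes.setdefault(doc_id, set()).add(entity_name)
                genes.setdefault(doc_id, set())
            elif kind == "gene":
                genes.setdefault(doc_id, set()).add(entity_name)
                microbes.setdefault(doc_id, set())
            else:
                raise ValueError(f"unknown entity_type {entity_type!r}")
        corpus = cls()
        for doc_id in microbes:
            corpus.add_document(doc_id, microbes[doc_id], genes[doc_id])
        return corpus

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MentionCorpus":
        """Read a 3-column TSV (document_id, entity_type, entity_name); header optional."""
        records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise FormatError("expected 3 tab-delimited fields", line_number=lineno)
                if lineno == 1 and parts[:2] == ["document_id", "entity_type"]:
                    continue
                records.append((parts[0], parts[1], parts[2]))
        return cls.from_records(records)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("document_id\tentity_type\tentity_name\n")
            for doc_id in sorted(self.documents):
                microbes, genes = self.documents[doc_id]
                for m in sorted(microbes):
                    fh.write(f"{doc_id}\tmicrobe\t{m}\n")
                for g in sorted(genes):
                    fh.write(f"{doc_id}\tgene\t{g}\n")


@dataclass
class AssociationMatrix:
    """Microbe × gene co-mention counts with per-entity document counts."""

    microbes: list[str]
    genes: list[str]
    co_counts: np.ndarray          # shape (n_microbes, n_genes), int
    microbe_doc_counts: np.ndarray  # shape (n_microbes,), int
    gene_doc_counts: np.ndarray     # shape (n_genes,), int

    def __post_init__(self):
        self.co_counts = np.asarray(self.co_counts, dtype=np.int64)
        self.microbe_doc_counts = np.asarray(self.microbe_doc_counts, dtype=np.int64)
        self.gene_doc_counts = np.asarray(self.gene_doc_counts, dtype=np.int64)
        if self.co_counts.shape != (len(self.microbes), len(self.genes)):
            raise ValueError("co_counts shape does not match entity lists")
        if (self.co_counts < 0).any():
            raise ValueError("negative co-counts")
        cap = np.minimum.outer(self.microbe_doc_counts, self.gene_doc_counts)
        if (self.co_counts > cap).any():
            raise ValueError("co-count exceeds a marginal document count")
        self._microbe_index = {m: i for i, m in enumerate(self.microbes)}
        self._gene_index = {g: j for j, g in enumerate(self.genes)}

    def microbe_idx(self, microbe: str) -> int:
        try:
            return self._microbe_index[microbe]
        except KeyError as exc:
            raise UnknownEntityError(f"unknown microbe {microbe!r}") from exc

    def gene_idx(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError as exc:
            raise UnknownEntityError(f"unknown gene {gene!r}") from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.co_counts, index=self.microbes, columns=self.genes)


@dataclass
class BinaryAssociations:
    """Retained microbe-gene pairs after top-fraction thresholding."""

    pairs: frozenset[tuple[str, str]]
    threshold: float   # realized Jaccard cutoff
    fraction: float    # requested top fraction

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path, matrix: AssociationMatrix | None = None) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("microbe\tgene\tjaccard\n")
            for microbe, gene in sorted(self.pairs):
                score = (jaccard_index(matrix, microbe, gene)
                         if matrix is not None else float("nan"))
                fh.write(f"{microbe}\t{gene}\t{score:.6g}\n")


def count_cooccurrence(corpus: MentionCorpus) -> AssociationMatrix:
    """Count, for every microbe-gene pair, the documents mentioning both.

    Marginal counts tally every document mentioning the entity at all, so a
    document with only microbe mentions still contributes to microbe
    marginals (and hence to Jaccard denominators).

    Raises
    ------
    EmptyCorpusError
        If no document carries both a microbe and a gene mention.
    """
    if not any(ms and gs for ms, gs in corpus.documents.values()):
        raise EmptyCorpusError("no document mentions both a microbe and a gene")
    microbes = sorted({m for ms, _ in corpus.documents.values() for m in ms})
    genes = sorted({g for _, gs in corpus.documents.values() for g in gs})
    m_index = {m: i for i, m in enumerate(microbes)}
    g_index = {g: j for j, g in enumerate(genes)}
    n_docs = len(corpus.documents)
    M = np.zeros((n_docs, len(microbes)), dtype=np.int64)
    G = np.zeros((n_docs, len(genes)), dtype=np.int64)
    for d, (ms, gs) in enumerate(corpus.documents.values()):
        for m in ms:
            M[d, m_index[m]] = 1
        for g in gs:
            G[d, g_index[g]] = 1
    co = M.T @ G
    return AssociationMatrix(microbes, genes, co, M.sum(axis=0), G.sum(axis=0))


def jaccard_index(matrix: AssociationMatrix, microbe: str, gene: str) -> float:
    """Jaccard index of the two entities' mentioning-document sets.

    Returns 0 by convention when both marginals are zero.
    """
    i = matrix.microbe_idx(microbe)
    j = matrix.gene_idx(gene)
    co = int(matrix.co_counts[i, j])
    denom = int(matrix.microbe_doc_counts[i]) + int(matrix.gene_doc_counts[j]) - co
    if denom == 0:
        return 0.0
    return co / denom


def jaccard_matrix(matrix: AssociationMatrix) -> np.ndarray:
    """Vectorized Jaccard scores for every microbe × gene pair."""
    co = matrix.co_counts.astype(float)
    denom = (matrix.microbe_doc_counts[:, None]
             + matrix.gene_doc_counts[None, :] - co)
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(denom > 0, co / np.where(denom > 0, denom, 1.0), 0.0)
    return J


def threshold_by_top_fraction(
    matrix: AssociationMatrix,
    fraction: float = DEFAULT_TOP_FRACTION,
) -> BinaryAssociations:
    """Retain the top ``fraction`` of all possible pairs by Jaccard score.

    "All possible pairs" is the full |microbes| × |genes| grid including
    zero-score pairs, so the default 0.001 keeps roughly the top 0.1% of the
    grid. Ties at the cut are all retained (the pair count may then exceed
    ``ceil(fraction * grid)``); zero-score pairs are never retained. The
    realized cutoff (the smallest retained score) is reported.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    J = jaccard_matrix(matrix)
    total = J.size
    k = math.ceil(fraction * total)
    flat = J.ravel()
    positive = flat[flat > 0]
    if positive.size == 0:
        return BinaryAssociations(frozenset(), float("nan"), fraction)
    if positive.size <= k:
        threshold = float(positive.min())
    else:
        threshold = float(np.sort(positive)[::-1][k - 1])
    keep = J >= threshold
    pairs = frozenset(
        (matrix.microbes[i], matrix.genes[j]) for i, j in zip(*np.nonzero(keep))
    )
    return BinaryAssociations(pairs, threshold, fraction)


def _gene_profiles(assoc: BinaryAssociations) -> dict[str, frozenset[str]]:
    """Per-microbe retained gene sets."""
    profiles: dict[str, set[str]] = {}
    for microbe, gene in assoc.pairs:
        profiles.setdefault(microbe, set()).add(gene)
    return {m: frozenset(gs) for m, gs in profiles.items()}


def select_threshold_by_taxonomy(
    matrix: AssociationMatrix,
    tree: TaxonomyTree,
    candidates: Sequence[float],
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> tuple[float, dict[float, float]]:
    """Pick the binarization fraction that best agrees with the taxonomy.

    For each candidate fraction the associations are binarized and each
    microbe receives its retained gene set. Over all microbe pairs present
    in the taxonomy tree, the Spearman rank correlation between gene-set
    Jaccard similarity and taxonomic similarity (depth of the deepest shared
    ancestor over the tree's maximum depth) is computed; the candidate
    maximizing the correlation wins. Candidates yielding an all-zero
    binarization (or a constant similarity vector) are skipped with a
    warning.

    The correlation statistic is pluggable via ``statistic`` (a callable on
    the two per-pair similarity vectors returning a scalar); Spearman's rho
    is the default.

    Returns
    -------
    (best_fraction, per_candidate_statistic)

    Raises
    ------
    NoValidThresholdError
        If every candidate is degenerate.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate fractions")
    index = tree.leaf_index_by_name()
    shared_microbes = [m for m in matrix.microbes if m.casefold() in index]
    if len(shared_microbes) < 2:
        raise NoValidThresholdError("fewer than two matrix microbes present in the tree")
    pair_list = [(a, b) for i, a in enumerate(shared_microbes)
                 for b in shared_microbes[i + 1:]]
    tax_sim = np.array([tree.lineage_similarity(a, b) for a, b in pair_list])

    def default_statistic(x: np.ndarray, y: np.ndarray) -> float:
        rho = spearmanr(x, y).statistic
        return float(rho)

    stat = statistic or default_statistic
    results: dict[float, float] = {}
    for fraction in candidates:
        assoc = threshold_by_top_fraction(matrix, fraction)
        if not assoc.pairs:
            logger.warning("candidate fraction %g yields no retained pairs; skipped", fraction)
            results[fraction] = float("nan")
            continue
        profiles = _gene_profiles(assoc)
        gene_sim = np.empty(len(pair_list))
        for p, (a, b) in enumerate(pair_list):
            ga = profiles.get(a, frozenset())
            gb = profiles.get(b, frozenset())
            union = len(ga | gb)
            gene_sim[p] = len(ga & gb) / union if union else 0.0
        if np.ptp(gene_sim) == 0 or np.ptp(tax_sim) == 0:
            logger.warning("candidate fraction %g yields a constant similarity vector; skipped",
                           fraction)
            results[fraction] = float("nan")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results[fraction] = stat(gene_sim, tax_sim)
    valid = {f: s for f, s in results.items() if np.isfinite(s)}
    if not valid:
        raise NoValidThresholdError("all candidate fractions are degenerate")
    best = max(valid, key=lambda f: valid[f])
    return best, results


def associations_to_library(
    assoc: BinaryAssociations,
    name: str = "literature",
) -> MicrobeSetLibrary:
    """Group retained microbes by shared gene into a gene-centric library.

    One set per gene; members are the microbes retained for it. Genes with
    no retained microbes do not appear.
    """
    if not assoc.pairs:
        raise EmptyCorpusError("no retained associations to organize into sets")
    by_gene: dict[str, list[str]] = {}
    for microbe, gene in assoc.pairs:
        by_gene.setdefault(gene, []).append(microbe)
    library = MicrobeSetLibrary(name, provenance="literature")
    for gene in sorted(by_gene):
        library.add(MicrobeSet.from_names(gene, by_gene[gene], term_label=gene))
    return library


def tfidf_normalize(matrix: AssociationMatrix) -> pd.DataFrame:
    """TF-IDF weighting of the co-mention matrix, microbes as documents.

    tf[i, j] is the row-normalized co-count; idf[j] = ln(N / df_j) where
    df_j counts microbes with a nonzero co-count for gene j. A gene
    co-mentioned with every microbe weighs zero everywhere (idf = 0),
    making the "offset ubiquitous entities" rationale literal; microbes
    with an all-zero row stay all-zero.
    """
    co = matrix.co_counts.astype(float)
    row_sums = co.sum(axis=1, keepdims=True)
    tf = np.divide(co, row_sums, out=np.zeros_like(co), where=row_sums > 0)
    df = (co > 0).sum(axis=0)
    n_microbes = co.shape[0]
    idf = np.where(df > 0, np.log(n_microbes / np.where(df > 0, df, 1)), 0.0)
    return pd.DataFrame(tf * idf, index=matrix.microbes, columns=matrix.genes)
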