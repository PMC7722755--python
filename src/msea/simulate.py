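"""Seeded generators for every input the package consumes.

The generators plant known structure so that each pipeline stage can be
validated end to end without any external download: a mention corpus with
planted microbe-gene co-occurrence, a set library with a planted enriched
term, and a balanced toy taxonomy. All generators are pure functions of
their specification: the same spec (including seed) reproduces the same
output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SimulationSpecError
from .libraries import MicrobeSet, MicrobeSetLibrary
from .literature import MentionCorpus
from .taxonomy import TaxonomyTree, parse_greengenes_taxonomy

__all__ = [
    "PlantedCorpusSpec",
    "PlantedEnrichmentSpec",
    "make_mention_corpus",
    "make_planted_library",
    "make_toy_taxonomy",
]


def _validate_rate(value: float, label: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise SimulationSpecError(f"{label} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class PlantedCorpusSpec:
    """Specification of a mention corpus with planted co-occurrence.

    Each of ``n_docs`` documents mentions every microbe and every gene
    independently with probability ``background_rate``; each planted
    ``(microbe_index, gene_index, co_rate)`` triple additionally inserts
    both entities jointly with probability ``co_rate`` per document.
    """

    n_docs: int = 500
    n_microbes: int = 20
    n_genes: int = 20
    background_rate: float = 0.02
    planted_pairs: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if min(self.n_docs, self.n_microbes, self.n_genes) < 1:
            raise SimulationSpecError("corpus dimensions must be positive")
        _validate_rate(self.background_rate, "background_rate")
        for mi, gi, rate in self.planted_pairs:
            if not (0 <= mi < self.n_microbes) or not (0 <= gi < self.n_genes):
                raise SimulationSpecError(
                    f"planted pair ({mi}, {gi}) outside declared entity ranges"
                )
            _validate_rate(rate, "co_rate")


@dataclass(frozen=True)
class PlantedEnrichmentSpec:
    """Specification of a set library with one planted enriched term.

    ``n_terms`` sets are drawn uniformly from a universe of
    ``universe_size`` named microbes with sizes uniform over
    ``set_size_range``; an input of ``input_size`` microbes is drawn, and
    the planted term is rebuilt to share exactly ``planted_term_overlap``
    members with it.
    """

    universe_size: int = 1000
    n_terms: int = 30
    set_size_range: tuple[int, int] = (10, 50)
    planted_term_overlap: int = 10
    input_size: int = 20
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise SimulationSpecError(f"bad set_size_range {self.set_size_range}")
        if self.planted_term_overlap > min(self.input_size, hi):
            raise SimulationSpecError(
                f"overlap {self.planted_term_overlap} exceeds "
                f"min(input_size, max set size)"
            )
        if self.planted_term_overlap < 0 or self.input_size < 1 or self.n_terms < 1:
            raise SimulationSpecError("counts must be non-negative (input, terms positive)")
        if self.universe_size < max(hi, self.input_size + hi):
            raise SimulationSpecError("universe too small for the requested sets")


def microbe_names(n: int, prefix: str = "M") -> list[str]:
    """Systematic entity names ("M0001"...) that normalization leaves alone."""
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def make_mention_corpus(spec: PlantedCorpusSpec, greengenes_style: bool = False) -> MentionCorpus:
    """Generate a mention corpus per the planted-corpus specification.

    With ``greengenes_style`` microbe names are emitted with rank prefixes
    and placeholder suffixes (``g__M0001_noname``) to exercise name
    normalization downstream; the normalized corpus is identical either way.
    """
    rng = np.random.default_rng(spec.seed)
    microbes = microbe_names(spec.n_microbes, "M")
    genes = microbe_names(spec.n_genes, "G")
    emit = (lambda m: f"g__{m}_noname") if greengenes_style else (lambda m: m)
    corpus = MentionCorpus()
    width = max(4, len(str(spec.n_docs)))
    for d in range(spec.n_docs):
        m_mask = rng.random(spec.n_microbes) < spec.background_rate
        g_mask = rng.random(spec.n_genes) < spec.background_rate
        doc_microbes = {microbes[i] for i in np.nonzero(m_mask)[0]}
        doc_genes = {genes[j] for j in np.nonzero(g_mask)[0]}
        for mi, gi, co_rate in spec.planted_pairs:
            if rng.random() < co_rate:
                doc_microbes.add(microbes[mi])
                doc_genes.add(genes[gi])
        corpus.add_document(
            f"D{d + 1:0{width}d}", {emit(m) for m in doc_microbes}, doc_genes
        )
    return corpus


def make_planted_library(
    spec: PlantedEnrichmentSpec,
) -> tuple[MicrobeSetLibrary, frozenset[str], str]:
    """Generate (library, input set, planted term id) per the specification.

    Non-planted terms are uniform draws from the universe; the planted term
    (always the first, ``T0001``) contains exactly
    ``spec.planted_term_overlap`` input members plus filler drawn outside
    the input. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    universe = np.array(microbe_names(spec.universe_size, "M"))
    lo, hi = spec.set_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_terms)
    input_idx = rng.choice(spec.universe_size, size=spec.input_size, replace=False)
    input_set = frozenset(universe[input_idx])
    width = max(4, len(str(spec.n_terms)))
    term_ids = [f"T{i + 1:0{width}d}" for i in range(spec.n_terms)]
    planted_id = term_ids[0]
    library = MicrobeSetLibrary("planted", provenance="user")
    non_input_idx = np.setdiff1d(np.arange(spec.universe_size), input_idx)
    for i, term_id in enumerate(term_ids):
        if term_id == planted_id:
            size = max(int(sizes[i]), spec.planted_term_overlap)
            overlap_members = rng.choice(input_idx, size=spec.planted_term_overlap,
                                         replace=False)
            n_fill = size - spec.planted_term_overlap
            fill = rng.choice(non_input_idx, size=n_fill, replace=False)
            idx = np.concatenate([overlap_members, fill])
        else:
            idx = rng.choice(spec.universe_size, size=int(sizes[i]), replace=False)
        library.add(MicrobeSet.from_names(term_id, universe[idx], term_label=term_id))
    return library, input_set, planted_id


def make_toy_taxonomy(
    n_phyla: int,
    genera_per_phylum: int,
    species_per_genus: int,
    seed: int = 0,
) -> TaxonomyTree:
    """Balanced toy taxonomy with systematic names.

    One kingdom (Bacteria), ``n_phyla`` phyla each holding
    ``genera_per_phylum`` genera of ``species_per_genus`` species; lineages
    run kingdom → phylum → genus → species. Fully systematic and
    deterministic; ``seed`` is accepted for generator-API symmetry but does
    not influence the output.
    """
    if min(n_phyla, genera_per_phylum, species_per_genus) < 1:
        raise SimulationSpecError("taxonomy counts must be positive")
    records = []
    for p in range(1, n_phyla + 1):
        for g in range(1, genera_per_phylum + 1):
            for s in range(1, species_per_genus + 1):
                records.append(
                    f"k__Bacteria;p__Phylum{p:02d};"
                    f"g__Genus{p:02d}x{g:02d};s__sp{s:02d}"
                )
    return parse_greengenes_taxonomy(records)


def write_lineages(tree: TaxonomyTree, path) -> None:
    """Write a taxonomy tree as one prefixed lineage string per leaf."""
    rank_letter = {"kingdom": "k", "phylum": "p", "class": "c", "order": "o",
                   "family": "f", "genus": "g", "species": "s"}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for leaf_id in sorted(tree.leaves):
            tokens = []
            genus = None
            for node in tree.ancestors(leaf_id):
                name = node.name
                if node.rank == "genus":
                    genus = name
                if node.rank == "species" and genus and \
                        name.casefold().startswith(genus.casefold() + " "):
                    name = name[len(genus) + 1:]
                tokens.append(f"{rank_letter[node.rank]}__{name.replace(' ', '_')}")
            fh.write(";".join(tokens) + "\n")
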