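"""The microbe-set enrichment statistic (MSEA).

Given an input microbe list (typically taxa with differential abundance
between conditions) and a microbe-set library, every library term is tested
for over-representation with a one-sided Fisher's exact test under a fixed
universe. Fisher-style proportion tests are biased toward large sets, so
the observed rank of each term is corrected against a Monte-Carlo null:
random inputs of the same size are drawn from the universe, every term is
ranked by p-value per draw, and the per-term rank mean and standard
deviation define a z-score for the observed rank,

    z = (observed_rank − mean_null_rank) / sd_null_rank.

Significance and rank surprise are blended into a combined score

    c = log10(p) · z,

so better-than-expected ranks (negative z) with small p give large positive
scores. The machinery is generic over any set library: the same engine runs
on gene-set libraries for downstream pathway analysis.

The universe (denominator population of the Fisher test) is the union of
everything the profiling pipeline can possibly identify and every name in
the library; when neither is supplied explicitly a default size of 1000 is
used, matching the scale of genus-level 16S reference taxonomies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .errors import (
    DomainError,
    EmptyInputError,
    EmptyLibraryError,
    UniverseTooSmallError,
    UnknownEntityError,
)
from .libraries import MicrobeSetLibrary, canonical_members
from .names import normalize_taxon_name

__all__ = [
    "DEFAULT_UNIVERSE_SIZE",
    "DEFAULT_NULL_REPS",
    "Universe",
    "ContingencyTable",
    "NullRankModel",
    "EnrichmentResult",
    "determine_universe",
    "build_contingency",
    "fisher_p",
    "fisher_sf",
    "odds_ratio",
    "bh_qvalues",
    "null_rank_model",
    "zscore",
    "combined_score",
    "msea",
]

logger = logging.getLogger("msea")

DEFAULT_UNIVERSE_SIZE = 1000
DEFAULT_NULL_REPS = 10_000
_P_FLOOR = 1e-300  # guards log10 against underflowed p-values


@dataclass(frozen=True)
class Universe:
    """The population the Fisher test draws from.

    ``members`` is the named portion (library union plus any profiled-taxa
    list); ``size`` may exceed the named count, the remainder standing for
    taxa the profiling pipeline can identify but that appear in no set.
    """

    members: frozenset[str]
    size: int

    def __post_init__(self):
        if self.size < len(self.members):
            raise UniverseTooSmallError(
                f"universe size {self.size} < {len(self.members)} named members"
            )
        object.__setattr__(self, "members", frozenset(self.members))

    @property
    def has_anonymous_capacity(self) -> bool:
        return self.size > len(self.members)

    def casefold_members(self) -> frozenset[str]:
        return frozenset(m.casefold() for m in self.members)


def determine_universe(
    library: MicrobeSetLibrary,
    profiled_taxa: Iterable[str] | None = None,
    size: int | None = None,
    default_size: int = DEFAULT_UNIVERSE_SIZE,
) -> Universe:
    """Resolve the test universe from a library and optional profiling info.

    The named portion is the library's member union plus ``profiled_taxa``
    when given. The size is, in order of precedence: the explicit ``size``
    (error if smaller than the named portion); the named-portion size when a
    profiled list is supplied; otherwise ``default_size`` (grown to the
    named portion if that is larger).
    """
    if not library.sets:
        raise EmptyLibraryError("library has no sets")
    named = set(library.member_union)
    if profiled_taxa is not None:
        named |= set(canonical_members(profiled_taxa))
    named = canonical_members(named, normalize=False)
    if size is not None:
        if size < len(named):
            raise UniverseTooSmallError(
                f"explicit universe size {size} < {len(named)} named members"
            )
        return Universe(frozenset(named), size)
    if profiled_taxa is not None:
        return Universe(frozenset(named), len(named))
    return Universe(frozenset(named), max(default_size, len(named)))


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 overlap table: a=input∩set, b=input-only, c=set-only, d=rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError(f"negative contingency cell in {self}")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def set_size(self) -> int:
        return self.a + self.c

    @property
    def input_size(self) -> int:
        return self.a + self.b


def filter_to_universe(input_set: Iterable[str], universe: Universe) -> frozenset[str]:
    """Drop input members that cannot belong to the universe.

    With anonymous capacity (size beyond the named portion) unknown names
    are kept — they stand for profiled taxa absent from every set. In a
    fully named universe unknown names are dropped with a logged warning.
    """
    members = canonical_members(input_set)
    if universe.has_anonymous_capacity:
        return members
    named_cf = universe.casefold_members()
    kept, dropped = [], []
    for m in members:
        (kept if m.casefold() in named_cf else dropped).append(m)
    if dropped:
        logger.warning(
            "dropping %d input member(s) outside the universe: %s",
            len(dropped), ", ".join(sorted(dropped)),
        )
    return frozenset(kept)


def build_contingency(
    input_set: Iterable[str],
    term_set: Iterable[str],
    universe: Universe,
) -> ContingencyTable:
    """Overlap table of an input set and a term set under the universe.

    Input members outside the universe are dropped first (see
    :func:`filter_to_universe`); matching is case-insensitive.

    Raises
    ------
    EmptyInputError
        If nothing remains of the input after filtering.
    """
    inp = filter_to_universe(input_set, universe)
    if not inp:
        raise EmptyInputError("input set is empty after universe filtering")
    term_cf = {str(t).casefold() for t in term_set}
    a = sum(1 for m in inp if m.casefold() in term_cf)
    b = len(inp) - a
    c = len(term_cf) - a
    d = universe.size - a - b - c
    if d < 0:
        raise UniverseTooSmallError(
            f"universe size {universe.size} cannot hold input ({len(inp)}) "
            f"and set ({len(term_cf)}) with overlap {a}"
        )
    return ContingencyTable(a, b, c, d)


def fisher_sf(a: np.ndarray | int, N: int, K: int, n: int) -> np.ndarray:
    """P(X ≥ a) for X ~ Hypergeometric(N, K, n), vectorized over ``a``.

    This single kernel backs every Fisher p-value in the package.
    """
    a = np.asarray(a)
    p = hypergeom.sf(a - 1, N, K, n)
    return np.clip(p, 0.0, 1.0)


def fisher_p(table: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher exact p-value for a 2×2 table.

    Equals the hypergeometric upper tail P(X ≥ a) with population N,
    K = a + c successes, and n = a + b draws.
    """
    p = float(fisher_sf(table.a, table.N, table.set_size, table.input_size))
    return min(1.0, p)


def odds_ratio(table: ContingencyTable) -> float:
    """Sample odds ratio (a·d)/(b·c), Haldane–Anscombe corrected.

    When any cell is zero, 0.5 is added to every cell before forming the
    ratio, keeping the estimate finite.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values over all tested terms."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if (pvalues <= 0).any() or (pvalues > 1).any():
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


@dataclass
class NullRankModel:
    """Per-term null distribution of p-value ranks under random inputs.

    Random inputs of fixed size are drawn uniformly without replacement
    from the universe; for each draw every term is scored by Fisher p and
    ranked ascending (average ranks on ties). The per-term mean and sample
    standard deviation over the repetitions calibrate observed ranks.
    """

    input_size: int
    universe_size: int
    reps: int
    seed: int
    term_ids: list[str]
    mean_rank: np.ndarray
    sd_rank: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {t: i for i, t in enumerate(self.term_ids)}

    def term_stats(self, term_id: str) -> tuple[float, float]:
        try:
            i = self._index[term_id]
        except KeyError as exc:
            raise UnknownEntityError(f"term {term_id!r} not in null model") from exc
        return float(self.mean_rank[i]), float(self.sd_rank[i])

    def is_degenerate(self, term_id: str) -> bool:
        return self.term_stats(term_id)[1] == 0.0


def _term_membership(
    library: MicrobeSetLibrary, universe: Universe
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Boolean term × universe membership matrix (anonymous slots all-false)."""
    term_ids = list(library.sets)
    named = sorted(universe.members)
    index = {m.casefold(): i for i, m in enumerate(named)}
    memb = np.zeros((len(term_ids), universe.size), dtype=bool)
    for t, term_id in enumerate(term_ids):
        for m in library.sets[term_id].members:
            i = index.get(m.casefold())
            if i is not None:
                memb[t, i] = True
    K = memb.sum(axis=1).astype(np.int64)
    return term_ids, memb, K


def null_rank_model(
    library: MicrobeSetLibrary,
    input_size: int,
    universe: Universe,
    reps: int = DEFAULT_NULL_REPS,
    seed: int = 0,
) -> NullRankModel:
    """Monte-Carlo expected-rank model for a library at one input size.

    Deterministic given ``seed`` (a dedicated numpy Generator is used).
    """
    if reps < 2:
        raise ValueError("reps must be at least 2")
    if input_size < 1:
        raise ValueError("input_size must be positive")
    if input_size > universe.size:
        raise ValueError(
            f"input_size {input_size} exceeds universe size {universe.size}"
        )
    term_ids, memb, K = _term_membership(library, universe)
    T = len(term_ids)
    N = universe.size
    n = input_size
    # p depends on the overlap a only through (a, K): precompute lookup rows.
    a_max = int(min(n, K.max() if T else 0))
    lookup = np.ones((T, a_max + 2))
    for t in range(T):
        hi = int(min(n, K[t]))
        lookup[t, : hi + 1] = fisher_sf(np.arange(hi + 1), N, int(K[t]), n)
        lookup[t, hi + 1:] = lookup[t, hi]
    rng = np.random.default_rng(seed)
    rank_sum = np.zeros(T)
    rank_sqsum = np.zeros(T)
    rows = np.arange(T)
    for _ in range(reps):
        idx = rng.choice(N, size=n, replace=False)
        a_obs = memb[:, idx].sum(axis=1)
        p = lookup[rows, a_obs]
        r = rankdata(p)
        rank_sum += r
        rank_sqsum += r * r
    mean = rank_sum / reps
    var = np.maximum(rank_sqsum - reps * mean**2, 0.0) / (reps - 1)
    return NullRankModel(
        input_size=input_size,
        universe_size=N,
        reps=reps,
        seed=seed,
        term_ids=term_ids,
        mean_rank=mean,
        sd_rank=np.sqrt(var),
    )


def zscore(observed_rank: float, model: NullRankModel, term_id: str) -> float:
    """Standardize an observed rank against the term's null rank distribution.

    Better-than-expected (smaller) ranks give negative z. A term whose null
    rank never varies (sd = 0) gets z = 0; such terms are flagged via
    :meth:`NullRankModel.is_degenerate`.
    """
    mean, sd = model.term_stats(term_id)
    if sd == 0.0:
        return 0.0
    return (observed_rank - mean) / sd


def combined_score(p: float, z: float) -> float:
    """Combined enrichment score c = log10(p) · z.

    Zero when p = 1 or z = 0; positive when a small p meets a
    better-than-expected rank (negative z).
    """
    if not (0 < p <= 1):
        raise DomainError(f"p-value must be in (0, 1], got {p}")
    return math.log10(p) * z


@dataclass(frozen=True)
class EnrichmentResult:
    """Full test result for one library term."""

    term_id: str
    shared_members: frozenset[str]
    overlap: int
    set_size: int
    input_size: int
    odds_ratio: float
    p_value: float
    q_value: float
    rank: float
    z_score: float
    combined_score: float
    z_degenerate: bool = False

    def __post_init__(self):
        if self.overlap != len(self.shared_members):
            raise ValueError("overlap does not equal |shared_members|")


def msea(
    input_set: Iterable[str],
    library: MicrobeSetLibrary,
    universe: Universe | None = None,
    reps: int = DEFAULT_NULL_REPS,
    seed: int = 0,
    sort: str = "p",
    null_model: NullRankModel | None = None,
) -> list[EnrichmentResult]:
    """Run microbe-set enrichment analysis of an input set against a library.

    Every term is tested; results carry the one-sided Fisher p, BH q over
    all terms of the library, the observed p-value rank (ascending, average
    ties), the rank z-score against the Monte-Carlo null at the input's
    cardinality, and the combined score. ``sort`` orders results by
    ascending p (``"p"``, default) or descending combined score
    (``"combined"``).

    A precomputed ``null_model`` (matching the filtered input size) can be
    supplied to amortize the Monte-Carlo cost across runs.
    """
    if sort not in ("p", "combined"):
        raise ValueError(f"sort must be 'p' or 'combined', got {sort!r}")
    if universe is None:
        universe = determine_universe(library)
    inp = filter_to_universe(input_set, universe)
    if not inp:
        raise EmptyInputError("input set is empty after universe filtering")
    term_ids = list(library.sets)
    inp_cf = {m.casefold() for m in inp}
    tables: list[ContingencyTable] = []
    shared: list[frozenset[str]] = []
    for term_id in term_ids:
        members = library.sets[term_id].members
        overlap = frozenset(m for m in members if m.casefold() in inp_cf)
        a = len(overlap)
        b = len(inp) - a
        c = len(members) - a
        d = universe.size - a - b - c
        if d < 0:
            raise UniverseTooSmallError(
                f"universe size {universe.size} too small for term {term_id!r}"
            )
        tables.append(ContingencyTable(a, b, c, d))
        shared.append(overlap)
    ps = np.array([fisher_p(t) for t in tables])
    ranks = rankdata(ps)
    qs = bh_qvalues(ps)
    if null_model is None:
        null_model = null_rank_model(library, len(inp), universe, reps=reps, seed=seed)
    elif null_model.input_size != len(inp):
        raise ValueError(
            f"null model input size {null_model.input_size} does not match "
            f"filtered input size {len(inp)}"
        )
    results = []
    for i, term_id in enumerate(term_ids):
        z = zscore(ranks[i], null_model, term_id)
        p_safe = max(ps[i], _P_FLOOR)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                shared_members=shared[i],
                overlap=tables[i].a,
                set_size=tables[i].set_size,
                input_size=tables[i].input_size,
                odds_ratio=odds_ratio(tables[i]),
                p_value=float(ps[i]),
                q_value=float(qs[i]),
                rank=float(ranks[i]),
                z_score=float(z),
                combined_score=combined_score(float(p_safe), float(z)),
                z_degenerate=null_model.is_degenerate(term_id),
            )
        )
    if sort == "p":
        results.sort(key=lambda r: (r.p_value, r.term_id))
    else:
        results.sort(key=lambda r: (-r.combined_score, r.term_id))
    return results
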