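"""Model/Results interface to microbe-set enrichment analysis.

``MSEA`` is constructed from an input microbe set and a set library (plus
optional universe information); ``fit`` runs the full procedure — Fisher
tests, BH correction, Monte-Carlo rank calibration, combined scores — and
returns an :class:`MSEAResults` carrying the per-term estimates, a tidy
DataFrame, a text summary table and graph constructors.

>>> model = MSEA(["Bacteroides", "Akkermansia"], library)
>>> res = model.fit(reps=1000, seed=0)
>>> print(res.summary(top=5))
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .enrichment import (
    DEFAULT_NULL_REPS,
    EnrichmentResult,
    NullRankModel,
    Universe,
    determine_universe,
    filter_to_universe,
    msea,
)
from .errors import EmptyInputError
from .libraries import MicrobeSetLibrary, read_gmt

__all__ = ["MSEA", "MSEAResults", "RESULT_COLUMNS"]

RESULT_COLUMNS = [
    "term_id", "overlap", "set_size", "input_size", "shared_members",
    "odds_ratio", "p_value", "q_value", "rank", "z_score", "combined_score",
]


class MSEA:
    """Microbe-set enrichment analysis model.

    Parameters
    ----------
    input_set:
        Microbe names to test (normalized internally), e.g. taxa with
        differential abundance between conditions.
    library:
        The annotated microbe-set library to test against.
    universe:
        An explicit :class:`~msea.enrichment.Universe`; mutually exclusive
        with the two options below.
    profiled_taxa:
        Names the upstream profiling pipeline can identify; unioned with the
        library members to form the universe.
    universe_size:
        Explicit universe size; defaults to 1000 when nothing else is given.
    """

    def __init__(
        self,
        input_set: Iterable[str],
        library: MicrobeSetLibrary,
        universe: Universe | None = None,
        profiled_taxa: Iterable[str] | None = None,
        universe_size: int | None = None,
    ):
        self.library = library
        if universe is None:
            universe = determine_universe(
                library, profiled_taxa=profiled_taxa, size=universe_size
            )
        elif profiled_taxa is not None or universe_size is not None:
            raise ValueError("pass either a Universe or its ingredients, not both")
        self.universe = universe
        self.input_set = filter_to_universe(input_set, universe)
        if not self.input_set:
            raise EmptyInputError("input set is empty after universe filtering")

    @classmethod
    def from_files(
        cls,
        library_path: str | Path,
        input_path: str | Path,
        universe_file: str | Path | None = None,
        universe_size: int | None = None,
    ) -> "MSEA":
        """Build a model from a GMT library and a one-name-per-line input list."""
        library = read_gmt(library_path)
        input_set = _read_name_list(input_path)
        profiled = _read_name_list(universe_file) if universe_file else None
        return cls(input_set, library, profiled_taxa=profiled, universe_size=universe_size)

    def fit(
        self,
        reps: int = DEFAULT_NULL_REPS,
        seed: int = 0,
        sort: str = "p",
        null_model: NullRankModel | None = None,
    ) -> "MSEAResults":
        """Run the enrichment procedure and return the results object."""
        results = msea(
            self.input_set,
            self.library,
            universe=self.universe,
            reps=reps,
            seed=seed,
            sort=sort,
            null_model=null_model,
        )
        return MSEAResults(self, results, reps=reps, seed=seed, sort=sort)


class MSEAResults:
    """Fitted enrichment results: per-term statistics and reporting helpers."""

    def __init__(
        self,
        model: MSEA,
        results: list[EnrichmentResult],
        reps: int,
        seed: int,
        sort: str,
    ):
        self.model = model
        self.results = results
        self.reps = reps
        self.seed = seed
        self.sort = sort

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-term results; shared members ;-joined and sorted."""
        rows = [
            {
                "term_id": r.term_id,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "input_size": r.input_size,
                "shared_members": ";".join(sorted(r.shared_members)),
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "rank": r.rank,
                "z_score": r.z_score,
                "combined_score": r.combined_score,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        """Write the results table as TSV (deterministic float formatting)."""
        frame = self.to_frame()
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(RESULT_COLUMNS) + "\n")
            for _, row in frame.iterrows():
                fields = [
                    row["term_id"],
                    str(int(row["overlap"])),
                    str(int(row["set_size"])),
                    str(int(row["input_size"])),
                    row["shared_members"],
                    repr(float(row["odds_ratio"])),
                    repr(float(row["p_value"])),
                    repr(float(row["q_value"])),
                    repr(float(row["rank"])),
                    repr(float(row["z_score"])),
                    repr(float(row["combined_score"])),
                ]
                fh.write("\t".join(fields) + "\n")

    def summary(self, top: int = 10) -> str:
        """Human-readable summary: run parameters and the top enriched terms."""
        frame = self.to_frame().head(top).copy()
        frame["shared_members"] = frame["shared_members"].str.slice(0, 40)
        header = [
            "Microbe-Set Enrichment Analysis",
            "=" * 31,
            f"Library:        {self.model.library.name} "
            f"({len(self.model.library)} sets, provenance {self.model.library.provenance})",
            f"Input size:     {len(self.model.input_set)}",
            f"Universe size:  {self.model.universe.size} "
            f"({len(self.model.universe.members)} named)",
            f"Null model:     {self.reps} reps, seed {self.seed}",
            f"Ordering:       {'ascending p' if self.sort == 'p' else 'descending combined score'}",
            "",
        ]
        body = frame.to_string(
            index=False,
            float_format=lambda x: f"{x:.4g}",
            columns=[c for c in RESULT_COLUMNS if c != "input_size"],
        )
        return "\n".join(header) + body

    # -- reporting hooks -------------------------------------------------

    def bipartite_graph(self, top_k: int = 10):
        """Bipartite term-microbe graph of the top terms (see msea.reporting)."""
        from .reporting import bipartite_graph

        return bipartite_graph(self.results, top_k=top_k)

    def plot_bipartite(self, top_k: int = 10, ax=None, seed: int = 0):
        """Draw the bipartite graph with edge widths scaled by combined score."""
        from .reporting import plot_bipartite

        return plot_bipartite(self.bipartite_graph(top_k=top_k), ax=ax, seed=seed)


def _read_name_list(path: str | Path) -> list[str]:
    """Read a plain-text list, one name per line; '#' lines are comments."""
    names = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names.append(line)
    return names
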