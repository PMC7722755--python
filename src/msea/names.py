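"""Normalization of microbial taxon names.

Profiling pipelines and taxonomy databases decorate taxon names with rank
prefixes (``g__Bacteroides``), placeholder suffixes (``Lactobacillus_noname``,
``..._unclassified``) and underscores in place of spaces. Set membership tests
only work when every producer and consumer agrees on one canonical spelling,
so a single normalizer is applied everywhere a name enters the package.
"""

from __future__ import annotations

import re

from .errors import InvalidNameError

__all__ = ["normalize_taxon_name"]

# Greengenes-style rank prefix: a single letter followed by two underscores.
_RANK_PREFIX = re.compile(r"^[A-Za-z]__")
# One or more trailing placeholder suffixes, e.g. "_noname", "_unclassified",
# possibly stacked ("_noname_unclassified").
_PLACEHOLDER_TAIL = re.compile(r"(?:_+(?:noname|unclassified))+\s*$", re.IGNORECASE)
_UNDERSCORES = re.compile(r"_+")
_WHITESPACE = re.compile(r"\s+")


def normalize_taxon_name(raw: str) -> str:
    """Return the canonical form of a taxon name.

    The transformation strips surrounding whitespace, removes a leading
    rank prefix of the form ``<letter>__``, removes trailing ``_noname`` /
    ``_unclassified`` placeholders, and replaces word-separating underscores
    with single spaces. Capitalization is preserved. The function is
    idempotent: applying it to its own output is a no-op.

    Parameters
    ----------
    raw:
        The name as it appears in the source (lineage string, mention table,
        input list).

    Raises
    ------
    InvalidNameError
        If nothing remains after stripping decorations.
    """
    if raw is None:
        raise InvalidNameError("taxon name is None")
    name = raw.strip()
    if not name:
        raise InvalidNameError("taxon name is empty")
    name = _RANK_PREFIX.sub("", name)
    name = _PLACEHOLDER_TAIL.sub("", name)
    name = _UNDERSCORES.sub(" ", name)
    name = _WHITESPACE.sub(" ", name).strip()
    if not name:
        raise InvalidNameError(f"taxon name {raw!r} is empty after normalization")
    return name
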