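import os

os.environ.setdefault("MPLBACKEND", "Agg")

import pytest

from msea.libraries import MicrobeSet, MicrobeSetLibrary
from msea.taxonomy import parse_greengenes_taxonomy

TOY_LINEAGES = [
    "k__Bacteria;p__Firmicutes;g__Lactobacillus;s__reuteri",
    "k__Bacteria;p__Firmicutes;g__Lactobacillus;s__gasseri",
    "k__Bacteria;p__Firmicutes;g__Clostridium;s__difficile",
    "k__Bacteria;p__Bacteroidetes;g__Bacteroides;s__fragilis",
    "k__Bacteria;p__Bacteroidetes;g__Bacteroides;s__ovatus",
    "k__Bacteria;p__Bacteroidetes;g__Prevotella;s__copri",
]


@pytest.fixture
def toy_tree():
    return parse_greengenes_taxonomy(TOY_LINEAGES)


@pytest.fixture
def toy_lineages():
    return list(TOY_LINEAGES)


def library_from_dict(sets: dict[str, set[str]], name="lib") -> MicrobeSetLibrary:
    lib = MicrobeSetLibrary(name)
    for term_id, members in sets.items():
        lib.add(MicrobeSet.from_names(term_id, members))
    return lib


@pytest.fixture
def small_library():
    return library_from_dict(
        {
            "D1": {"m1", "m2", "m3", "m4"},
            "D2": {"m3", "m4", "m5"},
            "D3": {"m6", "m7"},
        }
    )
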