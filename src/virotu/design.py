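"""Study design: samples, phenotypes, compartments, and sharing classes.

The study layout is a fully crossed design of two plant phenotypes
(``short``, ``tall``) and three microbiome compartments at increasing
proximity to root tissue (``bulk`` sediment, ``rhizosphere``, ``root``),
with replicate samples per cell. A multi-sample vOTU's occurrences fall
into one of 3 phenotype sharing classes and one of 7 compartment sharing
classes, which are the categories all co-occurrence statistics are
computed over.
"""
from __future__ import annotations

from typing import Iterable

import pandas as pd

PHENOTYPES: tuple[str, ...] = ("short", "tall")
COMPARTMENTS: tuple[str, ...] = ("bulk", "rhizosphere", "root")

PHENOTYPE_CLASSES: tuple[str, ...] = ("short-only", "tall-only", "both-phenotypes")

COMPARTMENT_CLASSES: tuple[str, ...] = (
    "bulk-only",
    "rhizosphere-only",
    "root-only",
    "bulk+rhizosphere",
    "rhizosphere+root",
    "bulk+root",
    "all-three",
)

COMPARTMENT_CLASS_SETS: dict[str, frozenset[str]] = {
    "bulk-only": frozenset({"bulk"}),
    "rhizosphere-only": frozenset({"rhizosphere"}),
    "root-only": frozenset({"root"}),
    "bulk+rhizosphere": frozenset({"bulk", "rhizosphere"}),
    "rhizosphere+root": frozenset({"rhizosphere", "root"}),
    "bulk+root": frozenset({"bulk", "root"}),
    "all-three": frozenset(COMPARTMENTS),
}

_SET_TO_COMPARTMENT_CLASS = {v: k for k, v in COMPARTMENT_CLASS_SETS.items()}


def phenotype_class(phenotypes: Iterable[str]) -> str:
    """Map the set of phenotypes a vOTU occurs in to its sharing class."""
    s = frozenset(phenotypes)
    if not s <= set(PHENOTYPES):
        raise ValueError(f"unknown phenotypes: {sorted(s - set(PHENOTYPES))}")
    if not s:
        raise ValueError("empty phenotype set")
    if len(s) == 2:
        return "both-phenotypes"
    return f"{next(iter(s))}-only"


def compartment_class(compartments: Iterable[str]) -> str:
    """Map the set of compartments a vOTU occurs in to one of the 7 classes."""
    s = frozenset(compartments)
    try:
        return _SET_TO_COMPARTMENT_CLASS[s]
    except KeyError:
        raise ValueError(f"not a valid compartment set: {sorted(s)}") from None


def generate_design(n_replicates: int = 4, seed: int | None = None) -> pd.DataFrame:
    """Build the sample design table: ``n_replicates`` per phenotype x compartment cell.

    The default of 4 replicates yields the study's 24-sample layout. Sample
    ids are deterministic (``{phenotype}_{compartment}_r{i}``); ``seed`` is
    accepted for interface symmetry with the stochastic generators but the
    layout does not depend on it.

    Returns a DataFrame with columns ``sample_id``, ``phenotype``,
    ``compartment``, ``replicate``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = [
        {
            "sample_id": f"{p}_{c}_r{i}",
            "phenotype": p,
            "compartment": c,
            "replicate": i,
        }
        for p in PHENOTYPES
        for c in COMPARTMENTS
        for i in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "phenotype", "compartment", "replicate"])


def validate_design(design: pd.DataFrame) -> None:
    """Check structural invariants of a design table; raise ValueError on failure."""
    required = {"sample_id", "phenotype", "compartment", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    bad_p = set(design["phenotype"]) - set(PHENOTYPES)
    if bad_p:
        raise ValueError(f"unknown phenotypes: {sorted(bad_p)}")
    bad_c = set(design["compartment"]) - set(COMPARTMENTS)
    if bad_c:
        raise ValueError(f"unknown compartments: {sorted(bad_c)}")
    if (design["replicate"] < 1).any():
        raise ValueError("replicate numbers must be positive")


def sample_labels(design: pd.DataFrame) -> pd.DataFrame:
    """Design table indexed by sample_id, for label lookups."""
    validate_design(design)
    return design.set_index("sample_id")
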