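"""Annotation-level filters: hit thresholds, the positional AMG rule, host tagging.

An auxiliary metabolic gene (AMG) candidate is a metabolic-annotated
gene located away from the contig ends and immediately surrounded by
viral-annotated genes on both sides — a conservative positional rule
that screens out host contamination at assembly edges. Host-prediction
tables are joined against a table of microbial orders with known
biogeochemical roles (sulfur oxidation, sulfate reduction, iron
oxidation, nitrification) to characterize the functions of the
microbes a viral community targets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import COMPARTMENTS, PHENOTYPES, sample_labels

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["contig_id", "gene_index", "annotation_class", "bit_score", "e_value"]
KNOWN_FUNCTIONS = ("sulfur-oxidizing", "sulfate-reducing", "iron-oxidizing", "nitrifying")


@dataclass
class HostFunctionSummary:
    n_votus_assigned: int
    n_unique_phyla: int
    n_unique_orders: int
    n_functional_orders: int
    fraction_votus_functional: float


def filter_hits(
    hit_table: pd.DataFrame, min_bitscore: float = 30.0, max_evalue: float = 0.01
) -> pd.DataFrame:
    """Keep hits with bit score strictly above ``min_bitscore`` and e-value
    at most ``max_evalue``. Rows with missing scores are dropped."""
    keep = (hit_table["bit_score"] > min_bitscore) & (hit_table["e_value"] <= max_evalue)
    return hit_table.loc[keep.fillna(False)].reset_index(drop=True)


def flag_amg(genes: pd.DataFrame, flank: int = 1) -> pd.DataFrame:
    """Positional AMG candidates from ordered per-contig gene tables.

    A gene is flagged iff its annotation class is ``metabolic``, it is not
    among the first or last ``flank`` genes of its contig, and its
    ``flank`` nearest neighbors on *both* sides are all ``viral``. Contigs
    with fewer than ``2*flank + 1`` genes cannot yield candidates and are
    logged.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    flagged = []
    for contig, g in genes.groupby("contig_id", sort=False):
        g = g.sort_values("gene_index")
        idx = g["gene_index"].to_numpy()
        if not (idx[0] == 1 and np.array_equal(idx, np.arange(1, len(g) + 1))):
            raise ValueError(f"{contig}: gene_index must be consecutive starting at 1")
        classes = g["annotation_class"].to_numpy()
        n = len(classes)
        if n < 2 * flank + 1:
            logger.info("contig %s has %d genes (< %d); no AMG candidates possible",
                        contig, n, 2 * flank + 1)
            continue
        for i in range(flank, n - flank):
            if classes[i] != "metabolic":
                continue
            left = classes[i - flank : i]
            right = classes[i + 1 : i + 1 + flank]
            if (left == "viral").all() and (right == "viral").all():
                flagged.append(g.iloc[i])
    if not flagged:
        return genes.iloc[0:0].copy()
    return pd.DataFrame(flagged).reset_index(drop=True)


def tag_host_functions(
    hosts: pd.DataFrame, functions: pd.DataFrame
) -> tuple[pd.DataFrame, HostFunctionSummary]:
    """Join host predictions with order-level biogeochemical functions.

    ``hosts`` columns: votu_id, host_phylum, host_order (order may be
    missing/"unknown"). ``functions`` is long-form: columns ``order,
    function``. Returns the per-vOTU tag table (one row per vOTU-function
    pair; vOTUs with no functional order get function ``none``) and a
    summary of unique phyla/orders and the fraction of host-assigned
    vOTUs hitting at least one function.
    """
    hosts = hosts.copy()
    order = hosts["host_order"].fillna("unknown")
    func_by_order = functions.groupby("order")["function"].apply(list).to_dict()
    rows = []
    functional_votus = 0
    for row, o in zip(hosts.itertuples(index=False), order):
        funcs = func_by_order.get(o, [])
        if funcs:
            functional_votus += 1
            for f in funcs:
                rows.append({"votu_id": row.votu_id, "host_order": o, "function": f})
        else:
            rows.append({"votu_id": row.votu_id, "host_order": o, "function": "none"})
    tags = pd.DataFrame(rows, columns=["votu_id", "host_order", "function"])

    known_orders = order[order != "unknown"]
    n_assigned = len(hosts)
    orders_set = set(known_orders)
    summary = HostFunctionSummary(
        n_votus_assigned=n_assigned,
        n_unique_phyla=hosts["host_phylum"].nunique(),
        n_unique_orders=len(orders_set),
        n_functional_orders=sum(1 for o in orders_set if func_by_order.get(o)),
        fraction_votus_functional=(functional_votus / n_assigned) if n_assigned else 0.0,
    )
    return tags, summary


def summarize_host_predictions(
    hosts: pd.DataFrame, occ: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Per phenotype x compartment cell: host-assigned vOTU counts and rates.

    A vOTU counts toward a cell when present in at least one of the cell's
    samples. Returns one row per cell with the number of vOTUs present,
    the number of those with a host prediction, the percentage, and a
    per-phylum breakdown (JSON-ish dict column ``phylum_counts``).
    """
    unknown = set(hosts["votu_id"]) - set(occ.index)
    if unknown:
        raise ValueError(f"host table references vOTUs absent from occurrence: {sorted(unknown)[:5]}")
    labels = sample_labels(design)
    host_by_votu = hosts.set_index("votu_id")["host_phylum"]
    rows = []
    for p in PHENOTYPES:
        for c in COMPARTMENTS:
            cell_samples = labels.index[
                (labels["phenotype"] == p) & (labels["compartment"] == c)
            ]
            cols = [s for s in cell_samples if s in occ.columns]
            present = occ[cols].any(axis=1) if cols else pd.Series(False, index=occ.index)
            present_ids = set(occ.index[present])
            with_host = present_ids & set(host_by_votu.index)
            phylum_counts = (
                host_by_votu.loc[sorted(with_host)].value_counts().to_dict() if with_host else {}
            )
            n_present = len(present_ids)
            rows.append(
                {
                    "phenotype": p,
                    "compartment": c,
                    "n_votus_present": n_present,
                    "n_with_host": len(with_host),
                    "pct_with_host": (100.0 * len(with_host) / n_present) if n_present else 0.0,
                    "phylum_counts": phylum_counts,
                }
            )
    return pd.DataFrame(rows)
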