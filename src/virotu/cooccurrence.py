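"""Sharing-class analysis of multi-sample vOTUs and its randomization null model.

Multi-sample vOTUs (present in two or more samples) are classified by
the set of plant phenotypes (3 classes) and compartments (7 classes)
across which their occurrences are spread. Observed class counts are
compared with a null model that randomizes vOTU identities while
conserving each sample's richness — the expected sharing-class
frequencies when there is no niche structure — and tested with a
Pearson chi-square goodness-of-fit statistic.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .design import (
    COMPARTMENT_CLASSES,
    COMPARTMENTS,
    PHENOTYPE_CLASSES,
    PHENOTYPES,
    sample_labels,
)

CLASSIFICATIONS = ("phenotype", "compartment")


@dataclass
class SharingClassCounts:
    """Counts of multi-sample vOTUs per sharing class."""

    phenotype: pd.Series  # indexed by PHENOTYPE_CLASSES
    compartment: pd.Series  # indexed by COMPARTMENT_CLASSES
    n_multi: int


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    infinite: bool = False  # expected 0 with observed > 0


@dataclass
class NullModelResult:
    classification: str
    observed: pd.Series  # observed class counts
    expected_proportions: pd.Series  # ratio of replicate-mean counts
    expected_counts: pd.Series  # proportions scaled to observed n_multi
    replicate_counts: pd.DataFrame  # n_replicates x classes
    n_replicates: int
    chi2: float
    df: int
    p_value: float
    seed: int | None
    mode: str


@dataclass
class ExactNullExpectations:
    classification: str
    expected_counts: pd.Series  # E[class count] over all assignments
    proportions: pd.Series  # E[count] / E[n_multi]
    expected_n_multi: float
    n_assignments: int


def multi_sample_filter(occ: pd.DataFrame) -> pd.DataFrame:
    """Rows (vOTUs) present in at least two samples."""
    return occ.loc[occ.sum(axis=1) >= 2]


def _class_counts(
    M: np.ndarray, group_masks: dict[str, np.ndarray], classes: tuple[str, ...]
) -> np.ndarray:
    """Vectorized sharing-class counts for a boolean occurrence array.

    ``group_masks`` maps each phenotype (or compartment) to a boolean mask
    over columns; a vOTU's class is determined by which groups it touches.
    """
    touch = {g: M[:, mask].any(axis=1) for g, mask in group_masks.items()}
    counts = np.zeros(len(classes), dtype=np.int64)
    if len(group_masks) == 2:  # phenotype classification
        a, b = PHENOTYPES
        counts[0] = (touch[a] & ~touch[b]).sum()
        counts[1] = (touch[b] & ~touch[a]).sum()
        counts[2] = (touch[a] & touch[b]).sum()
    else:  # compartment classification: 3-bit signature -> class
        bulk, rhizo, root = (touch[c] for c in COMPARTMENTS)
        counts[0] = (bulk & ~rhizo & ~root).sum()
        counts[1] = (~bulk & rhizo & ~root).sum()
        counts[2] = (~bulk & ~rhizo & root).sum()
        counts[3] = (bulk & rhizo & ~root).sum()
        counts[4] = (~bulk & rhizo & root).sum()
        counts[5] = (bulk & ~rhizo & root).sum()
        counts[6] = (bulk & rhizo & root).sum()
    return counts


def _group_masks(design: pd.DataFrame, columns, classification: str) -> dict[str, np.ndarray]:
    labels = sample_labels(design)
    unknown = set(columns) - set(labels.index)
    if unknown:
        raise ValueError(f"samples not in design: {sorted(unknown)}")
    if classification == "phenotype":
        key, groups = "phenotype", PHENOTYPES
    elif classification == "compartment":
        key, groups = "compartment", COMPARTMENTS
    else:
        raise ValueError(f"classification must be one of {CLASSIFICATIONS}")
    col_group = labels.loc[list(columns), key].to_numpy()
    return {g: col_group == g for g in groups}


def classify_phenotype_sharing(occ_multi: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Counts of multi-sample vOTUs per phenotype sharing class."""
    masks = _group_masks(design, occ_multi.columns, "phenotype")
    counts = _class_counts(occ_multi.to_numpy(bool), masks, PHENOTYPE_CLASSES)
    return pd.Series(counts, index=list(PHENOTYPE_CLASSES), name="count")


def classify_compartment_sharing(occ_multi: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Counts of multi-sample vOTUs per compartment sharing class (7 classes)."""
    masks = _group_masks(design, occ_multi.columns, "compartment")
    counts = _class_counts(occ_multi.to_numpy(bool), masks, COMPARTMENT_CLASSES)
    return pd.Series(counts, index=list(COMPARTMENT_CLASSES), name="count")


def sharing_class_counts(occ: pd.DataFrame, design: pd.DataFrame) -> SharingClassCounts:
    """Filter to multi-sample vOTUs and classify them both ways."""
    occ_multi = multi_sample_filter(occ)
    return SharingClassCounts(
        phenotype=classify_phenotype_sharing(occ_multi, design),
        compartment=classify_compartment_sharing(occ_multi, design),
        n_multi=len(occ_multi),
    )


def chi_square_gof(observed_counts, expected_proportions) -> ChiSquareResult:
    """Pearson chi-square goodness of fit against expected class proportions.

    Expected counts are the proportions scaled to the observed total.
    Classes with expected count 0 and observed 0 are dropped from the
    degrees of freedom; an expected 0 with observed > 0 makes the
    statistic infinite and is flagged explicitly.
    """
    obs = np.asarray(observed_counts, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected must have the same length")
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed counts must sum to a positive total")
    if not math.isclose(props.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError(f"expected proportions must sum to 1 (got {props.sum():.6g})")
    exp = props * total
    impossible = (exp == 0) & (obs > 0)
    if impossible.any():
        return ChiSquareResult(chi2=math.inf, df=int((exp > 0).sum() - 1) , p_value=0.0, infinite=True)
    keep = exp > 0
    if (exp[keep] < 5).any():
        warnings.warn(
            "expected counts below 5; chi-square approximation may be poor",
            RuntimeWarning,
            stacklevel=2,
        )
    stat = float((((obs[keep] - exp[keep]) ** 2) / exp[keep]).sum())
    df = int(keep.sum() - 1)
    p = float(chi2_dist.sf(stat, df)) if df > 0 else 1.0
    return ChiSquareResult(chi2=stat, df=df, p_value=p)


def _null_replicate_occurrence(
    rng: np.random.Generator,
    n_catalog: int,
    richness_per_sample: np.ndarray,
    mode: str,
    cell_of_sample: np.ndarray | None,
) -> np.ndarray:
    n_samples = richness_per_sample.size
    M = np.zeros((n_catalog, n_samples), dtype=bool)
    if mode == "per_sample":
        for j in range(n_samples):
            r = richness_per_sample[j]
            if r:
                M[rng.choice(n_catalog, size=r, replace=False), j] = True
    elif mode == "per_cell":
        for cell in np.unique(cell_of_sample):
            members = np.flatnonzero(cell_of_sample == cell)
            total = int(richness_per_sample[members].sum())
            if not total:
                continue
            ids = rng.choice(n_catalog, size=total, replace=False)
            pos = 0
            for j in members:
                r = int(richness_per_sample[j])
                M[ids[pos : pos + r], j] = True
                pos += r
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    return M


def null_model(
    occ: pd.DataFrame,
    design: pd.DataFrame,
    classification: str,
    n_replicates: int = 1000,
    mode: str = "per_sample",
    seed: int | None = None,
    catalog_size: int | None = None,
) -> NullModelResult:
    """Richness-conserving randomization null for sharing-class counts.

    Per replicate, every sample is assigned a uniformly random subset of
    vOTU identities (without replacement within a sample) of size equal to
    that sample's observed richness, drawn from the full catalog of all
    observed vOTUs; the multi-sample filter and sharing classification are
    then recomputed. Expected class proportions are the replicate-mean
    class counts normalized by the replicate-mean multi-sample total, and
    the observed counts are tested against them with a chi-square
    goodness-of-fit statistic.

    ``mode="per_cell"`` instead draws identities without replacement
    across each phenotype x compartment cell (per-sample richness is still
    conserved, but replicate samples within a cell can never share a
    vOTU), a stricter cell-level reading of richness conservation.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if classification not in CLASSIFICATIONS:
        raise ValueError(f"classification must be one of {CLASSIFICATIONS}")
    labels = sample_labels(design)
    columns = list(occ.columns)
    masks = _group_masks(design, columns, classification)
    classes = PHENOTYPE_CLASSES if classification == "phenotype" else COMPARTMENT_CLASSES

    n_catalog = catalog_size if catalog_size is not None else occ.shape[0]
    rich = occ.to_numpy(bool).sum(axis=0).astype(np.int64)
    if (rich > n_catalog).any():
        raise ValueError("a sample's richness exceeds the catalog size")
    cell = None
    if mode == "per_cell":
        cell_labels = (
            labels.loc[columns, "phenotype"] + "|" + labels.loc[columns, "compartment"]
        ).to_numpy()
        _, cell = np.unique(cell_labels, return_inverse=True)
        for c in np.unique(cell):
            if rich[cell == c].sum() > n_catalog:
                raise ValueError("a cell's pooled richness exceeds the catalog size")

    rng = np.random.default_rng(seed)
    rep_counts = np.zeros((n_replicates, len(classes)), dtype=np.int64)
    for r in range(n_replicates):
        M = _null_replicate_occurrence(rng, n_catalog, rich, mode, cell)
        multi = M[M.sum(axis=1) >= 2]
        rep_counts[r] = _class_counts(multi, masks, classes)

    mean_counts = rep_counts.mean(axis=0)
    mean_total = mean_counts.sum()
    if mean_total > 0:
        props = mean_counts / mean_total
    else:
        props = np.full(len(classes), 1.0 / len(classes))

    occ_multi = multi_sample_filter(occ)
    observed = pd.Series(
        _class_counts(occ_multi.to_numpy(bool), masks, classes),
        index=list(classes),
        name="observed",
    )
    if observed.sum() > 0:
        test = chi_square_gof(observed.to_numpy(), props)
    else:
        test = ChiSquareResult(chi2=0.0, df=len(classes) - 1, p_value=1.0)
    return NullModelResult(
        classification=classification,
        observed=observed,
        expected_proportions=pd.Series(props, index=list(classes), name="expected_proportion"),
        expected_counts=pd.Series(
            props * observed.sum(), index=list(classes), name="expected_count"
        ),
        replicate_counts=pd.DataFrame(rep_counts, columns=list(classes)),
        n_replicates=n_replicates,
        chi2=test.chi2,
        df=test.df,
        p_value=test.p_value,
        seed=seed,
        mode=mode,
    )


def exact_null_expectations(
    sample_richnesses,
    catalog_size: int,
    design: pd.DataFrame,
    classification: str,
    max_combinations: int = 10**6,
) -> ExactNullExpectations:
    """Exact per-sample-richness null expectations by full enumeration.

    Enumerates every combination of per-sample vOTU subsets (each sample
    choosing its observed richness from the catalog), computing the mean
    sharing-class counts across all Π_s C(catalog, r_s) equally likely
    assignments. Serves as the independent oracle for :func:`null_model`
    on small instances; refuses when the combination count exceeds
    ``max_combinations``.

    ``sample_richnesses`` maps sample_id -> richness (dict or Series) or
    is a sequence aligned with the design rows.
    """
    if classification not in CLASSIFICATIONS:
        raise ValueError(f"classification must be one of {CLASSIFICATIONS}")
    labels = sample_labels(design)
    if isinstance(sample_richnesses, (dict, pd.Series)):
        samples = list(sample_richnesses.keys() if isinstance(sample_richnesses, dict) else sample_richnesses.index)
        rich = np.asarray([int(sample_richnesses[s]) for s in samples])
    else:
        samples = list(labels.index)
        rich = np.asarray([int(r) for r in sample_richnesses])
        if rich.size != len(samples):
            raise ValueError("richness sequence must align with the design")
    if (rich < 0).any() or (rich > catalog_size).any():
        raise ValueError("richnesses must lie in [0, catalog_size]")
    masks = _group_masks(design, samples, classification)
    classes = PHENOTYPE_CLASSES if classification == "phenotype" else COMPARTMENT_CLASSES

    total_comb = 1
    for r in rich:
        total_comb *= math.comb(catalog_size, int(r))
        if total_comb > max_combinations:
            raise ValueError(
                f"enumeration would exceed {max_combinations} combinations; refusing"
            )

    per_sample_subsets = [
        list(itertools.combinations(range(catalog_size), int(r))) for r in rich
    ]
    sum_counts = np.zeros(len(classes), dtype=np.int64)
    sum_multi = 0
    M = np.zeros((catalog_size, len(samples)), dtype=bool)
    for combo in itertools.product(*per_sample_subsets):
        M[:] = False
        for j, subset in enumerate(combo):
            M[list(subset), j] = True
        multi = M[M.sum(axis=1) >= 2]
        sum_multi += multi.shape[0]
        sum_counts += _class_counts(multi, masks, classes)

    expected_counts = sum_counts / total_comb
    expected_n_multi = sum_multi / total_comb
    props = (
        expected_counts / expected_counts.sum()
        if expected_counts.sum() > 0
        else np.full(len(classes), 1.0 / len(classes))
    )
    return ExactNullExpectations(
        classification=classification,
        expected_counts=pd.Series(expected_counts, index=list(classes)),
        proportions=pd.Series(props, index=list(classes)),
        expected_n_multi=float(expected_n_multi),
        n_assignments=total_comb,
    )
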