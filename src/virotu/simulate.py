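"""Synthetic data generator for the vOTU analysis pipeline.

Emulates the statistical structure the downstream analysis assumes, so
every stage is testable without sequencing data:

* a replicated phenotype x compartment sample design (default 24 samples),
* vOTU occupancy with tunable phenotype fidelity (probability that a
  vOTU is restricted to a single plant phenotype) and a compartment
  proximity gradient encoded as class weights over the 7 compartment
  sharing classes (the weight of the spatially impossible
  bulk+root-without-rhizosphere class defaults to 0),
* per-(vOTU, sample) mapping-coverage summaries with overdispersed read
  depth over contigs of heterogeneous length, constructed so that the
  breadth-of-coverage presence rule recovers ground-truth occupancy
  exactly (present pairs have breadth >= the threshold, absent pairs sit
  strictly below it with a guard gap),
* gene-annotation tables and host-prediction tables for the annotation
  filters.

Ground truth is returned alongside every stochastic output, and every
generator is bit-reproducible under a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    COMPARTMENT_CLASS_SETS,
    COMPARTMENT_CLASSES,
    PHENOTYPES,
    generate_design,
    validate_design,
)

__all__ = [
    "SimulationParams",
    "generate_design",
    "generate_coverage",
    "generate_gene_tables",
    "generate_host_table",
]

#: Default weights over the 7 compartment sharing classes. These echo the
#: broad pattern of compartment sharing among multi-sample vOTUs in salt
#: marsh root-zone viromes: roughly a fifth of vOTUs confined to one
#: compartment, most shared between two spatially adjacent compartments
#: (rhizosphere+root dominating), a small fraction in all three, and the
#: spatially non-adjacent bulk+root-only combination absent.
DEFAULT_COMPARTMENT_WEIGHTS: dict[str, float] = {
    "bulk-only": 0.10,
    "rhizosphere-only": 0.06,
    "root-only": 0.04,
    "bulk+rhizosphere": 0.22,
    "rhizosphere+root": 0.50,
    "bulk+root": 0.0,
    "all-three": 0.08,
}


@dataclass
class SimulationParams:
    """Parameters of the coverage simulation.

    Parameters
    ----------
    n_votus
        Number of viral populations in the catalog.
    contig_length_range
        (min, max) contig length in bp; lengths are log-uniform on this
        range. min must be >= 5000 so the catalog survives the length filter.
    phenotype_fidelity
        Probability that a vOTU's occupancy is restricted to one randomly
        chosen phenotype. 1 forbids cross-phenotype sharing entirely.
    compartment_weights
        Categorical weights over the 7 compartment sharing classes giving
        each vOTU's eligible compartments. Need not be normalized.
    per_sample_occupancy
        Probability that a vOTU occupies each of its eligible samples.
    depth_mean, depth_dispersion
        Mean per-base read depth for present pairs and the negative-binomial
        dispersion (shape) parameter; smaller dispersion = more overdispersed.
    background_rate
        Fraction of absent (vOTU, sample) pairs that still show trace
        coverage (spurious read recruitment).
    background_breadth_max
        Upper bound of the breadth distribution for absent pairs; must be
        strictly below ``breadth_threshold`` so ground truth is recoverable.
    breadth_threshold
        Presence threshold the generated coverage is constructed around.
    read_length
        Read length used to convert depth to read counts.
    seed
        Seed for all randomness in the generator.
    """

    n_votus: int = 769
    contig_length_range: tuple[int, int] = (5000, 60000)
    phenotype_fidelity: float = 0.8
    compartment_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_WEIGHTS)
    )
    per_sample_occupancy: float = 0.3
    depth_mean: float = 10.0
    depth_dispersion: float = 1.0
    background_rate: float = 0.3
    background_breadth_max: float = 0.70
    breadth_threshold: float = 0.75
    read_length: int = 150
    seed: int = 0

    def validate(self) -> None:
        if self.n_votus < 1:
            raise ValueError("n_votus must be positive")
        lo, hi = self.contig_length_range
        if not (5000 <= lo <= hi):
            raise ValueError("contig_length_range must satisfy 5000 <= min <= max")
        for name in ("phenotype_fidelity", "per_sample_occupancy", "background_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        unknown = set(self.compartment_weights) - set(COMPARTMENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown compartment classes: {sorted(unknown)}")
        w = np.array([self.compartment_weights.get(c, 0.0) for c in COMPARTMENT_CLASSES])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("compartment weights must be non-negative with positive sum")
        if not (0.0 <= self.background_breadth_max < self.breadth_threshold <= 1.0):
            raise ValueError(
                "background_breadth_max must be < breadth_threshold <= 1 "
                "(the guard gap makes ground truth recoverable)"
            )
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")

    def with_(self, **kwargs) -> "SimulationParams":
        """Copy with fields replaced."""
        return replace(self, **kwargs)


def _votu_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"vOTU_{i:0{width}d}" for i in range(1, n + 1)]


def generate_coverage(
    design: pd.DataFrame, params: SimulationParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-(vOTU, sample) coverage summaries plus ground-truth occupancy.

    Each vOTU first receives an eligibility region: one phenotype (with
    probability ``phenotype_fidelity``) or both, crossed with a compartment
    set drawn from ``compartment_weights``. It then occupies each eligible
    sample independently with probability ``per_sample_occupancy``. Under
    the default weights (bulk+root-only weight 0) a realized occupancy of
    exactly {bulk, root} would misrepresent the proximity gradient, so when
    the drawn class includes the rhizosphere and the realized compartments
    collapse to {bulk, root}, one eligible rhizosphere sample is forced to
    occupied — the generated ground truth therefore never contains a
    bulk+root-only vOTU unless that class is given positive weight.

    Present pairs get breadth uniform on [breadth_threshold, 1] and
    negative-binomial read counts (>= 1); absent pairs get either zero
    coverage or trace coverage with breadth uniform on
    [0, background_breadth_max], strictly below the threshold.

    Returns
    -------
    coverage : DataFrame
        Columns ``votu_id, sample_id, contig_length, covered_bases,
        mapped_reads``, one row per (vOTU, sample) pair.
    truth : DataFrame
        Boolean occupancy matrix, index votu_id, columns sample_id.
    """
    params.validate()
    validate_design(design)
    rng = np.random.default_rng(params.seed)

    samples = design["sample_id"].to_numpy()
    pheno = design["phenotype"].to_numpy()
    comp = design["compartment"].to_numpy()
    n_samples = len(samples)
    n = params.n_votus
    votus = _votu_ids(n)

    lo, hi = params.contig_length_range
    lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    lengths = np.clip(np.round(lengths).astype(np.int64), lo, hi)

    class_names = list(COMPARTMENT_CLASSES)
    weights = np.array([params.compartment_weights.get(c, 0.0) for c in class_names], float)
    weights = weights / weights.sum()

    occ = np.zeros((n, n_samples), dtype=bool)
    restrict = rng.random(n) < params.phenotype_fidelity
    chosen_pheno = rng.choice(len(PHENOTYPES), size=n)
    chosen_class = rng.choice(len(class_names), size=n, p=weights)

    for i in range(n):
        allowed_p = (
            {PHENOTYPES[chosen_pheno[i]]} if restrict[i] else set(PHENOTYPES)
        )
        allowed_c = COMPARTMENT_CLASS_SETS[class_names[chosen_class[i]]]
        eligible = np.fromiter(
            ((pheno[j] in allowed_p) and (comp[j] in allowed_c) for j in range(n_samples)),
            dtype=bool,
            count=n_samples,
        )
        hit = eligible & (rng.random(n_samples) < params.per_sample_occupancy)
        realized = set(comp[hit])
        if realized == {"bulk", "root"} and "rhizosphere" in allowed_c:
            rhizo_idx = np.flatnonzero(eligible & (comp == "rhizosphere"))
            hit[rng.choice(rhizo_idx)] = True
        occ[i] = hit

    # coverage for all pairs, vectorized over the flattened (votu, sample) grid
    L = np.repeat(lengths, n_samples)
    present = occ.ravel()
    n_pairs = n * n_samples

    covered = np.zeros(n_pairs, dtype=np.int64)
    reads = np.zeros(n_pairs, dtype=np.int64)

    # present pairs: breadth in [threshold, 1], reads negative-binomial >= 1
    p_idx = np.flatnonzero(present)
    if p_idx.size:
        breadth = rng.uniform(params.breadth_threshold, 1.0, size=p_idx.size)
        covered[p_idx] = np.minimum(L[p_idx], np.ceil(breadth * L[p_idx]).astype(np.int64))
        mean_reads = params.depth_mean * L[p_idx] / params.read_length
        k = params.depth_dispersion
        nb = rng.negative_binomial(k, k / (k + mean_reads))
        # at least enough reads to physically cover the covered bases
        floor_reads = np.ceil(covered[p_idx] / params.read_length).astype(np.int64)
        reads[p_idx] = np.maximum(np.maximum(1, floor_reads), nb)

    # absent pairs: trace coverage strictly below the threshold, or nothing
    a_idx = np.flatnonzero(~present)
    if a_idx.size:
        trace = a_idx[rng.random(a_idx.size) < params.background_rate]
        if trace.size:
            breadth = rng.uniform(0.0, params.background_breadth_max, size=trace.size)
            cap = np.ceil(params.breadth_threshold * L[trace]).astype(np.int64) - 1
            covered[trace] = np.minimum(np.floor(breadth * L[trace]).astype(np.int64), cap)
            lam = np.maximum(covered[trace] / params.read_length, 0.0)
            r = rng.poisson(lam)
            floor_reads = np.ceil(covered[trace] / params.read_length).astype(np.int64)
            reads[trace] = np.where(
                covered[trace] > 0, np.maximum(np.maximum(1, floor_reads), r), 0
            )

    coverage = pd.DataFrame(
        {
            "votu_id": np.repeat(votus, n_samples),
            "sample_id": np.tile(samples, n),
            "contig_length": L,
            "covered_bases": covered,
            "mapped_reads": reads,
        }
    )
    truth = pd.DataFrame(occ, index=pd.Index(votus, name="votu_id"), columns=samples)
    truth.columns.name = "sample_id"
    return coverage, truth


def generate_gene_tables(
    n_contigs: int,
    genes_per_contig: int | tuple[int, int] = (8, 25),
    p_viral: float = 0.5,
    p_metabolic: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ordered per-contig gene annotations.

    Each gene is independently ``viral``, ``metabolic`` or ``unknown``
    (probabilities ``p_viral``, ``p_metabolic`` and the remainder).
    Annotated genes carry a bit score and e-value drawn around the usual
    hit-filter thresholds (bit score 30, e-value 0.01) so both sides of the
    filter are exercised; unannotated genes have missing scores.
    """
    if p_viral < 0 or p_metabolic < 0 or p_viral + p_metabolic > 1:
        raise ValueError("p_viral and p_metabolic must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    if isinstance(genes_per_contig, int):
        counts = np.full(n_contigs, genes_per_contig)
    else:
        glo, ghi = genes_per_contig
        counts = rng.integers(glo, ghi + 1, size=n_contigs)

    rows = []
    for c in range(n_contigs):
        contig = f"contig_{c + 1:04d}"
        m = int(counts[c])
        u = rng.random(m)
        classes = np.where(
            u < p_viral, "viral", np.where(u < p_viral + p_metabolic, "metabolic", "unknown")
        )
        bit = np.round(rng.uniform(15.0, 60.0, size=m), 2)
        evalue = 10.0 ** rng.uniform(-6.0, 0.0, size=m)
        for g in range(m):
            annotated = classes[g] != "unknown"
            rows.append(
                {
                    "contig_id": contig,
                    "gene_index": g + 1,
                    "annotation_class": classes[g],
                    "bit_score": bit[g] if annotated else np.nan,
                    "e_value": evalue[g] if annotated else np.nan,
                }
            )
    return pd.DataFrame(
        rows, columns=["contig_id", "gene_index", "annotation_class", "bit_score", "e_value"]
    )


def generate_host_table(
    votu_ids,
    orders,
    p_assigned: float = 0.083,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate singular host predictions for a fraction of vOTUs.

    ``orders`` is a sequence of ``(phylum, order)`` pairs to draw hosts
    from; each vOTU independently receives one host with probability
    ``p_assigned`` (the default mirrors the low assignment rates typical
    of soil viromes). Unassigned vOTUs are omitted from the table.
    """
    if not (0.0 <= p_assigned <= 1.0):
        raise ValueError("p_assigned must be in [0, 1]")
    orders = list(orders)
    rng = np.random.default_rng(seed)
    votu_ids = list(votu_ids)
    assigned = np.flatnonzero(rng.random(len(votu_ids)) < p_assigned)
    if assigned.size and not orders:
        raise ValueError("orders must be non-empty when hosts are assigned")
    picks = rng.integers(0, len(orders), size=assigned.size) if orders else []
    rows = [
        {
            "votu_id": votu_ids[i],
            "host_phylum": orders[k][0],
            "host_order": orders[k][1],
        }
        for i, k in zip(assigned, picks)
    ]
    return pd.DataFrame(rows, columns=["votu_id", "host_phylum", "host_order"])
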