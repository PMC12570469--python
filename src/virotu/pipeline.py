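"""Configuration and the end-to-end pipeline driver.

``PipelineConfig`` gathers every numeric constant of the analysis
(breadth 0.75, minimum length 5000 bp, ANI 0.95, alignment coverage
0.80, bit score 30, e-value 0.01, permutation counts) with validation
and lossless YAML round-tripping. ``run_pipeline`` executes the stages
occurrence -> diversity -> cooccurrence -> annotation, skipping stages
whose optional inputs are absent, and records a run manifest (config
hash, input checksums, outputs written).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, cooccurrence, diversity, io, occurrence

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    breadth: float = 0.75
    min_length: int = 5000
    ani: float = 0.95
    alignment_coverage: float = 0.80
    min_bitscore: float = 30.0
    max_evalue: float = 0.01

    def validate(self) -> None:
        for name in ("breadth", "ani", "alignment_coverage"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


@dataclass
class Permutations:
    rarefaction: int = 100
    null_replicates: int = 1000
    permanova: int = 999

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 1:
                raise ValueError(f"{f.name} must be >= 1")


@dataclass
class PipelineConfig:
    """All inputs, thresholds and switches of a pipeline run."""

    coverage: str | None = None  # CoverageSummary CSV (required)
    design: str | None = None  # design CSV (required)
    pairs: str | None = None  # pairwise similarity CSV (optional)
    lengths: str | None = None  # length TSV for dereplication (optional)
    genes: str | None = None  # GeneTable CSV (optional)
    hosts: str | None = None  # host predictions CSV (optional)
    functions: str | None = None  # order -> function CSV (optional)
    out_dir: str = "results"
    thresholds: Thresholds = field(default_factory=Thresholds)
    permutations: Permutations = field(default_factory=Permutations)
    seed: int = 0
    mask_absent: bool = False
    null_mode: str = "per_sample"
    flank: int = 1

    def validate(self) -> None:
        self.thresholds.validate()
        self.permutations.validate()
        if self.null_mode not in ("per_sample", "per_cell"):
            raise ValueError(f"null_mode must be per_sample or per_cell, got {self.null_mode!r}")
        if self.flank < 1:
            raise ValueError("flank must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "permutations" in d and isinstance(d["permutations"], dict):
            d["permutations"] = Permutations(**d["permutations"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the run manifest.

    Required inputs: coverage and design. Dereplication runs only when
    both ``pairs`` and ``lengths`` are given; the annotation stage only
    when gene/host tables are given. Outputs are deterministic given the
    configured seeds; the manifest's timestamps are the only varying part.
    """
    config.validate()
    for name in ("coverage", "design"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {path}")
    optional = {
        n: getattr(config, n)
        for n in ("pairs", "lengths", "genes", "hosts", "functions")
        if getattr(config, n)
    }
    for n, p in optional.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"configured input {n!r} does not exist: {p}")

    out = io.ensure_dir(config.out_dir)
    hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            yaml.safe_dump(hashed, sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {
            n: _sha256_file(getattr(config, n))
            for n in ("coverage", "design", *optional)
        },
        "outputs": [],
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def emit(name: str, writer, obj) -> None:
        path = out / name
        writer(path, obj)
        manifest["outputs"].append(name)

    th = config.thresholds
    pm = config.permutations

    # ---- occurrence stage -------------------------------------------------
    cov = io.read_coverage(config.coverage)
    design = io.read_design(config.design)
    logger.info("occurrence: %d coverage rows, %d samples", len(cov), design.shape[0])

    if config.pairs and config.lengths:
        pairs = io.read_pairs(config.pairs)
        lengths = occurrence.read_length_table(config.lengths)
        kept = occurrence.filter_min_length(
            pd.DataFrame({"seq_id": lengths.index, "length": lengths.to_numpy()}),
            th.min_length,
        )
        clusters = occurrence.dereplicate(
            kept.set_index("seq_id")["length"],
            pairs[pairs["seq_a"].isin(kept["seq_id"]) & pairs["seq_b"].isin(kept["seq_id"])],
            id_threshold=th.ani,
            cov_threshold=th.alignment_coverage,
        )
        emit("clusters.csv", lambda p, o: o.to_csv(p, index=False), clusters)
        reps = set(clusters.loc[clusters["seq_id"] == clusters["representative"], "seq_id"])
        cov = cov[cov["votu_id"].isin(reps)].reset_index(drop=True)
        logger.info("dereplication: %d clusters from %d sequences", len(reps), len(clusters))

    occ = occurrence.call_presence(cov, th.breadth)
    abund = occurrence.compute_tpm(cov, mask_absent=config.mask_absent, breadth_threshold=th.breadth)
    emit("occurrence.csv", io.write_occurrence, occ)
    emit("abundance_tpm.csv", io.write_abundance, abund)
    manifest["stages"]["occurrence"] = {"n_votus": occ.shape[0], "n_samples": occ.shape[1]}

    # ---- diversity stage --------------------------------------------------
    rich = diversity.richness(occ, design)
    emit("richness.csv", lambda p, o: o.to_csv(p, index=False), rich)
    curve = diversity.rarefaction(occ, n_permutations=pm.rarefaction, seed=config.seed)
    emit("rarefaction.csv", lambda p, o: o.to_csv(p, index=False), curve.to_frame())
    mw = diversity.pairwise_mann_whitney(rich)
    emit("mann_whitney.csv", lambda p, o: o.to_csv(p, index=False), mw)

    bc = diversity.bray_curtis(abund)
    emit("bray_curtis.csv", io.write_matrix, bc)
    ord_res = diversity.nmds(bc, seed=config.seed)
    emit("nmds_coordinates.csv", io.write_matrix, ord_res.coordinates)
    labels = design.set_index("sample_id")
    perma_rows = []
    for factor in ("phenotype", "compartment"):
        res = diversity.permanova(
            bc, labels[factor], n_permutations=pm.permanova, seed=config.seed
        )
        perma_rows.append(
            {
                "factor": factor,
                "pseudo_F": res.pseudo_f,
                "R2": res.r_squared,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        )
    emit("permanova.csv", lambda p, o: o.to_csv(p, index=False), pd.DataFrame(perma_rows))
    manifest["stages"]["diversity"] = {
        "nmds_stress": ord_res.stress,
        "total_richness": int(occ.any(axis=1).sum()),
    }

    # ---- cooccurrence stage ----------------------------------------------
    null_rows = []
    for classification in cooccurrence.CLASSIFICATIONS:
        res = cooccurrence.null_model(
            occ,
            design,
            classification,
            n_replicates=pm.null_replicates,
            mode=config.null_mode,
            seed=config.seed,
        )
        table = pd.DataFrame(
            {
                "class": res.observed.index,
                "observed": res.observed.to_numpy(),
                "expected": res.expected_counts.to_numpy(),
                "expected_proportion": res.expected_proportions.to_numpy(),
            }
        )
        emit(f"sharing_{classification}.csv", lambda p, o: o.to_csv(p, index=False), table)
        null_rows.append(
            {
                "classification": classification,
                "n_multi": int(res.observed.sum()),
                "chi2": res.chi2,
                "df": res.df,
                "p_value": res.p_value,
            }
        )
    emit("cooccurrence_tests.csv", lambda p, o: o.to_csv(p, index=False), pd.DataFrame(null_rows))
    manifest["stages"]["cooccurrence"] = {
        "n_multi": null_rows[0]["n_multi"],
    }

    # ---- annotation stage -------------------------------------------------
    if config.genes:
        genes = io.read_gene_table(config.genes)
        amg = annotation.flag_amg(genes, flank=config.flank)
        emit("amg_candidates.csv", lambda p, o: o.to_csv(p, index=False), amg)
        manifest["stages"]["annotation_amg"] = {"n_candidates": len(amg)}
    if config.hosts:
        hosts = io.read_hosts(config.hosts)
        cell_summary = annotation.summarize_host_predictions(hosts, occ, design)
        cell_summary = cell_summary.assign(
            phylum_counts=cell_summary["phylum_counts"].map(json.dumps)
        )
        emit("host_cell_summary.csv", lambda p, o: o.to_csv(p, index=False), cell_summary)
        if config.functions:
            functions = io.read_functions(config.functions)
            tags, summary = annotation.tag_host_functions(hosts, functions)
            emit("host_function_tags.csv", lambda p, o: o.to_csv(p, index=False), tags)
            manifest["stages"]["annotation_hosts"] = dataclasses.asdict(summary)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
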