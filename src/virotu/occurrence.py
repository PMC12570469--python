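"""From mapping coverage to the vOTU catalog, occurrence and abundance matrices.

Implements the catalog construction rules (minimum contig length,
greedy longest-first dereplication at ANI/coverage thresholds), the
breadth-of-coverage presence rule (a vOTU is present in a sample when
at least 75% of its contig length is covered by mapped reads), and
length-normalized TPM relative abundance.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

COVERAGE_COLUMNS = ["votu_id", "sample_id", "contig_length", "covered_bases", "mapped_reads"]


class DepthParseError(ValueError):
    """Raised on malformed samtools-depth input; carries the 1-based line number."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


def validate_coverage(cov: pd.DataFrame) -> None:
    missing = set(COVERAGE_COLUMNS) - set(cov.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    if (cov["contig_length"] <= 0).any():
        raise ValueError("contig_length must be positive")
    if ((cov["covered_bases"] < 0) | (cov["covered_bases"] > cov["contig_length"])).any():
        raise ValueError("covered_bases must lie in [0, contig_length]")
    if (cov["mapped_reads"] < 0).any():
        raise ValueError("mapped_reads must be non-negative")
    if cov.duplicated(["votu_id", "sample_id"]).any():
        raise ValueError("coverage table has duplicate (votu_id, sample_id) rows")


def filter_min_length(catalog: pd.DataFrame, min_length: int = 5000) -> pd.DataFrame:
    """Drop catalog entries shorter than ``min_length`` bp (inclusive threshold).

    ``catalog`` needs a ``length`` column; any id column is carried through.
    """
    if (catalog["length"] <= 0).any():
        raise ValueError("lengths must be positive")
    return catalog.loc[catalog["length"] >= min_length].reset_index(drop=True)


def dereplicate(
    lengths: dict[str, int] | pd.Series,
    pairs: pd.DataFrame,
    id_threshold: float = 0.95,
    cov_threshold: float = 0.80,
) -> pd.DataFrame:
    """Greedy longest-first clustering of sequences into populations.

    Sequences are visited by decreasing length (ties broken by id); each
    joins the first existing cluster whose *representative* it matches at
    both ``id_threshold`` (ANI) and ``cov_threshold`` (alignment coverage
    of the shorter sequence), else it founds a new cluster. The founding
    (longest) member is the cluster representative.

    ``pairs`` columns: ``seq_a, seq_b, identity, coverage`` (symmetric;
    either orientation accepted).

    Returns a DataFrame with columns ``seq_id, representative``.
    """
    if isinstance(lengths, pd.Series):
        lengths = lengths.to_dict()
    known = set(lengths)
    for col in ("seq_a", "seq_b"):
        unknown = set(pairs[col]) - known
        if unknown:
            raise ValueError(f"pairs reference ids with unknown length: {sorted(unknown)[:5]}")

    match: dict[frozenset, tuple[float, float]] = {}
    for row in pairs.itertuples(index=False):
        key = frozenset((row.seq_a, row.seq_b))
        if len(key) < 2:
            continue  # self-pairs are vacuous
        prev = match.get(key)
        cand = (float(row.identity), float(row.coverage))
        # keep the best-supported record if the pair is listed twice
        if prev is None or cand > prev:
            match[key] = cand

    def qualifies(a: str, b: str) -> bool:
        rec = match.get(frozenset((a, b)))
        return rec is not None and rec[0] >= id_threshold and rec[1] >= cov_threshold

    order = sorted(known, key=lambda s: (-lengths[s], s))
    representatives: list[str] = []
    assignment: dict[str, str] = {}
    for seq in order:
        for rep in representatives:
            if qualifies(seq, rep):
                assignment[seq] = rep
                break
        else:
            representatives.append(seq)
            assignment[seq] = seq
    out = pd.DataFrame(
        {"seq_id": order, "representative": [assignment[s] for s in order]}
    )
    return out.sort_values("seq_id", ignore_index=True)


def call_presence(cov: pd.DataFrame, breadth_threshold: float = 0.75) -> pd.DataFrame:
    """Boolean occurrence matrix from breadth of coverage.

    A vOTU is present in a sample iff covered_bases / contig_length >=
    ``breadth_threshold``. (vOTU, sample) pairs missing from the table are
    absent.
    """
    validate_coverage(cov)
    if not (0.0 < breadth_threshold <= 1.0):
        raise ValueError("breadth_threshold must be in (0, 1]")
    breadth = cov["covered_bases"] / cov["contig_length"]
    present = breadth >= breadth_threshold
    occ = (
        cov.assign(present=present)
        .pivot(index="votu_id", columns="sample_id", values="present")
        .fillna(False)
        .astype(bool)
    )
    return occ


def compute_tpm(
    cov: pd.DataFrame,
    mask_absent: bool = False,
    breadth_threshold: float = 0.75,
) -> pd.DataFrame:
    """TPM abundance matrix (vOTU x sample).

    Per sample, each vOTU's read count is divided by its contig length in
    kb, and the resulting rates are scaled to sum to 10^6. With
    ``mask_absent`` the counts of vOTUs failing the breadth-based presence
    rule are zeroed *before* normalization, so present vOTUs absorb the
    full 10^6; the default keeps all mapped reads in the denominator,
    treating presence and abundance as separate assessments. Samples with
    no counted reads yield an all-zero column.
    """
    validate_coverage(cov)
    reads = cov["mapped_reads"].astype(float)
    if mask_absent:
        breadth = cov["covered_bases"] / cov["contig_length"]
        reads = reads.where(breadth >= breadth_threshold, 0.0)
    rate = reads / (cov["contig_length"] / 1000.0)
    table = cov.assign(rate=rate).pivot(index="votu_id", columns="sample_id", values="rate")
    table = table.fillna(0.0)
    totals = table.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = table.divide(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def read_depth_file(
    path,
    lengths: dict[str, int] | pd.Series,
    sample_id: str,
    read_length: int = 150,
) -> pd.DataFrame:
    """Coverage summary rows from a samtools-depth style file.

    The file has three tab- or whitespace-separated columns: reference id,
    1-based position, depth. Positions with zero depth may be omitted.
    Contig lengths must be supplied (they cannot be inferred from the
    deepest position). ``mapped_reads`` is estimated as
    round(total depth / read_length).

    Raises :class:`DepthParseError` with the offending line number on
    malformed input.
    """
    if isinstance(lengths, pd.Series):
        lengths = lengths.to_dict()
    covered: dict[str, int] = {}
    depth_sum: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise DepthParseError(path, lineno, f"expected 3 columns, got {len(fields)}")
            ref, pos_s, depth_s = fields
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError:
                raise DepthParseError(path, lineno, "position and depth must be integers") from None
            if pos < 1:
                raise DepthParseError(path, lineno, "positions are 1-based (>= 1)")
            if depth < 0:
                raise DepthParseError(path, lineno, "depth must be non-negative")
            if ref not in lengths:
                raise DepthParseError(path, lineno, f"unknown reference {ref!r}")
            if pos > lengths[ref]:
                raise DepthParseError(
                    path, lineno, f"position {pos} exceeds length {lengths[ref]} of {ref!r}"
                )
            if depth >= 1:
                covered[ref] = covered.get(ref, 0) + 1
                depth_sum[ref] = depth_sum.get(ref, 0) + depth
    rows = [
        {
            "votu_id": ref,
            "sample_id": sample_id,
            "contig_length": int(length),
            "covered_bases": covered.get(ref, 0),
            "mapped_reads": int(round(depth_sum.get(ref, 0) / read_length)),
        }
        for ref, length in lengths.items()
    ]
    return pd.DataFrame(rows, columns=COVERAGE_COLUMNS)


def write_depth_file(path, cov: pd.DataFrame, read_length: int = 150) -> None:
    """Write a per-base depth file realizing a coverage summary.

    Inverse of :func:`read_depth_file` for one sample: each vOTU's
    ``mapped_reads * read_length`` bases of depth are spread uniformly over
    its first ``covered_bases`` positions, so reading the file back with
    the same ``read_length`` reproduces the summary exactly.
    """
    validate_coverage(cov)
    if cov["sample_id"].nunique() > 1:
        raise ValueError("depth files are per-sample; got multiple sample ids")
    short = cov["mapped_reads"] * read_length < cov["covered_bases"]
    if short.any():
        bad = cov.loc[short, "votu_id"].iloc[0]
        raise ValueError(
            f"{bad}: mapped_reads * read_length < covered_bases; "
            "reads cannot physically cover that many positions"
        )
    with open(path, "w") as fh:
        for row in cov.itertuples(index=False):
            c = int(row.covered_bases)
            if c == 0:
                continue
            total = int(row.mapped_reads) * read_length
            base, extra = divmod(total, c)  # >=1 depth on every covered base
            for pos in range(1, c + 1):
                depth = base + (1 if pos <= extra else 0)
                fh.write(f"{row.votu_id}\t{pos}\t{depth}\n")


def fasta_lengths(path) -> pd.Series:
    """Sequence lengths from a FASTA file (id -> length)."""
    from Bio import SeqIO

    data = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return pd.Series(data, name="length", dtype=int)


def read_length_table(path) -> pd.Series:
    """Lengths from a two-column TSV (id, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["seq_id", "length"], comment="#")
    return pd.Series(df["length"].to_numpy(int), index=df["seq_id"], name="length")
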