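"""Richness, rarefaction, richness hypothesis tests, and beta-diversity ordination.

Covers the community-level descriptive statistics of the analysis:
per-sample vOTU richness with group labels, permutation-based species
accumulation (rarefaction) curves, exact/asymptotic Mann-Whitney tests
for richness contrasts between small groups, Bray-Curtis dissimilarity
on TPM abundances, non-metric multidimensional scaling (NMDS, Kruskal
stress-1) and PERMANOVA on the resulting dissimilarity matrix.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from sklearn.isotonic import IsotonicRegression

from .design import sample_labels


@dataclass
class RarefactionCurve:
    """Cumulative richness as samples accumulate in random order."""

    k: np.ndarray  # sample counts 1..N
    mean_richness: np.ndarray  # mean cumulative richness at each k
    per_permutation: np.ndarray  # (n_permutations, N) cumulative richness
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "mean_richness": self.mean_richness})


@dataclass
class MannWhitneyResult:
    U: float
    p_value: float
    method: str  # "exact" or "asymptotic"


@dataclass
class OrdinationResult:
    """NMDS configuration; coordinates are defined up to rotation/reflection."""

    coordinates: pd.DataFrame  # samples x k
    stress: float  # Kruskal stress-1 of the best restart
    converged: bool
    n_restarts: int
    stress_history: np.ndarray  # accepted-iteration stress values, best restart


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    method: str  # "sampled" or "exact"


def richness(occ: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-sample vOTU counts with phenotype/compartment labels.

    Raises ValueError if the occurrence matrix contains samples absent
    from the design.
    """
    labels = sample_labels(design)
    unknown = set(occ.columns) - set(labels.index)
    if unknown:
        raise ValueError(f"samples not in design: {sorted(unknown)}")
    counts = occ.sum(axis=0).astype(int)
    out = pd.DataFrame(
        {
            "sample_id": counts.index,
            "phenotype": labels.loc[counts.index, "phenotype"].to_numpy(),
            "compartment": labels.loc[counts.index, "compartment"].to_numpy(),
            "richness": counts.to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def rarefaction(
    occ: pd.DataFrame, n_permutations: int = 100, seed: int | None = None
) -> RarefactionCurve:
    """Species-accumulation curve over random sample orderings.

    For each of ``n_permutations`` uniformly random orderings of the
    samples, records the cumulative number of distinct vOTUs present after
    the first k samples; the mean over orderings is the reported curve.
    """
    if occ.shape[1] < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    M = occ.to_numpy(bool)
    n_samples = M.shape[1]
    curves = np.empty((n_permutations, n_samples), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(n_samples)
        seen = np.cumsum(M[:, order], axis=1) > 0
        curves[p] = seen.sum(axis=0)
    return RarefactionCurve(
        k=np.arange(1, n_samples + 1),
        mean_richness=curves.mean(axis=0),
        per_permutation=curves,
        n_permutations=n_permutations,
    )


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test between two richness groups.

    Uses the exact null distribution when both groups have at most 8
    observations and there are no ties (the regime of 4-replicate designs);
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 8 and b.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return MannWhitneyResult(U=float(res.statistic), p_value=float(res.pvalue), method=method)


def pairwise_mann_whitney(
    rich: pd.DataFrame, holm: bool = False
) -> pd.DataFrame:
    """All pairwise richness contrasts between phenotype x compartment cells.

    ``rich`` is the output of :func:`richness`. Raw p-values are reported
    by default; ``holm`` applies a Holm step-down correction across the
    pairwise family.
    """
    cells = rich.groupby(["phenotype", "compartment"], sort=True)["richness"].apply(list)
    rows = []
    for (ka, va), (kb, vb) in itertools.combinations(cells.items(), 2):
        r = mann_whitney(va, vb)
        rows.append(
            {
                "group_a": f"{ka[0]}/{ka[1]}",
                "group_b": f"{kb[0]}/{kb[1]}",
                "U": r.U,
                "p_value": r.p_value,
                "method": r.method,
            }
        )
    out = pd.DataFrame(rows)
    if holm and len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    return out


def bray_curtis(abund: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity between samples (columns of ``abund``).

    BC(x, y) = 1 - 2 sum_i min(x_i, y_i) / (sum x + sum y). Pairs of
    all-zero samples are undefined under the formula and are reported as 0
    with a warning.
    """
    X = abund.to_numpy(float).T  # samples x votus
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    samples = list(abund.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        condensed = pdist(X, metric="braycurtis")
    if np.isnan(condensed).any():
        warnings.warn(
            "all-zero sample pair(s) in Bray-Curtis; dissimilarity reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        condensed = np.nan_to_num(condensed, nan=0.0)
    D = squareform(condensed)
    return pd.DataFrame(D, index=samples, columns=samples)


def _check_square_dissim(dissim) -> tuple[np.ndarray, list]:
    if isinstance(dissim, pd.DataFrame):
        labels = list(dissim.index)
        D = dissim.to_numpy(float)
    else:
        D = np.asarray(dissim, dtype=float)
        labels = list(range(D.shape[0]))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return D, labels


def _nmds_single(
    D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, np.ndarray]:
    """One SMACOF-style NMDS run from a random start.

    Alternates isotonic regression of configuration distances on the rank
    order of the input dissimilarities (giving disparities) with a Guttman
    transform using those disparities. An update is accepted only if
    Kruskal stress-1 decreases, so the recorded stress history is
    monotone non-increasing.
    """
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    target = D[iu]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    X = rng.normal(size=(n, k))

    def stress1(X):
        d = pdist(X)
        disp = iso.fit(target, d).predict(target)
        denom = float((d**2).sum())
        if denom == 0.0:
            return 0.0, d, disp
        s = math.sqrt(float(((d - disp) ** 2).sum()) / denom)
        return s, d, disp

    history = []
    stress, d, disp = stress1(X)
    history.append(stress)
    converged = False
    for _ in range(max_iter):
        if stress == 0.0:
            converged = True
            break
        # Guttman transform with current disparities
        ratio = np.zeros_like(d)
        nz = d > 0
        ratio[nz] = disp[nz] / d[nz]
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X_new = B @ X / n
        new_stress, new_d, new_disp = stress1(X_new)
        if new_stress > stress:  # reject non-improving step
            break
        improvement = stress - new_stress
        X, stress, d, disp = X_new, new_stress, new_d, new_disp
        history.append(stress)
        if improvement < tol:
            converged = True
            break
    return X, stress, converged, np.asarray(history)


def nmds(
    dissim,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Runs ``n_restarts`` random initializations of an iterative
    monotone-regression (SMACOF) scheme and returns the lowest-stress
    configuration. Coordinates are meaningful up to rotation, reflection
    and translation.
    """
    D, labels = _check_square_dissim(dissim)
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    if n == 1:
        coords = pd.DataFrame(np.zeros((1, k)), index=labels)
        return OrdinationResult(coords, 0.0, True, n_restarts, np.array([0.0]))
    best = None
    for _ in range(n_restarts):
        X, stress, converged, history = _nmds_single(D, k, rng, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, converged, history)
    X, stress, converged, history = best
    coords = pd.DataFrame(
        X - X.mean(axis=0), index=labels, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coords, float(stress), converged, n_restarts, history)


def _pseudo_f(D2: np.ndarray, group_indices: list[np.ndarray]) -> tuple[float, float]:
    """Anderson's PERMANOVA pseudo-F and R^2 from squared dissimilarities."""
    n = D2.shape[0]
    a = len(group_indices)
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for idx in group_indices:
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dissim,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
    method: str = "sampled",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    The pseudo-F statistic partitions the sum of squared dissimilarities
    into among- and within-group components; significance comes from
    uniformly random label permutations, p = (1 + #{F_perm >= F_obs}) /
    (1 + n_permutations). ``method="exact"`` enumerates all label
    permutations instead (guarded to n <= 8 samples) and reports the exact
    permutation p-value.
    """
    D, sample_ids = _check_square_dissim(dissim)
    if isinstance(labels, dict):
        lab = np.asarray([labels[s] for s in sample_ids])
    elif isinstance(labels, pd.Series):
        lab = labels.loc[sample_ids].to_numpy()
    else:
        lab = np.asarray(list(labels))
        if lab.size != len(sample_ids):
            raise ValueError("labels must cover all samples")
    groups, inv = np.unique(lab, return_inverse=True)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(inv)
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least two groups with two or more samples")
    D2 = D**2
    n = D.shape[0]

    def f_of(assign: np.ndarray) -> float:
        idx = [np.flatnonzero(assign == g) for g in range(groups.size)]
        return _pseudo_f(D2, idx)[0]

    f_obs, r2 = _pseudo_f(D2, [np.flatnonzero(inv == g) for g in range(groups.size)])

    if method == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8 samples")
        perms = list(itertools.permutations(range(n)))
        count = sum(1 for p in perms if f_of(inv[np.asarray(p)]) >= f_obs - 1e-12)
        p_value = count / len(perms)
        n_used = len(perms)
    elif method == "sampled":
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if f_of(inv[perm]) >= f_obs - 1e-12:
                count += 1
        p_value = (1 + count) / (1 + n_permutations)
        n_used = n_permutations
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p_value),
        n_permutations=n_used,
        method=method,
    )
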