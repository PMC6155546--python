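"""Alpha and beta diversity over OTU tables.

Richness at OTU or taxon rank, analytic rarefaction (hypergeometric expected
richness rather than repeated subsampling, so the curves are deterministic),
median-sequencing-depth normalization, Bray-Curtis dissimilarity, and
classical PCoA (metric multidimensional scaling). Normalized counts are kept
fractional; Bray-Curtis accepts fractional abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from gyrbench.amplicon_pipeline import OTUTable
from gyrbench.refdb import RANKS

__all__ = [
    "richness",
    "rarefy_expected",
    "rarefaction_curve",
    "median_depth_normalize",
    "bray_curtis",
    "bray_curtis_matrix",
    "Ordination",
    "pcoa",
    "composition_table",
]

logger = logging.getLogger(__name__)


def richness(
    table: OTUTable, rank: str = "otu", assignments: pd.DataFrame | None = None
) -> pd.Series:
    """Observed richness per sample.

    ``rank='otu'`` counts OTUs with nonzero counts; a taxonomy rank (e.g.
    ``genus``, ``species``) first merges OTU counts by their assigned taxon
    at that rank and counts nonzero taxa. OTUs whose assignment is truncated
    above the requested rank are excluded from taxon-rank counts.
    """
    if rank == "otu":
        return (table.df > 0).sum(axis=0)
    if rank not in RANKS[:7]:
        raise ValueError(f"rank must be 'otu' or one of {RANKS[:7]}")
    if assignments is None:
        raise ValueError("taxon-rank richness requires assignments")
    merged = merge_by_rank(table, assignments, rank)
    return (merged > 0).sum(axis=0)


def merge_by_rank(table: OTUTable, assignments: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Sum OTU counts into taxa at the given rank (plot-ready table)."""
    taxon = assignments.set_index("otu_id")[rank]
    labels = taxon.reindex(table.df.index)
    keep = labels.notna() & (labels != "")
    return table.df.loc[keep].groupby(labels[keep]).sum()


def rarefy_expected(counts: np.ndarray | pd.Series, n: int) -> float:
    """Expected richness in a random subsample of ``n`` reads.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)], evaluated with log-gamma
    arithmetic. Exact endpoints: 0 at n=0, observed richness at n=N.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if not 0 <= n <= total:
        raise ValueError(f"subsample size {n} outside [0, {total}]")
    if n == 0:
        return 0.0

    def log_choose(a: np.ndarray | int, b: int) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rest = total - counts
    with np.errstate(invalid="ignore"):
        log_p_absent = np.where(
            rest >= n, log_choose(rest, n) - log_choose(total, n), -np.inf
        )
    return float(np.sum(1.0 - np.exp(log_p_absent)))


def rarefaction_curve(
    table: OTUTable, points: int = 20
) -> pd.DataFrame:
    """Per-sample rarefaction grid: (sample, n, expected_richness)."""
    rows = []
    for sample in table.samples:
        counts = table.df[sample].to_numpy()
        total = int(counts.sum())
        grid = np.unique(np.linspace(0, total, points + 1).astype(int))
        for n in grid:
            rows.append(
                {"sample": sample, "n": int(n), "expected_richness": rarefy_expected(counts, int(n))}
            )
    return pd.DataFrame(rows)


def median_depth_normalize(table: OTUTable) -> OTUTable:
    """Scale every sample to the median sequencing depth of all samples.

    Each sample's counts are multiplied by median(depths) / depth, so totals
    after normalization all equal the median depth. Counts become fractional.
    """
    depths = table.df.sum(axis=0)
    median = float(depths.median())
    factors = median / depths
    df = table.df * factors
    return OTUTable(df=df, representatives=dict(table.representatives), d=table.d)


def bray_curtis(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> float:
    """Bray-Curtis dissimilarity: 1 - 2 sum(min) / sum(x + y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("abundance vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    denom = float((x + y).sum())
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * float(np.minimum(x, y).sum()) / denom


def bray_curtis_matrix(table: OTUTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between samples (columns)."""
    df = table.df if isinstance(table, OTUTable) else table
    samples = list(df.columns)
    n = len(samples)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = bray_curtis(df.iloc[:, i], df.iloc[:, j])
    return pd.DataFrame(mat, index=samples, columns=samples)


@dataclass
class Ordination:
    """Principal coordinates: sample coordinates and variance shares."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, decreasing
    proportion_explained: np.ndarray  # fractions of the positive-eigenvalue sum


def pcoa(distances: pd.DataFrame) -> Ordination:
    """Classical metric scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, orders axes by decreasing
    eigenvalue and keeps the positive ones; negative eigenvalues (expected
    for non-Euclidean distances like Bray-Curtis) are dropped from the
    variance denominator with a logged warning. No Cailliez correction.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigval[0]), 1.0))
    if (eigval < -tol).any():
        logger.warning(
            "pcoa: %d negative eigenvalues dropped (non-Euclidean distances)",
            int((eigval < -tol).sum()),
        )
    keep = eigval > tol
    eigval = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(eigval)
    labels = list(distances.index) if isinstance(distances, pd.DataFrame) else list(range(n))
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=labels, columns=axes),
        eigenvalues=eigval,
        proportion_explained=eigval / eigval.sum() if eigval.size else eigval,
    )


def composition_table(
    table: OTUTable, assignments: pd.DataFrame, rank: str = "phylum"
) -> pd.DataFrame:
    """Relative abundances per taxon at a rank (columns = samples; sums to 1)."""
    merged = merge_by_rank(table, assignments, rank)
    totals = merged.sum(axis=0)
    return merged / totals
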