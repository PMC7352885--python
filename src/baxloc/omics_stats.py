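"""Expression-matrix processing: quantile normalization, presence filtering,
t-test differential expression, hierarchical clustering and kNN imputation.

Conventions: matrices are genes x samples on log2 scale; the boolean mask
marks detection-failed entries (array detection p > 0.05 upstream), which are
excluded from every statistic.  Distances between items with missing data are
pairwise-complete by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateSampleError,
    LabelingError,
    UndefinedDistanceError,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression intensities with a detection-failure mask.

    ``values`` holds log2 intensities; ``mask`` is boolean with True marking a
    missing (detection-failed) entry.  Masked entries take part in no
    statistic; ``observed()`` materializes them as NaN.
    """

    values: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.values.index.equals(self.mask.index)
                and self.values.columns.equals(self.mask.columns)):
            raise ValueError("values and mask must share index and columns")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def observed(self) -> pd.DataFrame:
        """Values with masked entries as NaN."""
        return self.values.where(~self.mask)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], self.mask.loc[genes])

    @classmethod
    def from_observed(cls, observed: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a NaN-marked matrix (NaN becomes a masked entry)."""
        return cls(values=observed.fillna(0.0), mask=observed.isna())


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean of order statistics.

    For complete columns this is classic quantile normalization: sort each
    sample, average across samples at each rank, and hand each value the mean
    order statistic of its rank (ties receive the average of their ranks'
    reference values), so all samples end up with identical value multisets
    and unchanged within-sample ranks.  Samples with missing entries are
    mapped through the same reference distribution by interpolating on the
    fractional rank of their observed values.  Idempotent.
    """
    obs = m.observed()
    if obs.shape[1] < 2:
        raise DegenerateSampleError("quantile normalization needs >= 2 samples")
    counts = obs.notna().sum(axis=0)
    if (counts == 0).any():
        bad = list(counts.index[counts == 0])
        raise DegenerateSampleError(f"samples with no observed values: {bad}")

    n_genes = obs.shape[0]
    if counts.min() == n_genes:
        ref = np.mean(np.sort(obs.to_numpy(), axis=0), axis=1)
        out = obs.copy()
        for col in obs.columns:
            v = obs[col].to_numpy()
            order = st.rankdata(v, method="average") - 1.0  # 0-based, ties averaged
            lo = np.floor(order).astype(int)
            hi = np.ceil(order).astype(int)
            out[col] = (ref[lo] + ref[hi]) / 2.0
    else:
        # reference distribution on a common fractional-rank grid; each
        # sample's observed values are mapped through it by interpolation
        grid = (np.arange(n_genes) + 0.5) / n_genes
        per_sample = []
        for col in obs.columns:
            v = np.sort(obs[col].dropna().to_numpy())
            q = (np.arange(v.size) + 0.5) / v.size
            per_sample.append(np.interp(grid, q, v))
        ref = np.mean(per_sample, axis=0)
        out = obs.copy()
        for col in obs.columns:
            v = obs[col].to_numpy()
            idx = ~np.isnan(v)
            r = (st.rankdata(v[idx], method="average") - 0.5) / idx.sum()
            v = v.copy()
            v[idx] = np.interp(r, grid, ref)
            out[col] = v
    return ExpressionMatrix(values=out.fillna(m.values), mask=m.mask.copy())


def presence_filter(m: ExpressionMatrix, min_presence: float = 0.8) -> ExpressionMatrix:
    """Keep genes observed (unmasked) in at least ``min_presence`` of samples.

    The boundary is inclusive: a gene present in exactly 80% of samples
    survives the default filter.  Values are never altered.
    """
    frac = 1.0 - m.mask.mean(axis=1)
    keep = m.values.index[frac >= min_presence]
    return m.subset_genes(keep)


def de_genes(
    m: ExpressionMatrix,
    labels,
    alpha: float = 0.05,
    min_per_class: int = 2,
) -> pd.DataFrame:
    """Per-gene Student's (pooled-variance) t-test between two label classes.

    ``labels`` maps sample id to class (mapping, or sequence aligned with
    ``m.samples``).  Masked values are dropped per gene; genes with fewer than
    ``min_per_class`` observed values in either class, or zero pooled
    variance, are skipped and logged.  Returns a table of all tested genes
    (gene, t, df, p, p_bh, mean_diff, selected) sorted by p; ``selected``
    flags p < alpha.  Benjamini-Hochberg adjusted p-values are reported
    alongside so selection can be tightened.
    """
    if not isinstance(labels, dict):
        labels = dict(zip(m.samples, labels))
    classes = sorted({labels[s] for s in m.samples}, key=str)
    if len(classes) != 2:
        raise LabelingError(f"need exactly 2 label classes, got {classes}")
    cols_a = [s for s in m.samples if labels[s] == classes[0]]
    cols_b = [s for s in m.samples if labels[s] == classes[1]]

    obs = m.observed()
    a = obs[cols_a].to_numpy()
    b = obs[cols_b].to_numpy()
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore"):
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nansum((a - ma[:, None]) ** 2, axis=1)
        vb = np.nansum((b - mb[:, None]) ** 2, axis=1)
    df = na + nb - 2
    pooled = np.where(df > 0, (va + vb) / np.maximum(df, 1), np.nan)
    tested = (na >= min_per_class) & (nb >= min_per_class) & (pooled > 0)
    n_skipped = int(np.sum(~tested))
    if n_skipped:
        log.info("de_genes: skipped %d genes (insufficient observations or "
                 "zero pooled variance)", n_skipped)

    se = np.sqrt(pooled * (1.0 / np.maximum(na, 1) + 1.0 / np.maximum(nb, 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mb - ma) / se
    p = 2.0 * st.t.sf(np.abs(t), np.maximum(df, 1))

    out = pd.DataFrame({
        "gene": m.genes,
        "t": t,
        "df": df,
        "p": p,
        "mean_diff": mb - ma,
    }).loc[tested]
    out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1] if len(out) else []
    out["selected"] = out["p"] < alpha
    return out.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history over named leaves.

    ``merges`` is the scipy-style linkage matrix (n-1 rows: left id, right id,
    height, size) over leaf ids 0..n-1 in ``leaves`` order.
    """

    leaves: tuple[str, ...]
    merges: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = sch.leaves_list(self.merges)
        return [self.leaves[i] for i in order]

    def cut(self, k: int) -> pd.Series:
        """Cluster labels (1..k) from cutting the tree into k groups."""
        labels = sch.fcluster(self.merges, t=k, criterion="maxclust")
        return pd.Series(labels, index=list(self.leaves), name="cluster")

    def to_newick(self) -> str:
        n = len(self.leaves)
        node: dict[int, str] = {i: name for i, name in enumerate(self.leaves)}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for j, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + j] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + j] = h
        return node[n + len(self.merges) - 1] + ";"


def _pairwise_distance(obs: np.ndarray, metric: str, min_complete: int = 3) -> np.ndarray:
    """Condensed distance over rows with pairwise-complete handling of NaN."""
    n = obs.shape[0]
    if not np.isnan(obs).any():
        if metric == "pearson":
            if obs.shape[1] < min_complete:
                raise UndefinedDistanceError(
                    f"need >= {min_complete} values per item for Pearson distance")
            if (obs.std(axis=1) == 0).any():
                raise UndefinedDistanceError("zero-variance item under Pearson distance")
            # scipy's correlation distance is exactly 1 - Pearson r
            return ssd.pdist(obs, metric="correlation")
        return ssd.pdist(obs, metric="euclidean")
    d = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(np.isnan(obs[i]) | np.isnan(obs[j]))
            x, y = obs[i, shared], obs[j, shared]
            if metric == "pearson":
                if shared.sum() < min_complete:
                    raise UndefinedDistanceError(
                        f"items {i} and {j} share only {int(shared.sum())} "
                        f"observed values (< {min_complete}) for Pearson distance")
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    raise UndefinedDistanceError(
                        f"zero variance on shared values between items {i} and {j}")
                r = np.corrcoef(x, y)[0, 1]
                d[idx] = 1.0 - r
            else:  # euclidean over shared observed values
                if shared.sum() < 1:
                    raise UndefinedDistanceError(
                        f"items {i} and {j} share no observed values")
                d[idx] = float(np.sqrt(np.sum((x - y) ** 2)))
            idx += 1
    return d


def hierarchical_cluster(
    m: ExpressionMatrix,
    distance: str = "pearson",
    axis: str = "samples",
    k: int | None = None,
) -> Dendrogram | tuple[Dendrogram, pd.Series]:
    """Complete-linkage agglomerative clustering of samples (or genes).

    ``distance`` is ``"pearson"`` (1 - r on pairwise-complete values, the
    signature-clustering metric) or ``"euclidean"`` (over shared observed
    values, the patient-integration metric).  Returns the dendrogram, plus
    k-cut labels when ``k`` is given.  Deterministic for a given input.
    """
    if distance not in ("pearson", "euclidean"):
        raise ValueError(f"unknown distance {distance!r}")
    obs = m.observed()
    items = obs.columns if axis == "samples" else obs.index
    if len(items) < 2:
        raise ValueError("need >= 2 items to cluster")
    data = obs.to_numpy().T if axis == "samples" else obs.to_numpy()
    cond = _pairwise_distance(data, distance)
    merges = sch.linkage(cond, method="complete")
    dendro = Dendrogram(leaves=tuple(items), merges=merges)
    if k is None:
        return dendro
    return dendro, dendro.cut(k)


def knn_impute(m: ExpressionMatrix, k: int = 10) -> tuple[ExpressionMatrix, list]:
    """Fill missing entries with the mean of the k nearest genes' values.

    Gene-gene distance is the plain Euclidean distance over the samples both
    genes observe; the k nearest genes among those observed at the target
    sample supply an unweighted mean.  Entries with no donor gene are reported
    (second return value, (gene, sample) pairs) and left masked.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    obs = m.observed()
    data = obs.to_numpy()
    n_genes = data.shape[0]
    filled = data.copy()
    unimputable: list[tuple[str, str]] = []
    missing_rows = np.where(np.isnan(data).any(axis=1))[0]
    for gi in missing_rows:
        row = data[gi]
        shared = ~np.isnan(data) & ~np.isnan(row)[None, :]
        with np.errstate(invalid="ignore"):
            sq = np.where(shared, (data - row[None, :]) ** 2, 0.0)
        dist = np.sqrt(sq.sum(axis=1))
        dist[shared.sum(axis=1) == 0] = np.inf
        dist[gi] = np.inf
        order = np.argsort(dist, kind="stable")
        for sj in np.where(np.isnan(row))[0]:
            donors = [g for g in order
                      if np.isfinite(dist[g]) and not np.isnan(data[g, sj])][:k]
            if donors:
                filled[gi, sj] = data[donors, sj].mean()
            else:
                unimputable.append((m.genes[gi], m.samples[sj]))
    out_values = pd.DataFrame(filled, index=m.genes, columns=m.samples)
    out_mask = pd.DataFrame(np.isnan(filled), index=m.genes, columns=m.samples)
    out_values = out_values.fillna(m.values)
    if unimputable:
        log.info("knn_impute: %d entries had no donors and stay masked",
                 len(unimputable))
    return ExpressionMatrix(values=out_values, mask=out_mask), unimputable
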