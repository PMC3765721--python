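"""Cross-sample variability: CV, pooled t statistics, clustering, m/v.

The cross-sample unit of analysis is the expression matrix of rescaled
RPKMs, one row per (exon, host gene) pair and one column per sample.  A
cell is *missing* (NaN) when the host gene was un-expressed in that
sample -- gene-level filtering precedes all cross-sample statistics, so
missing cells are excluded from CV and median computations rather than
treated as zeros.  Clustering, which cannot tolerate missing entries,
zero-imputes them by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .annotation import AnnotationSet
from .quantify import SampleExpression

__all__ = [
    "ExpressionMatrix",
    "build_expression_matrix",
    "cv",
    "eligible_exons",
    "pooled_t",
    "group_t_statistics",
    "hcluster",
    "linkage_to_newick",
    "dispersion_summary",
    "kendall_tau",
]


@dataclass
class ExpressionMatrix:
    """Rescaled-RPKM matrix with exon metadata and sample group labels.

    ``values`` is indexed by (exon_id, gene_id) with one column per
    sample; NaN marks host-gene-un-expressed cells.  ``exon_meta``
    carries the exon class per row; ``sample_groups`` maps group-label
    columns (e.g. a disease contrast) to per-sample labels.
    """

    values: pd.DataFrame
    exon_meta: pd.DataFrame
    sample_groups: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_classes(self, *classes: str) -> "ExpressionMatrix":
        mask = self.exon_meta["exon_class"].isin(classes).to_numpy()
        return ExpressionMatrix(self.values.loc[mask],
                                self.exon_meta.loc[mask],
                                self.sample_groups)


def build_expression_matrix(samples: Sequence[SampleExpression],
                            annot: AnnotationSet,
                            sample_groups: pd.DataFrame | None = None,
                            ) -> ExpressionMatrix:
    """Assemble per-sample rescaled values into one (exon, gene) x sample
    matrix.  Cells absent from a sample's rescaled map (host gene
    un-expressed there) become NaN."""
    cols = {s.sample_id: s.rescaled for s in samples}
    values = pd.DataFrame(cols)
    values.index.names = ["exon_id", "gene_id"]
    exon_df = annot.tables()["exons"]
    meta = pd.DataFrame(
        {"exon_class": exon_df["exon_class"].reindex(
            values.index.get_level_values("exon_id")).to_numpy()},
        index=values.index)
    if sample_groups is None:
        sample_groups = pd.DataFrame(index=list(cols))
    return ExpressionMatrix(values=values, exon_meta=meta,
                            sample_groups=sample_groups)


def cv(values: Sequence[float]) -> float:
    """Coefficient of variance in percent: 100 x sample SD / mean.

    Missing (NaN) entries are excluded.  Undefined (fewer than two
    observations, or zero mean) is reported as NaN.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    mean = v.mean()
    if mean <= 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


def eligible_exons(matrix: ExpressionMatrix,
                   min_samples: int | None = None) -> pd.Index:
    """Rows whose host gene is expressed in at least ``min_samples``
    samples (default: half the samples, rounded up)."""
    if min_samples is None:
        min_samples = -(-matrix.n_samples // 2)
    n_obs = matrix.values.notna().sum(axis=1)
    return matrix.values.index[n_obs >= min_samples]


def pooled_t(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sample t statistic with pooled (equal-variance) SD.

    Returns NaN when the pooled SD is zero.  Antisymmetric in its
    arguments.
    """
    a = np.asarray(group_a, dtype=float)
    a = a[~np.isnan(a)]
    b = np.asarray(group_b, dtype=float)
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / (a.size + b.size - 2))
    if sp2 <= 0:
        return float("nan")
    se = np.sqrt(sp2) * np.sqrt(1.0 / a.size + 1.0 / b.size)
    return float((a.mean() - b.mean()) / se)


def group_t_statistics(matrix: ExpressionMatrix, contrast: str,
                       group_a: str, group_b: str) -> pd.Series:
    """Per-exon pooled-SD t statistics for a two-group sample contrast."""
    labels = matrix.sample_groups[contrast]
    cols_a = labels.index[labels == group_a]
    cols_b = labels.index[labels == group_b]
    out = {}
    for idx, row in matrix.values.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        if np.isnan(a).sum() > a.size - 2 or np.isnan(b).sum() > b.size - 2:
            out[idx] = float("nan")
        else:
            out[idx] = pooled_t(a, b)
    return pd.Series(out, name=f"t_{group_a}_vs_{group_b}")


def hcluster(samples_by_features: pd.DataFrame, k: int = 2,
             *, impute_missing_as_zero: bool = True,
             ) -> tuple[np.ndarray, pd.Series]:
    """Complete-linkage Euclidean clustering of samples.

    Rows are samples, columns features (typically the TE-exon columns of
    the expression matrix, transposed).  Missing values are zero-imputed
    by default.  Returns the scipy linkage matrix (merge heights
    non-decreasing; ties broken deterministically, lowest observation
    index first) and flat cluster labels at ``k`` clusters.
    """
    if samples_by_features.shape[0] < 2:
        raise ValueError("need at least two samples to cluster")
    X = samples_by_features.to_numpy(dtype=float)
    if np.isnan(X).any():
        if not impute_missing_as_zero:
            raise ValueError("missing values present; enable zero imputation")
        X = np.nan_to_num(X, nan=0.0)
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, pd.Series(labels, index=samples_by_features.index,
                        name="cluster")


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def dispersion_summary(matrix: ExpressionMatrix,
                       min_samples: int = 13) -> pd.DataFrame:
    """Per-exon median (m) and CV (v) of expression across samples.

    Restricted to exons whose host gene is expressed in at least
    ``min_samples`` samples; missing cells are excluded from both
    statistics.  Returns columns ``m``, ``v`` (percent) and
    ``n_expressed_samples``.
    """
    idx = eligible_exons(matrix, min_samples)
    sub = matrix.values.loc[idx]
    m = sub.median(axis=1, skipna=True)
    v = sub.apply(lambda row: cv(row.to_numpy(dtype=float)), axis=1)
    n_obs = sub.notna().sum(axis=1)
    return pd.DataFrame({"m": m, "v": v, "n_expressed_samples": n_obs})


def kendall_tau(m_list: Sequence[float], v_list: Sequence[float]
                ) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b and its two-sided p-value.

    Pairs with a missing member are dropped; an all-tied input yields
    (nan, nan).
    """
    m = np.asarray(m_list, dtype=float)
    v = np.asarray(v_list, dtype=float)
    if m.size != v.size:
        raise ValueError("m and v must be paired")
    mask = ~(np.isnan(m) | np.isnan(v))
    m, v = m[mask], v[mask]
    if m.size < 2 or np.unique(m).size == 1 or np.unique(v).size == 1:
        return float("nan"), float("nan")
    res = stats.kendalltau(m, v, variant="b")
    return float(res.statistic), float(res.pvalue)
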