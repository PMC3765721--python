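"""Per-sample class summaries and the stepwise nonparametric test ladder.

For each exon class the per-sample summary reports R (fraction of
un-expressed exons, i.e. count 0 within expressed genes), and M and SD
(mean and sample standard deviation of the rescaled RPKMs over the exons
with at least one read).  The class ladder C1 > C2 > C3 > C4 > C5 is
probed by four stepwise tests: Mann-Whitney for the three independent
comparisons (C1 vs C2, C2 vs C3, C3 vs C4) and a paired Wilcoxon
signed-rank test for C4 vs C5 (decoys are index-paired with their C4
exons).  Unless configured otherwise the tests compare whole rescaled-
RPKM distributions with zeros included, since the un-expressed mass is
part of an exon class's digital expression profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet
from .quantify import SampleExpression

__all__ = [
    "ClassSummary",
    "class_summary",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "sample_class_values",
    "stepwise_class_tests",
    "class_summary_table",
    "histogram_log10",
]

CLASS_ORDER = ("C1", "C2", "C3", "C4", "C5")
STEPWISE_PAIRS = (("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"))


@dataclass
class ClassSummary:
    """R/M/SD summary of one exon class in one sample.

    ``m_mean`` and ``sd`` are None when no exon of the class has a read
    (undefined statistics are reported as missing, never as 0).
    """

    sample_id: str
    exon_class: str
    r_unexpressed: float
    m_mean: float | None
    sd: float | None
    n_total: int
    n_expressed: int


def class_summary(rescaled_values: Sequence[tuple[float, bool]],
                  sample_id: str, exon_class: str) -> ClassSummary:
    """Summarize (value, has-read flag) pairs for one class and sample."""
    if len(rescaled_values) == 0:
        raise ValueError(f"no values for class {exon_class}")
    values = np.array([v for v, _ in rescaled_values], dtype=float)
    expressed = np.array([bool(f) for _, f in rescaled_values])
    n = values.size
    n_exp = int(expressed.sum())
    r = 1.0 - n_exp / n
    if n_exp == 0:
        m = sd = None
    else:
        sub = values[expressed]
        m = float(sub.mean())
        sd = float(sub.std(ddof=1)) if n_exp > 1 else None
    return ClassSummary(sample_id=sample_id, exon_class=exon_class,
                        r_unexpressed=r, m_mean=m, sd=sd,
                        n_total=n, n_expressed=n_exp)


def mann_whitney(x: Sequence[float], y: Sequence[float]
                 ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for two independent samples.

    Uses the exact U distribution when the pooled size is at most 20
    and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction.  Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]],
                         *, zero_method: str = "wilcox") -> float:
    """Two-sided Wilcoxon signed-rank test for paired values.

    Zero differences are dropped (``zero_method="wilcox"``, default) or
    kept in the Pratt manner (``"pratt"``).  The exact sign-enumeration
    distribution is used for at most 15 informative tie-free pairs;
    otherwise the normal approximation with continuity correction.
    """
    d = np.array([a - b for a, b in pairs], dtype=float)
    informative = d[d != 0]
    if informative.size == 0:
        raise ValueError("all pair differences are zero")
    if zero_method == "wilcox":
        d = informative        # zeros discarded before ranking
    absd = np.abs(informative)
    no_ties = np.unique(absd).size == absd.size
    # Exactness requires tie-free magnitudes and (for Pratt handling) no
    # zeros left in the ranked vector.
    exact_ok = informative.size <= 15 and no_ties and (d != 0).all()
    res = stats.wilcoxon(d, zero_method=zero_method, correction=True,
                         alternative="two-sided",
                         method="exact" if exact_ok else "approx")
    return float(res.pvalue)


def sample_class_values(sample: SampleExpression, annot: AnnotationSet,
                        ) -> dict[str, pd.DataFrame]:
    """Rescaled values and has-read flags per class for one sample.

    Returns a DataFrame per class with columns ``value`` and
    ``expressed``, indexed by (exon_id, gene_id).  Only exons of
    expressed genes appear.  The C4 and C5 frames are index-paired row
    by row (same host-gene expression filter applies to both ends of a
    pair, so the pairing survives the gene filter intact).
    """
    exon_df = annot.tables()["exons"]
    idx = sample.rescaled.index
    classes = exon_df["exon_class"].reindex(
        idx.get_level_values("exon_id")).to_numpy()
    counts = sample.exon_counts.reindex(
        idx.get_level_values("exon_id")).to_numpy()
    frame = pd.DataFrame({"value": sample.rescaled.to_numpy(),
                          "expressed": counts > 0,
                          "exon_class": classes}, index=idx)
    out: dict[str, pd.DataFrame] = {}
    for cls in ("C1", "C2", "C3"):
        out[cls] = frame.loc[frame["exon_class"] == cls,
                             ["value", "expressed"]]
    c4 = frame.loc[frame["exon_class"] == "C4", ["value", "expressed"]]
    c5 = frame.loc[frame["exon_class"] == "C5", ["value", "expressed"]]
    # align pairs: C5 id = C4 id + ".sim", shared host gene
    c4_ids = c4.index.get_level_values("exon_id")
    pair_index = pd.MultiIndex.from_arrays(
        [c4_ids + ".sim", c4.index.get_level_values("gene_id")],
        names=["exon_id", "gene_id"])
    mask = pair_index.isin(c5.index)
    out["C4"] = c4.loc[mask]
    out["C5"] = c5.reindex(pair_index[mask])
    return out


def stepwise_class_tests(class_values: dict[str, pd.DataFrame],
                         *, expressed_only: bool = False,
                         ) -> dict[str, float | None]:
    """The four-step class comparison ladder for one sample.

    Mann-Whitney for C1 vs C2, C2 vs C3 and C3 vs C4; paired Wilcoxon
    signed-rank for C4 vs C5.  Values are rescaled RPKMs, zeros included
    unless ``expressed_only``.  A comparison with an empty class (or a
    degenerate paired test) is reported as None; the others are still
    computed.
    """
    def values(cls: str) -> np.ndarray:
        df = class_values.get(cls)
        if df is None or len(df) == 0:
            return np.array([])
        if expressed_only:
            df = df.loc[df["expressed"]]
        return df["value"].to_numpy()

    out: dict[str, float | None] = {}
    for a, b in STEPWISE_PAIRS[:3]:
        va, vb = values(a), values(b)
        key = f"{a}_vs_{b}"
        if va.size == 0 or vb.size == 0:
            out[key] = None
        else:
            out[key] = mann_whitney(va, vb)[1]
    va, vb = values("C4"), values("C5")
    if expressed_only or va.size == 0 or va.size != vb.size:
        # the paired test is only defined on the index-paired full lists
        pairs = None
    else:
        pairs = list(zip(va, vb))
    if pairs is None:
        out["C4_vs_C5"] = None
    elif all(a == b for a, b in pairs):
        # identical paired lists carry no evidence against the null
        out["C4_vs_C5"] = 1.0
    else:
        out["C4_vs_C5"] = wilcoxon_signed_rank(pairs)
    return out


def class_summary_table(samples: Sequence[SampleExpression],
                        annot: AnnotationSet) -> pd.DataFrame:
    """Long-format sample x class table of R, M, SD and stepwise p."""
    rows = []
    for s in samples:
        cvals = sample_class_values(s, annot)
        pvals = stepwise_class_tests(cvals)
        for cls in CLASS_ORDER:
            df = cvals[cls]
            if len(df) == 0:
                continue
            cs = class_summary(list(zip(df["value"], df["expressed"])),
                               s.sample_id, cls)
            step = next((f"{a}_vs_{b}" for a, b in STEPWISE_PAIRS
                         if b == cls), None)
            rows.append({
                "sample_id": s.sample_id, "exon_class": cls,
                "R": cs.r_unexpressed, "M": cs.m_mean, "SD": cs.sd,
                "n_total": cs.n_total, "n_expressed": cs.n_expressed,
                "p_step": pvals.get(step) if step else None})
    return pd.DataFrame(rows)


def histogram_log10(values: Sequence[float], n_bins: int,
                    cap: float = 10.0,
                    ) -> tuple[float, np.ndarray, np.ndarray]:
    """Zero-separated log10 histogram of non-negative expression values.

    Returns (zero_proportion, bin_edges, bin_counts).  Zeros are set
    aside as a point mass; positive values are binned on the log10 scale
    between the smallest positive value and the cap (values at the cap
    fall in the last bin).  With no positive values the edges and counts
    are empty.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    if (values < 0).any():
        raise ValueError("values must be non-negative")
    zero_prop = float((values == 0).mean())
    pos = values[values > 0]
    if pos.size == 0:
        return 1.0, np.array([]), np.array([])
    lo = math.log10(pos.min())
    hi = math.log10(cap)
    if lo >= hi:
        lo = hi - 1.0                      # degenerate: single point mass
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(np.log10(pos), bins=edges)
    return zero_prop, edges, counts
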