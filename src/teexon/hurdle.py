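"""The two-step (hurdle) regression of genomic factors on TE-exon expression.

Because a large fraction of TE exons have no mapped reads, a single
linear model of log expression is not estimable; the analysis therefore
splits into

* **Model-1** (logistic): presence/absence of expression (z = 1 when the
  exon has at least one read) regressed on the genomic factors;
* **Model-2** (ordinary least squares): log10 rescaled RPKM among the
  exons with non-zero expression, regressed on the same factors.

The shared design has 13 columns in fixed order: intercept; location
indicators UTR3, UTR5 (CDS baseline); family indicators ERV1, ERVL, L1,
L2, MaLR, MER1, MER2, MIR (Alu baseline); log10 exon length (ELN); and
TE nucleotide proportion (RTE).  Baseline coefficients are pinned to
zero by omission.  Exons from the rare CR1 and other_DNA families are
excluded before design construction.

The same design also serves two cross-sample summary fits with the
per-exon median (on log10 scale) and CV of expression as dependent
variables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .annotation import (AnnotationSet, EXCLUDED_FAMILIES, MODELED_FAMILIES,
                         TEExonFeature)
from .quantify import SampleExpression

__all__ = [
    "DESIGN_COLUMNS",
    "HurdleFit",
    "SeparationError",
    "build_design",
    "fit_model1",
    "fit_model2",
    "two_step_fit",
    "fit_summary_models",
    "discretize_p",
    "coefficient_table",
    "category_matrix",
]

DESIGN_COLUMNS = ("intercept", "UTR3", "UTR5",
                  "ERV1", "ERVL", "L1", "L2", "MaLR", "MER1", "MER2", "MIR",
                  "log10ELN", "RTE")

_MAX_ITER = 100
_LL_TOL = 1e-8


class SeparationError(RuntimeError):
    """Complete or quasi-separation in the logistic fit."""


@dataclass
class HurdleFit:
    """Coefficient tables of the two fitted models.

    ``model1``/``model2`` are DataFrames indexed by design term with
    columns estimate, se, p; either may be None when its fit was
    degenerate (recorded in ``notes``).  ``n1``/``n2`` are the
    observation counts of the two steps (n2 <= n1 always).
    """

    model1: pd.DataFrame | None
    model2: pd.DataFrame | None
    n1: int
    n2: int
    tag: str = ""
    notes: list[str] = field(default_factory=list)
    model2_residuals: np.ndarray | None = None


def build_design(features: Iterable[TEExonFeature]) -> pd.DataFrame:
    """Design matrix rows for the given TE-exon features.

    The caller must have removed features of excluded families; one
    slipping through is an error, never silently dropped.
    """
    rows = []
    index = []
    for f in features:
        if f.family in EXCLUDED_FAMILIES:
            raise ValueError(
                f"exon {f.exon_id}: family {f.family!r} is excluded from "
                f"the regression analysis; filter before building the design")
        if f.family not in MODELED_FAMILIES:
            raise ValueError(f"unknown family {f.family!r}")
        row = dict.fromkeys(DESIGN_COLUMNS, 0.0)
        row["intercept"] = 1.0
        if f.location != "CDS":
            row[f.location] = 1.0
        if f.family != "Alu":
            row[f.family] = 1.0
        row["log10ELN"] = math.log10(f.eln)
        row["RTE"] = f.rte
        rows.append(row)
        index.append(f.exon_id)
    return pd.DataFrame(rows, index=index, columns=list(DESIGN_COLUMNS))


def _check_design(X: pd.DataFrame) -> None:
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more observations ({X.shape[0]}) than design columns "
            f"({X.shape[1]})")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        suspects = []
        arr = X.to_numpy()
        for j, name in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                suspects.append(name)
        raise ValueError(f"singular design; collinear columns: {suspects}")


def fit_model1(design: pd.DataFrame, z: Sequence[int]) -> pd.DataFrame:
    """Maximum-likelihood logistic fit of presence/absence.

    Wald standard errors and two-sided p-values per coefficient.
    Degenerate responses (all 0 or all 1) and separation are errors.
    """
    z = np.asarray(z, dtype=float)
    if design.shape[0] != z.size:
        raise ValueError("design and response lengths differ")
    if not np.isin(z, (0.0, 1.0)).all():
        raise ValueError("z must be binary")
    if z.min() == z.max():
        raise ValueError(
            "degenerate response: all exons "
            + ("expressed" if z.min() == 1 else "un-expressed"))
    _check_design(design)
    model = sm.Logit(z, design.to_numpy())
    try:
        # divergence is re-detected below and raised as SeparationError,
        # so statsmodels' own warnings about it are redundant noise
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=_MAX_ITER, tol=_LL_TOL,
                            disp=0)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(str(exc)) from exc
    params = np.asarray(res.params)
    if not res.mle_retvals.get("converged", True) or np.abs(params).max() > 30:
        worst = design.columns[int(np.abs(params).argmax())]
        raise SeparationError(
            f"logistic fit diverged; column {worst!r} separates the response")
    return pd.DataFrame({"estimate": params,
                         "se": np.asarray(res.bse),
                         "p": np.asarray(res.pvalues)},
                        index=design.columns)


def fit_model2(design: pd.DataFrame, y: Sequence[float],
               *, log_transform: bool = True,
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """OLS fit of log10 expression level among expressed exons.

    ``y`` are strictly positive rescaled RPKMs (the hurdle split removes
    zeros); t-based standard errors and p-values per coefficient.
    Returns the coefficient table and the residual vector.
    """
    y = np.asarray(y, dtype=float)
    if design.shape[0] != y.size:
        raise ValueError("design and response lengths differ")
    if log_transform:
        if (y <= 0).any():
            raise ValueError("y must be strictly positive for the log scale")
        y = np.log10(y)
    _check_design(design)
    res = sm.OLS(y, design.to_numpy()).fit()
    table = pd.DataFrame({"estimate": np.asarray(res.params),
                          "se": np.asarray(res.bse),
                          "p": np.asarray(res.pvalues)},
                         index=design.columns)
    return table, np.asarray(res.resid)


def _te_observations(sample: SampleExpression, annot: AnnotationSet,
                     ) -> tuple[list[TEExonFeature], np.ndarray, np.ndarray]:
    """Modeled TE-exon features of expressed genes with z and y vectors.

    One observation per (exon, host gene) rescaled pair; z = 1 when the
    exon has at least one read, y the capped rescaled RPKM.
    """
    feats, z, y = [], [], []
    counts = sample.exon_counts
    for (exon_id, gene_id), value in sample.rescaled.items():
        feat = annot.te_features.get(exon_id)
        if feat is None or feat.family in EXCLUDED_FAMILIES:
            continue
        feats.append(feat)
        z.append(1 if counts[exon_id] > 0 else 0)
        y.append(value)
    return feats, np.asarray(z), np.asarray(y, dtype=float)


def two_step_fit(sample: SampleExpression, annot: AnnotationSet,
                 *, tag: str | None = None) -> HurdleFit:
    """Fit Model-1 and Model-2 for one sample.

    TE exons within un-expressed genes are excluded up front.  Model-1
    sees every remaining TE exon; Model-2 the subset with at least one
    read.  A degenerate Model-1 response (e.g. every TE exon expressed)
    is recorded in ``notes`` while Model-2 is still returned.
    """
    feats, z, y = _te_observations(sample, annot)
    design = build_design(feats)
    notes: list[str] = []
    model1 = None
    try:
        model1 = fit_model1(design, z)
    except (ValueError, SeparationError) as exc:
        notes.append(f"model1: {exc}")
    mask = z == 1
    model2 = None
    residuals = None
    try:
        model2, residuals = fit_model2(design.loc[mask], y[mask])
    except ValueError as exc:
        notes.append(f"model2: {exc}")
    return HurdleFit(model1=model1, model2=model2,
                     n1=int(z.size), n2=int(mask.sum()),
                     tag=tag if tag is not None else sample.sample_id,
                     notes=notes, model2_residuals=residuals)


def fit_summary_models(dispersion: pd.DataFrame, annot: AnnotationSet,
                       ) -> tuple[HurdleFit, HurdleFit]:
    """Regress the cross-sample median and CV on the genomic factors.

    ``dispersion`` is the per-exon m/v table (eligibility already
    applied).  Rows with m = 0 are excluded from the log10(m) fit and,
    for comparability, the identical subset is reused for the raw-scale
    v fit.  Returns two single-model HurdleFit results tagged
    ``"median"`` and ``"cv"``.
    """
    feats, m_vals, v_vals = [], [], []
    for idx, row in dispersion.iterrows():
        exon_id = idx[0] if isinstance(idx, tuple) else idx
        feat = annot.te_features.get(exon_id)
        if feat is None or feat.family in EXCLUDED_FAMILIES:
            continue
        if not (row["m"] > 0) or np.isnan(row["v"]):
            continue
        feats.append(feat)
        m_vals.append(row["m"])
        v_vals.append(row["v"])
    design = build_design(feats)
    m_table, m_resid = fit_model2(design, np.asarray(m_vals))
    v_table, v_resid = fit_model2(design, np.asarray(v_vals),
                                  log_transform=False)
    n = len(feats)
    fit_m = HurdleFit(model1=None, model2=m_table, n1=n, n2=n, tag="median",
                      model2_residuals=m_resid)
    fit_v = HurdleFit(model1=None, model2=v_table, n1=n, n2=n, tag="cv",
                      model2_residuals=v_resid)
    return fit_m, fit_v


def discretize_p(coefficient: float, p: float) -> str:
    """Discretize an effect into one of five signed significance bins.

    Categories: ``pos p<0.01``, ``pos p<0.05``, ``ns``, ``neg p<0.05``,
    ``neg p<0.01`` (bin edges 0.01 and 0.05, strict inequality).
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p >= 0.05:
        return "ns"
    sign = "pos" if coefficient > 0 else "neg"
    level = "p<0.01" if p < 0.01 else "p<0.05"
    return f"{sign} {level}"


def coefficient_table(fit: HurdleFit) -> pd.DataFrame:
    """Long-format term/estimate/se/p/category table for one fit."""
    rows = []
    for model_name, table in (("model1", fit.model1), ("model2", fit.model2)):
        if table is None:
            continue
        for term, row in table.iterrows():
            rows.append({"tag": fit.tag, "model": model_name, "term": term,
                         "estimate": row["estimate"], "se": row["se"],
                         "p": row["p"],
                         "category": discretize_p(row["estimate"], row["p"])})
    return pd.DataFrame(rows)


def category_matrix(fits: Sequence[HurdleFit], model: str = "model2",
                    ) -> pd.DataFrame:
    """Term x sample matrix of discretized effect categories."""
    cols = {}
    for fit in fits:
        table = getattr(fit, model)
        if table is None:
            continue
        cols[fit.tag] = {
            term: discretize_p(row["estimate"], row["p"])
            for term, row in table.iterrows()}
    return pd.DataFrame(cols)
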