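"""Synthetic annotation, covariates and hurdle-structured counts.

The generator emulates the study design end to end: a multi-gene
annotation with C1-C4 exon classes (C4 exons intronic, with room for
their C5 decoys), TE covariates (location, family, ELN, RTE) whose
distributions differ between annotated (C3) and un-annotated (C4) TE
exons, 26 group-labelled pseudo-samples with two two-group contrasts,
and read counts drawn from the same two-part process the analysis fits:

* presence ~ Bernoulli(logit^-1(mu + R alpha + F beta + gamma l + phi c));
* if present, rescaled level = 10^(mu* + R alpha* + F beta* + gamma* l
  + phi* c + e), e ~ Normal(0, sd);
* the level is converted to an expected read count through the host
  gene's expression and the library size, and the observed count is
  drawn zero-truncated around it, so the planted presence indicator is
  exactly the observed has-a-read indicator (the count realization
  never contradicts the planted hurdle);
* non-TE exons use class-level retention multipliers; C5 decoys receive
  background reads at a near-zero pre-mRNA rate.

All planted parameters live in :class:`SyntheticTruth` and are
serialized losslessly, so every pipeline stage can be tested against
known ground truth.  Generators are pure functions of (config, truth,
seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (AnnotationSet, ExonRecord, GeneModel,
                         GenomicInterval, TEExonFeature,
                         build_annotation_set, write_alt_table,
                         write_c5_bed, write_gene_table, write_te_exon_table)
from .hurdle import DESIGN_COLUMNS

__all__ = [
    "GroupShift",
    "SyntheticTruth",
    "GeneratorConfig",
    "SyntheticAnnotation",
    "SyntheticDataset",
    "default_truth",
    "make_sample_sheet",
    "generate_annotation",
    "generate_counts",
    "generate_alignments",
    "generate_null_class_values",
    "planted_sample_matrix",
    "save_truth",
    "load_truth",
    "simulate_dataset",
]

TRUTH_FORMAT = "teexon-truth/1"

#: the sample with no contrast membership and no planted group shift,
#: used as the reference for parameter-recovery studies
REFERENCE_SAMPLE = "Brain"


@dataclass(frozen=True)
class GroupShift:
    """A planted between-group expression shift for one contrast.

    ``level_shift`` is added on the log10 scale to the planted level of
    a random ``affected_fraction`` of TE exons in the samples belonging
    to ``group``.
    """

    contrast: str
    group: str
    level_shift: float
    affected_fraction: float


@dataclass
class SyntheticTruth:
    """Planted generator parameters (the recovery targets).

    ``model1``/``model2`` map design terms to the planted presence-
    logit and log10-level coefficients; the CDS and Alu baselines are
    implicitly zero by omission.  ``class_presence``/``class_level``
    hold the retention parameters of the non-TE classes.
    """

    model1: dict[str, float]
    model2: dict[str, float]
    noise_sd: float
    class_presence: dict[str, float]
    class_level: dict[str, float]
    c5_background_rpkm: float
    znf_level_boost: float
    group_shifts: list[GroupShift]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name, d in (("model1", self.model1), ("model2", self.model2)):
            unknown = set(d) - set(DESIGN_COLUMNS)
            if unknown:
                raise ValueError(f"{name}: unknown terms {sorted(unknown)}")


def default_truth(seed: int = 0) -> SyntheticTruth:
    """Default planted parameters.

    The signs echo the qualitative findings the analysis is built to
    detect: UTR5/MIR/L2/MaLR raise both presence and level relative to
    the CDS/Alu baselines, exon length raises apparent presence but
    lowers the expression level, and the TE nucleotide proportion
    depresses both.
    """
    model1 = {"intercept": -0.5, "UTR3": 0.5, "UTR5": 1.0,
              "ERV1": -0.2, "ERVL": 0.1, "L1": 0.0, "L2": 0.8,
              "MaLR": 0.5, "MER1": 0.2, "MER2": 0.2, "MIR": 1.2,
              "log10ELN": 0.5, "RTE": -1.5}
    model2 = {"intercept": 0.0, "UTR3": 0.3, "UTR5": 0.5,
              "ERV1": -0.1, "ERVL": 0.0, "L1": -0.05, "L2": 0.4,
              "MaLR": 0.3, "MER1": 0.1, "MER2": 0.1, "MIR": 0.6,
              "log10ELN": -0.4, "RTE": -1.0}
    return SyntheticTruth(
        model1=model1,
        model2=model2,
        noise_sd=0.4,
        class_presence={"C1": 0.97, "C2": 0.91},
        class_level={"C1": 1.0, "C2": 0.85},
        c5_background_rpkm=0.02,
        znf_level_boost=0.6,
        group_shifts=[
            GroupShift("breast_ER", "ERpos", 0.4, 0.10),
            GroupShift("prostate", "tumor", -0.6, 0.15),
        ],
        seed=seed)


@dataclass
class GeneratorConfig:
    """Study-condition knobs of the synthetic genome and experiment."""

    n_genes: int = 600
    exons_per_gene: tuple[int, int] = (5, 11)
    n_c3: int = 210
    n_c4: int = 1190
    c2_fraction: float = 0.17
    log10_eln: tuple[float, float] = (2.1, 0.25)   # mean, sd of log10 length
    eln_range: tuple[int, int] = (60, 2000)
    family_probs_c3: dict[str, float] = field(default_factory=lambda: {
        "MIR": 0.40, "L2": 0.22, "MaLR": 0.12, "Alu": 0.08, "L1": 0.06,
        "MER1": 0.05, "MER2": 0.03, "ERVL": 0.02, "ERV1": 0.01,
        "CR1": 0.005, "other_DNA": 0.005})
    family_probs_c4: dict[str, float] = field(default_factory=lambda: {
        "Alu": 0.55, "L1": 0.14, "MIR": 0.08, "L2": 0.05, "MaLR": 0.06,
        "MER1": 0.04, "MER2": 0.03, "ERVL": 0.02, "ERV1": 0.015,
        "CR1": 0.005, "other_DNA": 0.01})
    location_probs: dict[str, float] = field(default_factory=lambda: {
        "CDS": 0.667, "UTR5": 0.319, "UTR3": 0.014})
    rte_beta_c3: tuple[float, float] = (2.0, 5.0)
    rte_beta_c4: tuple[float, float] = (4.0, 2.0)
    n_fictional: int = 500
    fictional_exon_range: tuple[int, int] = (4, 40)
    n_samples: int = 26
    library_size: int = 80_000_000
    library_log10_sd: float = 0.08
    gene_log10_rpkm: tuple[float, float] = (1.3, 0.4)
    gene_sample_log10_sd: float = 0.15
    znf_gene_fraction: float = 0.08
    nb_dispersion: float | None = None    # Poisson when None
    seed: int = 0

    def __post_init__(self) -> None:
        for probs in (self.family_probs_c3, self.family_probs_c4,
                      self.location_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("probabilities must sum to 1")
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SyntheticAnnotation:
    """Raw synthetic annotation tables (the parsers' input dialects)."""

    genes: list[GeneModel]
    te_exons: list[ExonRecord]
    te_features: list[TEExonFeature]
    alt_intervals: list[GenomicInterval]
    znf_genes: set[str]


@dataclass
class SyntheticDataset:
    """A complete simulated experiment with recorded ground truth."""

    annotation: AnnotationSet
    znf_genes: set[str]
    truth: SyntheticTruth
    counts: pd.DataFrame          # exon x sample integer counts
    samples: pd.DataFrame         # sample sheet with group labels
    library_sizes: pd.Series
    affected_exons: dict[str, set[str]]


def make_sample_sheet(n_samples: int = 26) -> pd.DataFrame:
    """Sample sheet with two two-group contrasts.

    Mirrors the 26-sample study design: breast cancer lines split by
    estrogen-receptor status (contrast ``breast_ER``), prostate tissue
    split into tumor and normal (contrast ``prostate``), plus untested
    cell-line/tissue samples.  For other sample counts the composition
    is scaled while both contrasts keep at least three samples per arm.
    """
    rows = []

    def add(sample_id, tissue, breast=None, prostate=None):
        rows.append({"sample_id": sample_id, "tissue": tissue,
                     "breast_ER": breast, "prostate": prostate})

    for i in range(1, 4):
        add(f"BRneg{i}", "breast", breast="ERneg")
    for i in range(1, 5):
        add(f"BRpos{i}", "breast", breast="ERpos")
    add("BRnorm", "breast")
    add("PRC_t", "prostate_line")
    add("PRC_n", "prostate_line")
    add("LCL1", "lymphocyte")
    add("LCL2", "lymphocyte")
    for i in range(1, 7):
        add(f"OV{i}", "ovary")
    for i in range(1, 4):
        add(f"PRT_t{i}", "prostate", prostate="tumor")
    for i in range(1, 4):
        add(f"PRT_n{i}", "prostate", prostate="normal")
    add("Brain", "brain")
    add("Liver", "liver")

    df = pd.DataFrame(rows).set_index("sample_id")
    if n_samples == len(df):
        return df
    if n_samples < 12:
        raise ValueError("need at least 12 samples to keep both contrasts")
    # keep the contrast samples; trim or replicate the untested ones
    contrast = df[df["breast_ER"].notna() | df["prostate"].notna()]
    free = df[df["breast_ER"].isna() & df["prostate"].isna()]
    need = n_samples - len(contrast)
    reps = [free.iloc[i % len(free)] for i in range(need)]
    free2 = pd.DataFrame(reps)
    free2.index = [f"{r.name}_{i}" if i >= len(free) else r.name
                   for i, r in enumerate(reps)]
    return pd.concat([contrast, free2])


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

def _draw_lengths(rng, n, cfg: GeneratorConfig) -> np.ndarray:
    raw = 10 ** rng.normal(cfg.log10_eln[0], cfg.log10_eln[1], size=n)
    return np.clip(np.round(raw), cfg.eln_range[0], cfg.eln_range[1]
                   ).astype(int)


def _draw_categorical(rng, probs: dict[str, float], n: int) -> np.ndarray:
    keys = list(probs)
    return rng.choice(keys, size=n, p=[probs[k] for k in keys])


def generate_annotation(config: GeneratorConfig) -> SyntheticAnnotation:
    """Generate a synthetic genome annotation with planted exon classes.

    Genes are packed without overlap on one toy chromosome; each C4 exon
    sits in an intron of its host gene with the interval immediately
    downstream (strand-relative) left free, so its C5 decoy never
    collides with any exon.  Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chrT1"

    # two-pass: first decide per-gene annotated exon counts, then place
    # the exact global numbers of C3 slots and C4 introns
    n_ann = rng.integers(config.exons_per_gene[0],
                         config.exons_per_gene[1] + 1, size=config.n_genes)
    total_ann = int(n_ann.sum())
    if config.n_c3 > total_ann:
        raise ValueError("more C3 exons requested than annotated exon slots")
    intron_slots = [(g, j) for g in range(config.n_genes)
                    for j in range(int(n_ann[g]) - 1)]
    if config.n_c4 > len(intron_slots):
        raise ValueError("more C4 exons requested than intron slots; "
                         "increase n_genes or exons per gene")
    c3_slots = set(map(int, rng.choice(total_ann, size=config.n_c3,
                                       replace=False)))
    c4_slot_idx = rng.choice(len(intron_slots), size=config.n_c4,
                             replace=False)
    c4_by_gene: dict[int, set[int]] = {}
    for k in sorted(map(int, c4_slot_idx)):
        g, j = intron_slots[k]
        c4_by_gene.setdefault(g, set()).add(j)

    genes: list[GeneModel] = []
    te_exons: list[ExonRecord] = []
    te_class: list[str] = []
    alt_intervals: list[GenomicInterval] = []

    cursor = 1000
    slot = 0                       # global annotated-exon slot counter
    for g in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(n_ann[g])
        lengths = _draw_lengths(rng, k, config)
        gid = f"G{g:04d}"
        exon_ivs: list[GenomicInterval] = []
        for j in range(k):
            s = cursor
            e = s + int(lengths[j])
            iv = GenomicInterval(chrom, s, e, strand)
            exon_ivs.append(iv)
            cls = "C3" if slot in c3_slots else (
                "C2" if rng.random() < config.c2_fraction else "C1")
            if cls == "C3":
                te_exons.append(ExonRecord(exon_id=f"{chrom}:{s}-{e}",
                                           interval=iv, gene_ids={gid}))
                te_class.append("C3")
            elif cls == "C2":
                alt_intervals.append(GenomicInterval(chrom, s, e))
            slot += 1
            cursor = e
            if j < k - 1:
                if j in c4_by_gene.get(g, ()):
                    # intron hosting a C4 exon plus its C5 decoy room
                    c4_len = int(_draw_lengths(rng, 1, config)[0])
                    cursor += int(rng.integers(300, 801))
                    if strand == "-":
                        cursor += c4_len          # decoy room upstream-left
                    c4_s = cursor
                    c4_e = c4_s + c4_len
                    te_exons.append(ExonRecord(
                        exon_id=f"{chrom}:{c4_s}-{c4_e}",
                        interval=GenomicInterval(chrom, c4_s, c4_e, strand),
                        gene_ids={gid}))
                    te_class.append("C4")
                    cursor = c4_e
                    if strand == "+":
                        cursor += c4_len          # decoy room downstream
                    cursor += int(rng.integers(300, 801))
                else:
                    cursor += int(rng.integers(300, 1201))
        genes.append(GeneModel(
            gene_id=gid,
            interval=GenomicInterval(chrom, exon_ivs[0].start,
                                     exon_ivs[-1].end, strand),
            exons=[ExonRecord(exon_id=f"{chrom}:{iv.start}-{iv.end}",
                              interval=iv, gene_ids={gid})
                   for iv in exon_ivs]))
        cursor += int(rng.integers(2000, 4001))

    # TE covariates; RTE rounded to whole TE-derived nucleotides so the
    # tables round-trip exactly
    te_features: list[TEExonFeature] = []
    for rec, cls in zip(te_exons, te_class):
        eln = rec.length
        fam_probs = (config.family_probs_c3 if cls == "C3"
                     else config.family_probs_c4)
        a, b = config.rte_beta_c3 if cls == "C3" else config.rte_beta_c4
        rte = float(rng.beta(a, b))
        te_nt = int(round(rte * eln))
        te_nt = min(max(te_nt, 0), eln)
        te_features.append(TEExonFeature(
            exon_id=rec.exon_id,
            location=str(_draw_categorical(rng, config.location_probs, 1)[0]),
            family=str(_draw_categorical(rng, fam_probs, 1)[0]),
            eln=eln,
            rte=te_nt / eln,
            annotated=cls == "C3"))

    gene_ids = [g.gene_id for g in genes]
    n_znf = int(round(config.znf_gene_fraction * len(gene_ids)))
    znf = set(rng.choice(gene_ids, size=n_znf, replace=False))
    return SyntheticAnnotation(genes=genes, te_exons=te_exons,
                               te_features=te_features,
                               alt_intervals=alt_intervals, znf_genes=znf)


# ---------------------------------------------------------------------------
# Count generation
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _linear_predictor(feat: TEExonFeature, coefs: Mapping[str, float]
                      ) -> float:
    """Planted linear predictor; excluded families carry no family term."""
    lp = coefs.get("intercept", 0.0)
    lp += coefs.get(feat.location, 0.0) if feat.location != "CDS" else 0.0
    if feat.family != "Alu":
        lp += coefs.get(feat.family, 0.0)
    lp += coefs.get("log10ELN", 0.0) * np.log10(feat.eln)
    lp += coefs.get("RTE", 0.0) * feat.rte
    return float(lp)


def _zero_truncated_poisson(rng, lam: np.ndarray,
                            nb_dispersion: float | None) -> np.ndarray:
    """Exact zero-truncated counts via inverse-CDF sampling."""
    lam = np.maximum(np.asarray(lam, dtype=float), 1e-8)
    if nb_dispersion:
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, lam / shape)     # gamma-Poisson mixture
        lam = np.maximum(lam, 1e-8)
    p0 = np.exp(-lam)
    u = rng.uniform(p0, 1.0)
    return stats.poisson.ppf(u, lam).astype(int)


def generate_counts(annot: AnnotationSet, truth: SyntheticTruth,
                    config: GeneratorConfig, seed: int,
                    znf_genes: set[str] | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series,
                               dict[str, set[str]]]:
    """Draw the exon x sample count matrix from the planted model.

    Returns (counts, sample sheet, library sizes, affected exon ids per
    contrast).  See the module docstring for the generative process.
    """
    rng = np.random.default_rng(seed)
    znf_genes = znf_genes or set()
    sheet = make_sample_sheet(config.n_samples)
    tables = annot.tables()
    exon_df = tables["exons"]
    exon_ids = exon_df.index.to_numpy()
    cls = exon_df["exon_class"].to_numpy()
    len_kb = (exon_df["length"] / 1e3).to_numpy()

    real_genes = sorted(annot.real_gene_ids)
    gene_pos = {g: i for i, g in enumerate(real_genes)}
    theta = 10 ** rng.normal(config.gene_log10_rpkm[0],
                             config.gene_log10_rpkm[1], size=len(real_genes))

    # host gene per exon (C5 -> paired C4's host); fictional hosts ignored
    host = np.full(len(exon_ids), -1, dtype=int)
    for i, exon_id in enumerate(exon_ids):
        rec = annot.exons[exon_id]
        if rec.exon_class == "C5":
            rec = annot.exons[annot.paired_c4(exon_id)]
        for g in rec.gene_ids:
            if g in gene_pos:
                host[i] = gene_pos[g]
                break

    # planted linear predictors for TE exons
    lp1 = np.full(len(exon_ids), np.nan)
    lp2 = np.full(len(exon_ids), np.nan)
    znf_exon = np.zeros(len(exon_ids), dtype=bool)
    for i, exon_id in enumerate(exon_ids):
        feat = annot.te_features.get(exon_id)
        if feat is None:
            continue
        lp1[i] = _linear_predictor(feat, truth.model1)
        lp2[i] = _linear_predictor(feat, truth.model2)
        znf_exon[i] = bool(annot.exons[exon_id].gene_ids & znf_genes)
    lp2 = np.where(znf_exon, lp2 + truth.znf_level_boost, lp2)
    is_te = ~np.isnan(lp1)

    # expected retention per exon -> expected gene expression denominator
    log10_sq = (truth.noise_sd * np.log(10)) ** 2
    expected_ret = np.zeros(len(exon_ids))
    for name in ("C1", "C2"):
        m = cls == name
        expected_ret[m] = (truth.class_presence[name]
                           * truth.class_level[name])
    expected_ret[is_te] = (_sigmoid(lp1[is_te])
                           * 10 ** lp2[is_te] * np.exp(log10_sq / 2))
    members = tables["annotated_members"]
    pos = {e: i for i, e in enumerate(exon_ids)}
    member_rows = np.array([pos[e] for e in members["exon_id"]])
    member_gene = np.array([gene_pos[g] for g in members["gene_id"]])
    denom = np.zeros(len(real_genes))
    n_members = np.zeros(len(real_genes))
    np.add.at(denom, member_gene, expected_ret[member_rows])
    np.add.at(n_members, member_gene, 1.0)
    denom = denom / np.maximum(n_members, 1.0)

    # planted group shifts
    te_ids = exon_ids[is_te]
    affected: dict[str, set[str]] = {}
    shift_cols: list[tuple[GroupShift, np.ndarray]] = []
    for gs in truth.group_shifts:
        n_aff = int(round(gs.affected_fraction * te_ids.size))
        chosen = set(rng.choice(te_ids, size=n_aff, replace=False))
        affected[f"{gs.contrast}:{gs.group}"] = chosen
        mask = np.array([e in chosen for e in exon_ids])
        shift_cols.append((gs, mask))

    lib = np.round(config.library_size
                   * 10 ** rng.normal(0.0, config.library_log10_sd,
                                      size=len(sheet))).astype(np.int64)
    library_sizes = pd.Series(lib, index=sheet.index, name="library_size")

    counts = np.zeros((len(exon_ids), len(sheet)), dtype=np.int64)
    c5_mask = cls == "C5"
    for s, sample_id in enumerate(sheet.index):
        lib_m = lib[s] / 1e6
        theta_s = theta * 10 ** rng.normal(0.0, config.gene_sample_log10_sd,
                                           size=theta.size)
        gene_rpkm = theta_s * denom

        shift = np.zeros(len(exon_ids))
        for gs, mask in shift_cols:
            if sheet.loc[sample_id, gs.contrast] == gs.group:
                shift[mask] += gs.level_shift

        col = np.zeros(len(exon_ids), dtype=np.int64)

        # non-TE annotated exons: class-level retention
        for name in ("C1", "C2"):
            m = cls == name
            z = rng.random(m.sum()) < truth.class_presence[name]
            lam = (truth.class_level[name] * theta_s[host[m]]
                   * len_kb[m] * lib_m)
            _guard_lambda(lam)
            vals = np.zeros(m.sum(), dtype=np.int64)
            vals[z] = _zero_truncated_poisson(rng, lam[z],
                                              config.nb_dispersion)
            col[m] = vals

        # TE exons: planted hurdle
        z = rng.random(is_te.sum()) < _sigmoid(lp1[is_te])
        level = 10 ** (lp2[is_te] + shift[is_te]
                       + rng.normal(0.0, truth.noise_sd, size=is_te.sum()))
        lam = level * gene_rpkm[host[is_te]] * len_kb[is_te] * lib_m
        _guard_lambda(lam)
        vals = np.zeros(is_te.sum(), dtype=np.int64)
        vals[z] = _zero_truncated_poisson(rng, lam[z], config.nb_dispersion)
        col[is_te] = vals

        # C5 decoys: plain Poisson background
        lam = truth.c5_background_rpkm * len_kb[c5_mask] * lib_m
        col[c5_mask] = rng.poisson(lam)

        counts[:, s] = col

    counts_df = pd.DataFrame(counts, index=exon_df.index,
                             columns=sheet.index)
    return counts_df, sheet, library_sizes, affected


def _guard_lambda(lam: np.ndarray) -> None:
    if lam.size and np.max(lam) > 1e7:
        raise ValueError(
            "expected read count exceeds 1e7 for some exon; use a smaller "
            "library size or lower expression parameters")


# ---------------------------------------------------------------------------
# SAM fixture generation
# ---------------------------------------------------------------------------

def generate_alignments(annot: AnnotationSet,
                        counts: Mapping[str, int],
                        read_length: int = 50,
                        seed: int = 0,
                        decoy_fraction: float = 0.1) -> str:
    """Emit SAM text whose filtered per-exon counts equal ``counts``.

    Clean reads are primary single-hit records placed entirely inside
    their target exon (so each read overlaps exactly that exon); a
    ``decoy_fraction`` of extra non-primary and multi-hit records is
    interleaved and must be removed by the ambiguity filter.  Fixture
    scale: at most 10,000 clean reads.
    """
    total = int(sum(counts.values()))
    if total > 10_000:
        raise ValueError("fixture scale exceeded: at most 10,000 reads")
    rng = np.random.default_rng(seed)
    chrom_len: dict[str, int] = {}
    for rec in annot.exons.values():
        iv = rec.interval
        chrom_len[iv.chrom] = max(chrom_len.get(iv.chrom, 0), iv.end + 1000)

    out = io.StringIO()
    out.write("@HD\tVN:1.6\tSO:unknown\n")
    for chrom in sorted(chrom_len):
        out.write(f"@SQ\tSN:{chrom}\tLN:{chrom_len[chrom]}\n")

    def emit(name, flag, chrom, start0, nh):
        out.write(f"{name}\t{flag}\t{chrom}\t{start0 + 1}\t255\t"
                  f"{read_length}M\t*\t0\t0\t{'A' * read_length}\t*\t"
                  f"NH:i:{nh}\n")

    i = 0
    exon_list = [annot.exons[e] for e in sorted(counts)]
    for rec in exon_list:
        k = int(counts[rec.exon_id])
        iv = rec.interval
        if read_length > len(iv):
            warnings.warn(
                f"read length {read_length} exceeds exon {rec.exon_id} "
                f"length {len(iv)}; reads will spill into flanking sequence")
            starts = np.full(k, iv.start)
        else:
            starts = rng.integers(iv.start, iv.end - read_length + 1, size=k)
        for s in starts:
            emit(f"r{i:06d}", 0, iv.chrom, int(s), 1)
            i += 1

    n_decoys = int(round(decoy_fraction * total))
    all_exons = list(annot.exons.values())
    for j in range(n_decoys):
        rec = all_exons[int(rng.integers(len(all_exons)))]
        iv = rec.interval
        s = int(rng.integers(iv.start, max(iv.start + 1,
                                           iv.end - read_length + 1)))
        if j % 2 == 0:
            emit(f"d{j:06d}", 256, iv.chrom, s, 2)   # secondary alignment
        else:
            emit(f"d{j:06d}", 0, iv.chrom, s, 3)     # multi-hit primary
    return out.getvalue()


# ---------------------------------------------------------------------------
# Null and planted helpers for calibration / clustering properties
# ---------------------------------------------------------------------------

def generate_null_class_values(n_per_class: int = 100,
                               presence: float = 0.8,
                               log10_level_mean: float = -0.5,
                               noise_sd: float = 0.4,
                               seed: int = 0) -> dict[str, pd.DataFrame]:
    """Class-labelled values with NO class differences (null generator).

    Each class's values follow the same hurdle distribution:
    Bernoulli(presence) x 10^Normal(mean, sd).  C4 and C5 are iid and
    index-paired.  The output plugs directly into the stepwise tests.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for cls in ("C1", "C2", "C3", "C4", "C5"):
        z = rng.random(n_per_class) < presence
        values = np.where(
            z, 10 ** rng.normal(log10_level_mean, noise_sd, n_per_class),
            0.0)
        idx = pd.MultiIndex.from_arrays(
            [[f"{cls}_{i}" for i in range(n_per_class)],
             ["g"] * n_per_class], names=["exon_id", "gene_id"])
        out[cls] = pd.DataFrame({"value": values, "expressed": z}, index=idx)
    return out


def planted_sample_matrix(n_a: int = 5, n_b: int = 5,
                          n_features: int = 200,
                          shift: float = 2.0, noise_sd: float = 0.4,
                          seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Two planted sample groups separated by a mean shift on every
    feature, with iid Gaussian noise.  Returns (samples x features,
    true labels)."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.0, 1.0, size=n_features)
    rows, labels = [], []
    for i in range(n_a + n_b):
        group = 1 if i < n_a else 2
        rows.append(base + (shift if group == 2 else 0.0)
                    + rng.normal(0.0, noise_sd, size=n_features))
        labels.append(group)
    index = [f"S{i:02d}" for i in range(n_a + n_b)]
    return (pd.DataFrame(rows, index=index),
            pd.Series(labels, index=index, name="group"))


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------

def _truth_payload(truth: SyntheticTruth) -> dict:
    d = dataclasses.asdict(truth)
    d["group_shifts"] = [dataclasses.asdict(g) for g in truth.group_shifts]
    return d


def save_truth(truth: SyntheticTruth, path) -> None:
    payload = _truth_payload(truth)
    blob = json.dumps(payload, sort_keys=True).encode()
    doc = {"format": TRUTH_FORMAT, "payload": payload,
           "sha256": hashlib.sha256(blob).hexdigest()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != TRUTH_FORMAT:
        raise ValueError(f"unsupported truth format {doc.get('format')!r}")
    blob = json.dumps(doc["payload"], sort_keys=True).encode()
    if hashlib.sha256(blob).hexdigest() != doc.get("sha256"):
        raise ValueError("truth file checksum mismatch (tampered file?)")
    payload = dict(doc["payload"])
    payload["group_shifts"] = [GroupShift(**g)
                               for g in payload["group_shifts"]]
    return SyntheticTruth(**payload)


# ---------------------------------------------------------------------------
# One-call dataset simulation
# ---------------------------------------------------------------------------

def simulate_dataset(config: GeneratorConfig | None = None,
                     truth: SyntheticTruth | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate a complete, self-consistent dataset.

    ``seed`` overrides ``config.seed`` for both the annotation and the
    counts (count randomness uses an offset stream so annotation and
    counts are independently reproducible).
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    truth = truth or default_truth(config.seed)
    syn = generate_annotation(config)
    annot = build_annotation_set(
        syn.genes, syn.te_exons, syn.te_features, syn.alt_intervals,
        n_fictional=config.n_fictional,
        fictional_exon_range=config.fictional_exon_range,
        seed=config.seed)
    counts, sheet, lib, affected = generate_counts(
        annot, truth, config, seed=config.seed + 100_003,
        znf_genes=syn.znf_genes)
    return SyntheticDataset(annotation=annot, znf_genes=syn.znf_genes,
                            truth=truth, counts=counts, samples=sheet,
                            library_sizes=lib, affected_exons=affected)


def write_dataset(ds: SyntheticDataset, directory) -> None:
    """Write the dataset as the plain-text dialects the parsers consume."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    real = [g for g in ds.annotation.genes.values() if not g.fictional]
    write_gene_table(real, directory / "genes.tsv")
    te_ids = sorted(ds.annotation.te_features)
    te_exons = [ds.annotation.exons[e] for e in te_ids]
    feats = [ds.annotation.te_features[e] for e in te_ids]
    write_te_exon_table(te_exons, feats, directory / "te_exons.tsv")
    alt = [ds.annotation.exons[e].interval
           for e in ds.annotation.exons
           if ds.annotation.exons[e].exon_class == "C2"]
    write_alt_table(alt, directory / "alt_exons.bed")
    write_c5_bed(ds.annotation, directory / "c5_exons.bed")
    ds.counts.to_csv(directory / "counts.tsv", sep="\t")
    ds.samples.to_csv(directory / "samples.tsv", sep="\t")
    ds.library_sizes.to_csv(directory / "library_sizes.tsv", sep="\t")
    with open(directory / "znf_genes.txt", "w") as fh:
        for g in sorted(ds.znf_genes):
            fh.write(g + "\n")
    save_truth(ds.truth, directory / "truth.json")
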