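"""Gene models, exonized-TE features and the C1-C5 exon classification.

The analysis distinguishes five exon classes:

* **C1** -- constitutive exons: annotated gene exons absent from both the
  exonized-TE table and the known alternative-exon table.
* **C2** -- cassette exons: annotated gene exons present in the known
  alternative-exon table but not TE-derived.
* **C3** -- annotated TE exons: entries of the exonized-TE table whose
  coordinates exactly match an annotated gene exon.
* **C4** -- un-annotated TE exons: exonized-TE entries with no exact
  coordinate counterpart among annotated gene exons (they sit in introns
  of their host genes).
* **C5** -- simulated decoy exons: the intronic interval immediately
  downstream of each C4 exon, with equal length.  C5 exons are assembled
  into *fictional genes* whose expression distribution later calibrates
  the per-sample expressed-gene cutoff.

All internal coordinates are 0-based half-open (BED convention); parsers
for 1-based fully-closed dialects convert on ingestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LOCATIONS",
    "FAMILIES",
    "MODELED_FAMILIES",
    "EXCLUDED_FAMILIES",
    "GenomicInterval",
    "GeneModel",
    "ExonRecord",
    "TEExonFeature",
    "AnnotationSet",
    "ParseError",
    "parse_gene_table",
    "parse_alt_table",
    "parse_te_exon_table",
    "compute_rte",
    "classify_exons",
    "build_simulated_exons",
    "build_fictional_genes",
    "build_annotation_set",
    "write_gene_table",
    "write_alt_table",
    "write_te_exon_table",
    "write_c5_bed",
]

#: TE-exon location categories within the host gene.
LOCATIONS = ("CDS", "UTR3", "UTR5")

#: All recognized TE families.
FAMILIES = ("Alu", "ERV1", "ERVL", "L1", "L2", "MaLR", "MER1", "MER2",
            "MIR", "CR1", "other_DNA")

#: Families entering the regression design (Alu is the baseline).
MODELED_FAMILIES = ("Alu", "ERV1", "ERVL", "L1", "L2", "MaLR", "MER1",
                    "MER2", "MIR")

#: Rare families excluded from the regression analysis.
EXCLUDED_FAMILIES = ("CR1", "other_DNA")

_LOCATION_ALIASES = {
    "CDS": "CDS",
    "UTR3": "UTR3", "3UTR": "UTR3", "3'UTR": "UTR3",
    "UTR5": "UTR5", "5UTR": "UTR5", "5'UTR": "UTR5",
}

#: Suffix appended to a C4 exon id to form its paired C5 (decoy) exon id.
C5_SUFFIX = ".sim"


class ParseError(ValueError):
    """Raised for malformed annotation tables; names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        """Coordinate identity (strand is not part of exon identity)."""
        return (self.chrom, self.start, self.end)


@dataclass
class ExonRecord:
    """An exon with its host gene membership and C1-C5 class."""

    exon_id: str
    interval: GenomicInterval
    gene_ids: set[str] = field(default_factory=set)
    exon_class: str | None = None

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class GeneModel:
    """A gene with its ordered exon list.

    Fictional genes are decoys assembled from C5 exons; their exons may
    lie anywhere in the genome and need not fall inside ``interval``.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[ExonRecord]
    fictional: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons.sort(key=lambda e: (e.interval.start, e.interval.end))
        if not self.fictional:
            prev_end = -1
            for e in self.exons:
                iv = e.interval
                if iv.chrom != self.interval.chrom:
                    raise ValueError(
                        f"gene {self.gene_id}: exon on {iv.chrom}, "
                        f"gene on {self.interval.chrom}")
                if iv.start < self.interval.start or iv.end > self.interval.end:
                    raise ValueError(
                        f"gene {self.gene_id}: exon [{iv.start},{iv.end}) "
                        f"outside transcript span")
                if iv.start < prev_end:
                    raise ValueError(
                        f"gene {self.gene_id}: overlapping exons")
                prev_end = iv.end

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class TEExonFeature:
    """Genomic covariates of one exonized-TE exon.

    ``eln`` is the exon length in bp; ``rte`` the proportion of its
    nucleotides derived from the cognate TE; ``annotated`` records
    whether the exon has an exact-coordinate counterpart among annotated
    gene exons (i.e. whether it is C3 rather than C4).
    """

    exon_id: str
    location: str
    family: str
    eln: int
    rte: float
    annotated: bool = False
    est_inclusion: float | None = None

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(
                f"unknown location {self.location!r}; allowed: {LOCATIONS}")
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown TE family {self.family!r}; allowed: {FAMILIES}")
        if self.eln < 1:
            raise ValueError(f"eln must be >= 1, got {self.eln}")
        if not 0.0 <= self.rte <= 1.0:
            raise ValueError(f"rte must lie in [0, 1], got {self.rte}")


# ---------------------------------------------------------------------------
# Parsers.  Tables are TSV; pandas handles gzip transparently.
# ---------------------------------------------------------------------------

def _maybe_shift(start: int, one_based_closed: bool) -> int:
    return start - 1 if one_based_closed else start


def parse_gene_table(path, *, one_based_closed: bool = False) -> list[GeneModel]:
    """Parse a refGene-like TSV into gene models.

    Expected columns: ``gene_id chrom strand txStart txEnd exonStarts
    exonEnds`` with the exon columns holding comma-separated lists.
    ``one_based_closed=True`` converts 1-based fully-closed input to the
    internal 0-based half-open convention.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "chrom", "strand", "txStart", "txEnd",
                "exonStarts", "exonEnds"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gid = row.gene_id
        if gid in seen:
            raise ParseError(f"{path} line {i}: duplicate gene_id {gid!r}")
        seen.add(gid)
        tx_start = _maybe_shift(int(row.txStart), one_based_closed)
        tx_end = int(row.txEnd)
        if tx_start >= tx_end:
            raise ParseError(
                f"{path} line {i}: txStart >= txEnd for gene {gid!r}")
        starts = [int(s) for s in str(row.exonStarts).split(",") if s != ""]
        ends = [int(s) for s in str(row.exonEnds).split(",") if s != ""]
        if len(starts) != len(ends):
            raise ParseError(
                f"{path} line {i}: exonStarts/exonEnds length mismatch "
                f"({len(starts)} vs {len(ends)}) for gene {gid!r}")
        exons = []
        for s, e in sorted(zip(starts, ends)):
            s = _maybe_shift(s, one_based_closed)
            iv = GenomicInterval(row.chrom, s, e, row.strand)
            exons.append(ExonRecord(exon_id=f"{row.chrom}:{s}-{e}",
                                    interval=iv, gene_ids={gid}))
        genes.append(GeneModel(
            gene_id=gid,
            interval=GenomicInterval(row.chrom, tx_start, tx_end, row.strand),
            exons=exons))
    return genes


def parse_alt_table(path, *, one_based_closed: bool = False) -> list[GenomicInterval]:
    """Parse a BED3 file of known alternative (cassette) exon intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2],
                     dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        s = _maybe_shift(int(row.start), one_based_closed)
        out.append(GenomicInterval(str(row.chrom), s, int(row.end)))
    return out


def compute_rte(te_nucleotides: int, exon_length: int) -> float:
    """TE nucleotide proportion: TE-derived bases / exon length."""
    if exon_length < 1:
        raise ValueError("exon_length must be >= 1")
    if not 0 <= te_nucleotides <= exon_length:
        raise ValueError(
            f"te_nucleotides must lie in [0, exon_length]; got "
            f"{te_nucleotides} for a {exon_length} bp exon")
    return te_nucleotides / exon_length


def parse_te_exon_table(path, *, one_based_closed: bool = False,
                        ) -> tuple[list[ExonRecord], list[TEExonFeature]]:
    """Parse an exonized-TE TSV into index-paired exon records and features.

    Expected columns: ``exon_id chrom start end strand gene_id location
    family`` plus either ``te_nucleotides`` (raw TE-derived base count,
    from which RTE is computed) or a precomputed ``rte`` column, and an
    optional ``est_inclusion`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["exon_id", "chrom", "start", "end", "strand", "gene_id",
                "location", "family"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if "te_nucleotides" not in df.columns and "rte" not in df.columns:
        raise ParseError(f"{path}: need a te_nucleotides or rte column")
    exons: list[ExonRecord] = []
    feats: list[TEExonFeature] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        s = _maybe_shift(int(row.start), one_based_closed)
        iv = GenomicInterval(str(row.chrom), s, int(row.end), str(row.strand))
        length = len(iv)
        try:
            if "te_nucleotides" in df.columns and not pd.isna(row.te_nucleotides):
                rte = compute_rte(int(row.te_nucleotides), length)
            else:
                rte = float(row.rte)
            loc_raw = str(row.location)
            if loc_raw not in _LOCATION_ALIASES:
                raise ValueError(
                    f"unknown location {loc_raw!r}; allowed: {LOCATIONS}")
            est = None
            if "est_inclusion" in df.columns and not pd.isna(row.est_inclusion):
                est = float(row.est_inclusion)
            feat = TEExonFeature(
                exon_id=str(row.exon_id),
                location=_LOCATION_ALIASES[loc_raw],
                family=str(row.family),
                eln=length,
                rte=rte,
                est_inclusion=est)
        except ValueError as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
        exons.append(ExonRecord(exon_id=str(row.exon_id), interval=iv,
                                gene_ids={str(row.gene_id)}))
        feats.append(feat)
    return exons, feats


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_exons(genes: list[GeneModel],
                   te_exons: list[ExonRecord],
                   te_features: list[TEExonFeature],
                   alt_table: list[GenomicInterval],
                   ) -> tuple[dict[str, ExonRecord], dict[str, TEExonFeature]]:
    """Assign every exon a class in {C1, C2, C3, C4}.

    Annotated gene exons become C3 if the exonized-TE table holds an
    exact-coordinate match, C2 if the alternative-exon table does, and C1
    otherwise.  TE-table entries without an exact gene-exon counterpart
    become C4 records (hosted by the gene named in the TE table).

    Classification is total: every distinct real exon receives exactly
    one class.  Exact matching compares (chrom, start, end); strand is
    not part of exon identity.  Returns ``(exons, features)`` keyed by
    the final exon id (C3 features are re-keyed to the gene-table exon
    id they matched).
    """
    te_by_key: dict[tuple, tuple[ExonRecord, TEExonFeature]] = {}
    for rec, feat in zip(te_exons, te_features):
        te_by_key[rec.interval.key] = (rec, feat)
    alt_keys = {iv.key for iv in alt_table}

    exons: dict[str, ExonRecord] = {}
    features: dict[str, TEExonFeature] = {}
    by_key: dict[tuple, ExonRecord] = {}
    matched_te_keys: set[tuple] = set()

    for gene in genes:
        for ex in gene.exons:
            key = ex.interval.key
            if key in by_key:                      # exon shared between genes
                by_key[key].gene_ids |= ex.gene_ids
                continue
            rec = ExonRecord(exon_id=ex.exon_id, interval=ex.interval,
                             gene_ids=set(ex.gene_ids))
            if key in te_by_key:
                rec.exon_class = "C3"
                matched_te_keys.add(key)
                _, feat = te_by_key[key]
                features[rec.exon_id] = replace(feat, exon_id=rec.exon_id,
                                                annotated=True)
            elif key in alt_keys:
                rec.exon_class = "C2"
            else:
                rec.exon_class = "C1"
            by_key[key] = rec
            exons[rec.exon_id] = rec

    for rec, feat in zip(te_exons, te_features):
        key = rec.interval.key
        if key in matched_te_keys:
            continue
        c4 = ExonRecord(exon_id=rec.exon_id, interval=rec.interval,
                        gene_ids=set(rec.gene_ids), exon_class="C4")
        exons[c4.exon_id] = c4
        features[c4.exon_id] = replace(feat, annotated=False)
    return exons, features


def build_simulated_exons(c4_exons: list[ExonRecord],
                          genes: dict[str, GeneModel] | list[GeneModel],
                          *, strand_aware: bool = True) -> list[ExonRecord]:
    """Construct the C5 decoy exon for each C4 exon.

    The decoy is the intronic interval immediately downstream of the C4
    exon with equal length; "downstream" follows the host gene's strand
    (3' direction) unless ``strand_aware=False``, in which case the
    interval to the right is always used.  The returned list is
    index-paired with ``c4_exons`` (required by the paired C4-vs-C5
    signed-rank test); decoy ids are the C4 id plus ``".sim"``.
    Intervals that would start below zero are clipped to zero with a
    warning.
    """
    gene_map = ({g.gene_id: g for g in genes} if isinstance(genes, list)
                else genes)
    out: list[ExonRecord] = []
    for c4 in c4_exons:
        host = next(iter(c4.gene_ids))
        strand = gene_map[host].strand if strand_aware else "+"
        s, e = c4.interval.start, c4.interval.end
        length = e - s
        if strand == "+":
            ns, ne = e, e + length
        else:
            ns, ne = s - length, s
        if ns < 0:
            warnings.warn(
                f"C5 decoy of {c4.exon_id} clipped at chromosome start; "
                f"length reduced from {length} to {max(ne, 0)}")
            ns = 0
            if ne <= 0:
                continue
        iv = GenomicInterval(c4.interval.chrom, ns, ne, strand)
        out.append(ExonRecord(exon_id=c4.exon_id + C5_SUFFIX, interval=iv,
                              gene_ids=set(), exon_class="C5"))
    return out


def build_fictional_genes(c5_exons: list[ExonRecord], n_genes: int = 500,
                          min_exons: int = 4, max_exons: int = 40,
                          seed: int = 0) -> list[GeneModel]:
    """Assemble decoy (fictional) genes from C5 exons.

    Each fictional gene receives ``k`` distinct C5 exons with ``k``
    drawn uniformly from ``[min_exons, max_exons]``; a C5 exon may serve
    several fictional genes but appears at most once per gene.  The
    fictional-gene expression distribution later sets the sample-specific
    expressed-gene cutoff.  Deterministic for a fixed seed.
    """
    if len(c5_exons) < min_exons:
        raise ValueError(
            f"need at least {min_exons} C5 exons, got {len(c5_exons)}")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    hi = min(max_exons, len(c5_exons))
    for i in range(n_genes):
        k = int(rng.integers(min_exons, hi + 1))
        idx = rng.choice(len(c5_exons), size=k, replace=False)
        members = [c5_exons[j] for j in sorted(idx)]
        gid = f"FICT{i:04d}"
        for ex in members:
            ex.gene_ids.add(gid)
        chrom = members[0].interval.chrom
        span = GenomicInterval(chrom,
                               min(e.interval.start for e in members),
                               max(e.interval.end for e in members))
        genes.append(GeneModel(gene_id=gid, interval=span,
                               exons=list(members), fictional=True))
    return genes


# ---------------------------------------------------------------------------
# Assembled annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Classified annotation bundle consumed by the quantification stage.

    ``c4_ids`` and ``c5_ids`` are index-paired; each C5 decoy is
    rescaled against the expression of its paired C4 exon's host gene
    while never contributing to any gene's expression.
    """

    genes: dict[str, GeneModel]
    exons: dict[str, ExonRecord]
    te_features: dict[str, TEExonFeature]
    c4_ids: list[str]
    c5_ids: list[str]
    #: C5 decoys overlapping an annotated exon of some gene; kept (to
    #: preserve the C4/C5 pairing) but flagged for the caller.
    colliding_c5_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self._tables: dict | None = None

    @property
    def real_gene_ids(self) -> list[str]:
        return [g for g, m in self.genes.items() if not m.fictional]

    @property
    def fictional_gene_ids(self) -> list[str]:
        return [g for g, m in self.genes.items() if m.fictional]

    def exons_of_class(self, *classes: str) -> list[ExonRecord]:
        return [e for e in self.exons.values() if e.exon_class in classes]

    def paired_c4(self, c5_id: str) -> str:
        if not c5_id.endswith(C5_SUFFIX):
            raise KeyError(f"{c5_id!r} is not a C5 decoy id")
        return c5_id[: -len(C5_SUFFIX)]

    def tables(self) -> dict[str, pd.DataFrame]:
        """Tabular views used by vectorized quantification (cached).

        * ``exons``: exon_id -> chrom/start/end/length/class
        * ``annotated_members``: (exon_id, gene_id) for C1-C3 membership
          in real genes -- the exons whose RPKMs average into gene
          expression.
        * ``fictional_members``: (exon_id, gene_id) for C5 membership in
          fictional genes.
        * ``rescale_hosts``: (exon_id, gene_id) pairs used for rescaling
          (C1-C4 against their host genes; C5 against the paired C4's
          hosts).
        """
        if self._tables is not None:
            return self._tables
        rows = [(e.exon_id, e.interval.chrom, e.interval.start,
                 e.interval.end, e.length, e.exon_class)
                for e in self.exons.values()]
        exon_df = pd.DataFrame(
            rows, columns=["exon_id", "chrom", "start", "end", "length",
                           "exon_class"]).set_index("exon_id")

        ann, fict, resc = [], [], []
        for e in self.exons.values():
            if e.exon_class in ("C1", "C2", "C3"):
                for g in e.gene_ids:
                    if not self.genes[g].fictional:
                        ann.append((e.exon_id, g))
                        resc.append((e.exon_id, g))
            elif e.exon_class == "C4":
                for g in e.gene_ids:
                    resc.append((e.exon_id, g))
            elif e.exon_class == "C5":
                for g in e.gene_ids:       # fictional membership
                    fict.append((e.exon_id, g))
                c4 = self.exons.get(self.paired_c4(e.exon_id))
                if c4 is not None:
                    for g in c4.gene_ids:
                        resc.append((e.exon_id, g))
        self._tables = {
            "exons": exon_df,
            "annotated_members": pd.DataFrame(
                ann, columns=["exon_id", "gene_id"]),
            "fictional_members": pd.DataFrame(
                fict, columns=["exon_id", "gene_id"]),
            "rescale_hosts": pd.DataFrame(
                resc, columns=["exon_id", "gene_id"]),
        }
        return self._tables


def build_annotation_set(genes: list[GeneModel],
                         te_exons: list[ExonRecord],
                         te_features: list[TEExonFeature],
                         alt_table: list[GenomicInterval],
                         *, n_fictional: int = 500,
                         fictional_exon_range: tuple[int, int] = (4, 40),
                         seed: int = 0,
                         c5_strand_aware: bool = True,
                         c5_collision: str = "flag") -> AnnotationSet:
    """Classify exons, build C5 decoys and fictional genes, and bundle.

    ``c5_collision`` controls decoys overlapping an annotated exon:
    ``"flag"`` (default) keeps them and records their ids in
    ``colliding_c5_ids`` (preserving the C4/C5 pairing), ``"shift"``
    slides them further downstream until clear of every exon.
    """
    if c5_collision not in ("flag", "shift"):
        raise ValueError("c5_collision must be 'flag' or 'shift'")
    exons, features = classify_exons(genes, te_exons, te_features, alt_table)
    c4 = sorted((e for e in exons.values() if e.exon_class == "C4"),
                key=lambda e: e.exon_id)
    gene_map = {g.gene_id: g for g in genes}
    c5 = build_simulated_exons(c4, gene_map, strand_aware=c5_strand_aware)

    from intervaltree import IntervalTree
    trees: dict[str, IntervalTree] = {}
    for e in exons.values():
        trees.setdefault(e.interval.chrom, IntervalTree()).addi(
            e.interval.start, e.interval.end)

    colliding: set[str] = set()
    for i, e in enumerate(c5):
        iv = e.interval
        tree = trees.get(iv.chrom)
        if tree is None or not tree.overlap(iv.start, iv.end):
            continue
        if c5_collision == "flag":
            colliding.add(e.exon_id)
            continue
        length = len(iv)
        step = length if iv.strand == "+" else -length
        s, t = iv.start, iv.end
        while tree.overlap(s, t) and s + step >= 0:
            s, t = s + step, t + step
        c5[i] = replace(e, interval=GenomicInterval(iv.chrom, s, t,
                                                    iv.strand))
    for e in c5:
        exons[e.exon_id] = e
    fictional = build_fictional_genes(
        c5, n_genes=n_fictional, min_exons=fictional_exon_range[0],
        max_exons=fictional_exon_range[1], seed=seed)
    for g in fictional:
        gene_map[g.gene_id] = g
    return AnnotationSet(genes=gene_map, exons=exons, te_features=features,
                         c4_ids=[e.exon_id for e in c4],
                         c5_ids=[e.exon_id for e in c5],
                         colliding_c5_ids=frozenset(colliding))


# ---------------------------------------------------------------------------
# Writers (round-trip counterparts of the parsers)
# ---------------------------------------------------------------------------

def write_gene_table(genes: list[GeneModel], path) -> None:
    rows = []
    for g in genes:
        starts = ",".join(str(e.interval.start) for e in g.exons) + ","
        ends = ",".join(str(e.interval.end) for e in g.exons) + ","
        rows.append((g.gene_id, g.interval.chrom, g.strand,
                     g.interval.start, g.interval.end, starts, ends))
    pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "txStart",
                                "txEnd", "exonStarts", "exonEnds"]
                 ).to_csv(path, sep="\t", index=False)


def write_alt_table(intervals: list[GenomicInterval], path) -> None:
    pd.DataFrame([(iv.chrom, iv.start, iv.end) for iv in intervals]
                 ).to_csv(path, sep="\t", index=False, header=False)


def write_te_exon_table(te_exons: list[ExonRecord],
                        te_features: list[TEExonFeature], path) -> None:
    rows = []
    for rec, feat in zip(te_exons, te_features):
        rows.append((rec.exon_id, rec.interval.chrom, rec.interval.start,
                     rec.interval.end, rec.interval.strand,
                     next(iter(rec.gene_ids)), feat.location, feat.family,
                     int(round(feat.rte * feat.eln)),
                     "" if feat.est_inclusion is None else feat.est_inclusion))
    pd.DataFrame(rows, columns=["exon_id", "chrom", "start", "end", "strand",
                                "gene_id", "location", "family",
                                "te_nucleotides", "est_inclusion"]
                 ).to_csv(path, sep="\t", index=False)


def write_c5_bed(annot: AnnotationSet, path) -> None:
    """Export C5 decoys as BED6; the name field carries the paired C4 id."""
    rows = []
    for c5_id in annot.c5_ids:
        e = annot.exons[c5_id]
        rows.append((e.interval.chrom, e.interval.start, e.interval.end,
                     annot.paired_c4(c5_id), 0, e.interval.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
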