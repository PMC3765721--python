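"""Read filtering, exon counting, RPKM and rescaled-RPKM quantification.

The quantification chain for one sample:

1. drop ambiguously mapped reads (non-primary alignments, multi-hit reads);
2. count reads per exon (a read increments an exon if any aligned block
   overlaps it by at least one base; at most once per exon);
3. exon RPKM = count / (exon length in kb x filtered reads in millions);
4. gene expression = mean RPKM of the gene's annotated (C1-C3) exons,
   zero-count exons included; C4 and C5 exons never contribute;
5. the expressed-gene cutoff = an upper quantile (default 0.95,
   nearest-rank) of the 500 fictional decoy genes' expression values;
6. rescaled RPKM = exon RPKM / host-gene expression, capped at 10, for
   exons of expressed genes only.  C5 decoys are rescaled against the
   paired C4 exon's host gene.

The rescaled RPKM proxies the exon's retention (inclusion) rate in the
host gene's transcripts; by construction the mean uncapped rescaled RPKM
over a gene's annotated exons is exactly 1.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import AnnotationSet, ExonRecord, GenomicInterval

__all__ = [
    "AlignmentRecord",
    "SampleExpression",
    "iter_sam",
    "filter_alignments",
    "count_reads_per_exon",
    "rpkm",
    "gene_expression",
    "rescaled_rpkm",
    "determine_cutoff",
    "quantify_sample",
    "read_count_matrix",
    "sample_exon_table",
    "sample_gene_table",
]

logger = logging.getLogger(__name__)

DEFAULT_CAP = 10.0
DEFAULT_CUTOFF_QUANTILE = 0.95


@dataclass
class AlignmentRecord:
    """One reported alignment of one read.

    ``blocks`` are the aligned segments (several for junction-spanning
    reads); ``hit_count`` is the number of reported alignments for the
    read (SAM NH tag).
    """

    read_id: str
    blocks: list[GenomicInterval]
    is_primary: bool = True
    hit_count: int = 1


@dataclass
class SampleExpression:
    """Per-sample expression state after the full quantification chain.

    ``rescaled`` maps (exon_id, gene_id) -> capped rescaled RPKM; an
    exon of an un-expressed gene has no entry.  ``expressed_genes``
    holds the real genes whose expression reached ``cutoff``.
    """

    sample_id: str
    total_filtered_reads: int
    exon_counts: pd.Series
    exon_rpkm: pd.Series
    gene_rpkm: pd.Series
    fictional_gene_rpkm: pd.Series
    cutoff: float
    expressed_genes: set[str]
    rescaled: pd.Series = field(repr=False)  # MultiIndex (exon_id, gene_id)


def iter_sam(path, *, missing_nh: str = "unique") -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM/BAM file via pysam.

    ``missing_nh`` controls records without an NH tag: ``"unique"``
    treats them as single-hit (with a warning once), ``"error"`` raises.
    """
    import pysam

    warned = False
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            try:
                nh = aln.get_tag("NH")
            except KeyError:
                if missing_nh == "error":
                    raise ValueError(
                        f"read {aln.query_name}: missing NH tag")
                if not warned:
                    logger.warning(
                        "reads without NH tag treated as uniquely mapped")
                    warned = True
                nh = 1
            blocks = [GenomicInterval(aln.reference_name, s, e)
                      for s, e in aln.get_blocks()]
            yield AlignmentRecord(read_id=aln.query_name, blocks=blocks,
                                  is_primary=not aln.is_secondary,
                                  hit_count=int(nh))


def filter_alignments(records: Iterable[AlignmentRecord],
                      ) -> Iterator[AlignmentRecord]:
    """Drop ambiguously mapped reads.

    Keeps records that are primary alignments of uniquely mapped reads
    (hit count 1).  Drop counts per reason are logged when the stream is
    exhausted.
    """
    dropped = {"non_primary": 0, "multi_hit": 0}
    for rec in records:
        if not rec.is_primary:
            dropped["non_primary"] += 1
            continue
        if rec.hit_count != 1:
            dropped["multi_hit"] += 1
            continue
        yield rec
    logger.info("filter_alignments dropped %d non-primary, %d multi-hit",
                dropped["non_primary"], dropped["multi_hit"])


def count_reads_per_exon(alignments: Iterable[AlignmentRecord],
                         exons: Iterable[ExonRecord]) -> dict[str, int]:
    """Count, per exon, the reads with any block overlapping it.

    A junction-spanning read increments every exon one of its blocks
    overlaps by >= 1 base, but a given exon at most once per read.
    Exons with no overlapping read get count 0.
    """
    exons = list(exons)
    trees: dict[str, IntervalTree] = {}
    for ex in exons:
        iv = ex.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, ex.exon_id)
    counts = {ex.exon_id: 0 for ex in exons}
    for rec in alignments:
        hit: set[str] = set()
        for block in rec.blocks:
            tree = trees.get(block.chrom)
            if tree is None:
                continue
            for node in tree.overlap(block.start, block.end):
                hit.add(node.data)
        for exon_id in hit:
            counts[exon_id] += 1
    return counts


def rpkm(count: float, exon_length: int, total_filtered_reads: int) -> float:
    """Reads per kilobase of exon per million filtered reads."""
    if exon_length < 1:
        raise ValueError("exon_length must be >= 1")
    if total_filtered_reads < 1:
        raise ValueError("total_filtered_reads must be >= 1")
    return count / ((exon_length / 1e3) * (total_filtered_reads / 1e6))


def gene_expression(exon_rpkms_of_gene: Iterable[float]) -> float:
    """Gene-level expression: arithmetic mean of annotated-exon RPKMs."""
    values = list(exon_rpkms_of_gene)
    if not values:
        raise ValueError("gene has no annotated exon RPKMs")
    return float(np.mean(values))


def rescaled_rpkm(exon_rpkm: float, gene_rpkm: float,
                  cap: float = DEFAULT_CAP) -> float:
    """Exon RPKM divided by host-gene expression, capped.

    The caller must have filtered un-expressed genes: a zero gene
    expression is an error, not a convention.
    """
    if gene_rpkm <= 0:
        raise ValueError("gene_rpkm must be positive; filter un-expressed "
                         "genes before rescaling")
    return min(exon_rpkm / gene_rpkm, cap)


def determine_cutoff(fictional_gene_rpkms: Iterable[float],
                     quantile: float = DEFAULT_CUTOFF_QUANTILE) -> float:
    """Sample-specific expressed-gene cutoff from the decoy genes.

    Nearest-rank (type-1) empirical quantile of the fictional-gene
    expression distribution; genes below the cutoff are treated as
    un-expressed in this sample.
    """
    values = np.asarray(list(fictional_gene_rpkms), dtype=float)
    if values.size == 0:
        raise ValueError("no fictional gene RPKMs provided")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must lie in (0, 1]")
    values = np.sort(values)
    rank = math.ceil(quantile * values.size)     # 1-based nearest rank
    return float(values[rank - 1])


def read_count_matrix(path) -> pd.DataFrame:
    """Load a precomputed exon x sample count matrix (TSV, exon_id index)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def quantify_sample(annot: AnnotationSet,
                    *,
                    sample_id: str,
                    alignments: Iterable[AlignmentRecord] | None = None,
                    counts: Mapping[str, int] | pd.Series | None = None,
                    total_filtered_reads: int | None = None,
                    cutoff_quantile: float = DEFAULT_CUTOFF_QUANTILE,
                    cap: float = DEFAULT_CAP,
                    already_filtered: bool = False) -> SampleExpression:
    """Run the full quantification chain for one sample.

    Input is either a stream of alignment records (filtered here unless
    ``already_filtered``) or a precomputed per-exon count mapping.  For
    the count-matrix route ``total_filtered_reads`` defaults to the sum
    of the supplied counts.
    """
    if (alignments is None) == (counts is None):
        raise ValueError("provide exactly one of alignments or counts")

    tables = annot.tables()
    exon_df = tables["exons"]

    if alignments is not None:
        stream = alignments if already_filtered else filter_alignments(alignments)
        kept = list(stream)
        total = len(kept) if total_filtered_reads is None else total_filtered_reads
        count_map = count_reads_per_exon(kept, annot.exons.values())
        count_s = pd.Series(count_map, dtype=float)
    else:
        count_s = pd.Series(counts, dtype=float)
        total = (int(count_s.sum()) if total_filtered_reads is None
                 else total_filtered_reads)
    count_s = count_s.reindex(exon_df.index, fill_value=0.0)
    if total < 1:
        raise ValueError(f"sample {sample_id!r} has no filtered reads")

    rpkm_s = count_s / ((exon_df["length"] / 1e3) * (total / 1e6))

    members = tables["annotated_members"]
    gene_rpkm = (rpkm_s.reindex(members["exon_id"]).to_numpy())
    gene_rpkm = pd.Series(gene_rpkm, index=members["gene_id"].to_numpy()
                          ).groupby(level=0).mean()

    fict = tables["fictional_members"]
    fict_rpkm = pd.Series(rpkm_s.reindex(fict["exon_id"]).to_numpy(),
                          index=fict["gene_id"].to_numpy()
                          ).groupby(level=0).mean()

    cutoff = determine_cutoff(fict_rpkm.to_numpy(), quantile=cutoff_quantile)
    expressed_mask = gene_rpkm >= cutoff
    # A gene with zero expression cannot serve as a rescaling denominator;
    # only reachable in the degenerate all-zero-decoy case (cutoff 0).
    expressed_mask &= gene_rpkm > 0
    expressed = set(gene_rpkm.index[expressed_mask])

    hosts = tables["rescale_hosts"]
    keep = hosts["gene_id"].isin(expressed).to_numpy()
    sub = hosts.loc[keep]
    ratio = (rpkm_s.reindex(sub["exon_id"]).to_numpy()
             / gene_rpkm.reindex(sub["gene_id"]).to_numpy())
    rescaled = pd.Series(np.minimum(ratio, cap),
                         index=pd.MultiIndex.from_frame(
                             sub, names=["exon_id", "gene_id"]))

    return SampleExpression(
        sample_id=sample_id,
        total_filtered_reads=int(total),
        exon_counts=count_s,
        exon_rpkm=rpkm_s,
        gene_rpkm=gene_rpkm,
        fictional_gene_rpkm=fict_rpkm,
        cutoff=cutoff,
        expressed_genes=expressed,
        rescaled=rescaled)


def sample_exon_table(sample: SampleExpression,
                      annot: AnnotationSet) -> pd.DataFrame:
    """Stable per-sample exon TSV view: one row per (exon, host gene)."""
    exon_df = annot.tables()["exons"]
    idx = sample.rescaled.index
    exon_ids = idx.get_level_values("exon_id")
    return pd.DataFrame({
        "exon_id": exon_ids,
        "gene_id": idx.get_level_values("gene_id"),
        "exon_class": exon_df["exon_class"].reindex(exon_ids).to_numpy(),
        "count": sample.exon_counts.reindex(exon_ids).to_numpy(),
        "rpkm": sample.exon_rpkm.reindex(exon_ids).to_numpy(),
        "rescaled_rpkm": sample.rescaled.to_numpy(),
    })


def sample_gene_table(sample: SampleExpression) -> pd.DataFrame:
    """Per-sample gene TSV view with the expressed flag and cutoff."""
    return pd.DataFrame({
        "gene_id": sample.gene_rpkm.index,
        "gene_rpkm": sample.gene_rpkm.to_numpy(),
        "expressed": [g in sample.expressed_genes
                      for g in sample.gene_rpkm.index],
        "cutoff": sample.cutoff,
    })
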