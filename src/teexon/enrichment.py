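"""Highly-expressed TE exons and their enrichment in C2H2 ZNF genes.

A TE exon is *highly expressed* when its rescaled RPKM exceeds 0.25
(strictly) in at least two samples.  For each TE family a 2x2 table
cross-classifies that family's exons by expression status and by whether
a host gene belongs to the C2H2 zinc-finger gene family; Fisher's exact
test probes independence.  Families that contributed no exonized TE to
a ZNF gene are excluded (p reported missing) rather than tested on a
degenerate margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet, FAMILIES, TEExonFeature
from .variability import ExpressionMatrix

__all__ = [
    "ContingencyTable2x2",
    "flag_highly_expressed",
    "host_gene_set",
    "family_znf_tables",
    "fisher_exact",
    "load_znf_list",
    "znf_enrichment_table",
]

DEFAULT_THRESHOLD = 0.25
DEFAULT_MIN_SAMPLES = 2


@dataclass
class ContingencyTable2x2:
    """Family-wise cross-classification of TE exons.

    ``n1``/``n2``: other / highly-expressed exons in non-ZNF genes;
    ``n3``/``n4``: other / highly-expressed exons in ZNF genes.
    ``excluded`` marks families with no exonized TE in any ZNF gene
    (n3 + n4 = 0), for which no test is performed.
    """

    family: str
    n1: int
    n2: int
    n3: int
    n4: int

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n3, self.n4) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must hold at least one exon")

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4

    @property
    def excluded(self) -> bool:
        return self.n3 + self.n4 == 0


def flag_highly_expressed(matrix: ExpressionMatrix,
                          threshold: float = DEFAULT_THRESHOLD,
                          min_samples: int = DEFAULT_MIN_SAMPLES,
                          ) -> set[str]:
    """Exons with rescaled RPKM strictly above ``threshold`` in at least
    ``min_samples`` samples (missing cells never qualify)."""
    above = (matrix.values > threshold).sum(axis=1)
    flagged = matrix.values.index[above >= min_samples]
    return set(flagged.get_level_values("exon_id"))


def host_gene_set(flagged_exons: Iterable[str],
                  annot: AnnotationSet) -> set[str]:
    """Union of the host genes of the flagged exons."""
    out: set[str] = set()
    for exon_id in flagged_exons:
        out |= annot.exons[exon_id].gene_ids
    return out


def family_znf_tables(te_features: Mapping[str, TEExonFeature],
                      flagged: Set[str],
                      znf_genes: Set[str],
                      annot: AnnotationSet) -> list[ContingencyTable2x2]:
    """One 2x2 table per TE family present in the data.

    An exon counts as ZNF-hosted when any of its host genes is in the
    C2H2 ZNF list.  Counts within a family always sum to the family's
    TE-exon total.
    """
    counts = {fam: [0, 0, 0, 0] for fam in FAMILIES}
    for exon_id, feat in te_features.items():
        hosts = annot.exons[exon_id].gene_ids
        in_znf = bool(hosts & znf_genes)
        high = exon_id in flagged
        slot = (2 if in_znf else 0) + (1 if high else 0)
        counts[feat.family][slot] += 1
    out = []
    for fam in FAMILIES:
        n1, n2, n3, n4 = counts[fam]
        if n1 + n2 + n3 + n4 == 0:
            continue
        out.append(ContingencyTable2x2(fam, n1, n2, n3, n4))
    return out


def fisher_exact(table: ContingencyTable2x2,
                 sided: str = "two-sided") -> float:
    """Fisher's exact hypergeometric p-value for a 2x2 table.

    Two-sided by default (sum of outcome probabilities no larger than
    the observed one); ``sided`` may also be ``"less"`` or
    ``"greater"``.  A zero row or column margin leaves the test
    undefined (NaN).
    """
    a, b, c, d = table.n1, table.n2, table.n3, table.n4
    if min(a + b, c + d, a + c, b + d) == 0:
        return float("nan")
    res = stats.fisher_exact([[a, b], [c, d]], alternative=sided)
    return float(res.pvalue)


def load_znf_list(path) -> set[str]:
    """Read a plain-text ZNF gene list, one gene id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def znf_enrichment_table(matrix: ExpressionMatrix,
                         annot: AnnotationSet,
                         znf_genes: Set[str],
                         threshold: float = DEFAULT_THRESHOLD,
                         min_samples: int = DEFAULT_MIN_SAMPLES,
                         sided: str = "two-sided") -> pd.DataFrame:
    """End-to-end family-wise ZNF enrichment (flag, tabulate, test)."""
    flagged = flag_highly_expressed(matrix, threshold, min_samples)
    tables = family_znf_tables(annot.te_features, flagged, znf_genes, annot)
    rows = []
    for t in tables:
        p = float("nan") if t.excluded else fisher_exact(t, sided)
        rows.append({"family": t.family, "N1": t.n1, "N2": t.n2,
                     "N3": t.n3, "N4": t.n4, "p": p,
                     "excluded": t.excluded})
    return pd.DataFrame(rows)
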