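"""Genomic feature classification of insertion sites and the genic
enrichment / transcriptional-orientation tests.

Insertions are classified into 3'-UTR, 5'-UTR, coding, intronic or
nongenic compartments.  Under random insertion the expected count in a
compartment is proportional to its size in Mb, so enrichment or
depletion is tested by comparing observed against size-proportional
expected counts.  Insertions landing inside genes are additionally
tested for a bias toward the orientation opposite the gene's
transcription, the signature of purifying selection against same-strand
insertions.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .model import MEIError, MEILocus

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("3UTR", "5UTR", "coding", "intronic", "nongenic")

#: Precedence when an insertion overlaps several annotations: a coding
#: exon of one gene wins over the intron of an overlapping gene, etc.
_PRECEDENCE = {"coding": 0, "5UTR": 1, "3UTR": 2, "intronic": 3, "nongenic": 4}

#: Genome compartment sizes (Mb) for the build-38 RefSeq-style partition
#: used throughout: 3'-UTR, 5'-UTR, coding, intronic and everything else.
GENOME_CLASS_SIZES_MB = {
    "3UTR": 90.75,
    "5UTR": 21.02,
    "coding": 41.94,
    "intronic": 1830.01,
    "nongenic": 1273.63,
}
GENOME_TOTAL_MB = 3257.35


@dataclass
class FeatureMap:
    """Interval annotation of a genome into feature compartments.

    ``intervals`` uses half-open 0-based coordinates (BED convention)
    with columns chrom, start, end, feature_class, gene_strand.  Regions
    not covered by any interval are nongenic.  ``chrom_lengths`` bounds
    each chromosome; positions beyond a bound (or on an unknown
    chromosome) are rejected rather than silently classified.
    """

    intervals: pd.DataFrame
    chrom_lengths: dict[str, int]
    class_sizes_mb: dict[str, float] | None = None
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "feature_class", "gene_strand"}
        missing = required - set(self.intervals.columns)
        if missing:
            raise MEIError(f"feature map missing columns: {sorted(missing)}")
        bad = set(self.intervals["feature_class"]) - set(FEATURE_CLASSES)
        if bad:
            raise MEIError(f"unknown feature classes: {sorted(bad)}")
        for chrom, sub in self.intervals.groupby("chrom"):
            tree = IntervalTree()
            for row in sub.itertuples(index=False):
                if row.end > row.start:
                    tree.addi(row.start, row.end, (row.feature_class, row.gene_strand))
            self._trees[str(chrom)] = tree
        if self.class_sizes_mb is None:
            self.class_sizes_mb = self._sizes_from_intervals()

    def _sizes_from_intervals(self) -> dict[str, float]:
        sizes = {c: 0.0 for c in FEATURE_CLASSES}
        # attribute every base to its highest-precedence covering class
        for chrom, length in self.chrom_lengths.items():
            tree = self._trees.get(chrom, IntervalTree())
            boundaries = sorted({0, length} | {b for iv in tree for b in (iv.begin, iv.end)})
            for lo, hi in zip(boundaries[:-1], boundaries[1:]):
                if lo >= length:
                    continue
                hi = min(hi, length)
                hits = [iv.data[0] for iv in tree.overlap(lo, hi)]
                cls = min(hits, key=_PRECEDENCE.get) if hits else "nongenic"
                sizes[cls] += (hi - lo) / 1e6
        return sizes

    @property
    def total_mb(self) -> float:
        return float(sum(self.class_sizes_mb.values()))

    @classmethod
    def from_bed(
        cls,
        path: str | os.PathLike,
        chrom_lengths: dict[str, int],
        class_sizes_mb: dict[str, float] | None = None,
    ) -> "FeatureMap":
        """Read a BED6-style annotation: name column = feature class."""
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "feature_class", "score", "gene_strand"],
            dtype={"chrom": str},
        )
        frame = frame.drop(columns="score")
        frame["gene_strand"] = frame["gene_strand"].fillna("none")
        return cls(frame, chrom_lengths, class_sizes_mb)

    def to_bed(self, path: str | os.PathLike) -> None:
        out = self.intervals.copy()
        out.insert(4, "score", 0)
        out.to_csv(path, sep="\t", header=False, index=False)


def classify_insertion(locus: MEILocus, fmap: FeatureMap) -> tuple[str, str]:
    """Assign an insertion point to a feature class and gene strand.

    Overlapping annotations resolve by precedence
    coding > 5'-UTR > 3'-UTR > intronic > nongenic; the strand returned
    is that of the assigned gene (``"none"`` for nongenic).
    """
    length = fmap.chrom_lengths.get(locus.chrom)
    if length is None:
        raise MEIError(f"chromosome {locus.chrom!r} not present in feature map")
    point = locus.pos - 1  # 1-based insertion point -> 0-based coordinate
    if point >= length:
        raise MEIError(
            f"position {locus.chrom}:{locus.pos} beyond chromosome end ({length})"
        )
    tree = fmap._trees.get(locus.chrom)
    hits = sorted(tree.at(point), key=lambda iv: (_PRECEDENCE[iv.data[0]], iv.begin)) if tree else []
    if not hits:
        return "nongenic", "none"
    feature_class, strand = hits[0].data
    return feature_class, strand


def classify_callset(loci: list[MEILocus], fmap: FeatureMap) -> pd.DataFrame:
    rows = [classify_insertion(l, fmap) for l in loci]
    return pd.DataFrame(rows, columns=["feature_class", "gene_strand"])


def expected_counts(
    total: int,
    class_sizes_mb: dict[str, float],
    total_mb: float | None = None,
) -> dict[str, int]:
    """Size-proportional expected insertion counts per feature class.

    ``expected_c = round(total * size_c / total_mb)`` with half-up
    rounding.  ``total_mb`` defaults to the sum of the class sizes and
    must agree with it to within 0.01 Mb when given explicitly.
    """
    sizes_sum = sum(class_sizes_mb.values())
    if total_mb is None:
        total_mb = sizes_sum
    elif abs(total_mb - sizes_sum) > 0.01:
        raise MEIError(
            f"total_mb {total_mb} does not match class size sum {sizes_sum:.2f}"
        )
    out = {}
    for cls, size in class_sizes_mb.items():
        if size <= 0:
            raise MEIError(f"class size must be positive ({cls}: {size})")
        out[cls] = int(np.floor(total * size / total_mb + 0.5))
    return out


def enrichment_test(
    observed_c: int,
    total: int,
    size_c: float,
    total_mb: float,
    method: str = "fisher",
) -> float:
    """Two-sided test of enrichment/depletion of a feature class.

    ``method="fisher"`` runs Fisher's exact test on the 2x2 table of
    observed vs size-proportional expected counts; ``method="binomial"``
    tests the observed count against a Binomial(total, size_c/total_mb)
    null directly.
    """
    if observed_c > total:
        raise MEIError("observed count cannot exceed the total")
    if size_c <= 0 or total_mb <= 0:
        raise MEIError("sizes must be positive")
    if method == "binomial":
        return float(stats.binomtest(observed_c, total, size_c / total_mb).pvalue)
    if method != "fisher":
        raise MEIError(f"unknown method {method!r}")
    expected_c = int(np.floor(total * size_c / total_mb + 0.5))
    table = np.array(
        [[observed_c, total - observed_c], [expected_c, total - expected_c]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 table %s; returning p = 1", table.tolist())
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def enrichment_table(
    observed: dict[str, int],
    class_sizes_mb: dict[str, float] | None = None,
    total_mb: float | None = None,
    method: str = "fisher",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Observed/expected/p table over all feature classes for one MEI type.

    Significance is Bonferroni-corrected for the number of classes
    tested.
    """
    if class_sizes_mb is None:
        class_sizes_mb = GENOME_CLASS_SIZES_MB
    if total_mb is None:
        total_mb = sum(class_sizes_mb.values())
    total = sum(observed.values())
    expected = expected_counts(total, class_sizes_mb, total_mb)
    rows = []
    m = len(class_sizes_mb)
    for cls, size in class_sizes_mb.items():
        p = enrichment_test(observed[cls], total, size, total_mb, method=method)
        rows.append(
            {
                "feature_class": cls,
                "size_mb": size,
                "observed": observed[cls],
                "expected": expected[cls],
                "p": p,
                "significant": p < alpha / m,
            }
        )
    return pd.DataFrame(rows)


def orientation_bias_test(n_opposite: int, n_total: int) -> float:
    """Two-sided z-test of the opposite-orientation proportion against 0.5.

    Uses the null variance p0(1-p0)/n without continuity correction.
    """
    if n_total <= 0:
        raise MEIError("n_total must be positive")
    if n_opposite > n_total or n_opposite < 0:
        raise MEIError("n_opposite must lie in [0, n_total]")
    _, p = proportions_ztest(n_opposite, n_total, value=0.5, prop_var=0.5)
    return float(p)
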