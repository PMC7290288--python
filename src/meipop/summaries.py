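"""Cohort-level summaries: discovery rates, per-group novel singleton
rates, and LINE-1 transduction totals."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MEIError, MEICallSet, MISSING, SamplePanel


def discovery_rate(n_meis: int, n_individuals: int) -> float:
    """MEIs discovered per sequenced individual."""
    if n_individuals <= 0:
        raise MEIError("n_individuals must be positive")
    return n_meis / n_individuals


def singleton_mask(calls: MEICallSet) -> np.ndarray:
    """Per-locus flag: all nonreference alleles confined to one individual.

    A singleton locus has exactly one carrier, whether heterozygous
    (a true singleton allele) or homozygous (a doubleton in one person).
    """
    carriers = (calls.genotypes > 0).sum(axis=1)
    return carriers == 1


def singleton_rates_by_group(
    calls: MEICallSet,
    panel: SamplePanel,
    novel: np.ndarray | None = None,
) -> pd.Series:
    """Novel singleton MEIs per individual, by major population group.

    ``novel`` is a per-locus boolean flag (e.g. absence from an earlier
    call set, see :func:`meipop.io.novel_mask`); all loci count when
    omitted.  The rate for a group is the number of novel singleton loci
    whose single carrier belongs to the group, divided by the group size.
    Empty groups yield NaN.
    """
    if novel is None:
        novel = np.ones(calls.n_loci, dtype=bool)
    novel = np.asarray(novel, dtype=bool)
    if novel.shape != (calls.n_loci,):
        raise MEIError("novel flag length must equal the number of loci")
    group_of = panel.group_of()
    singles = singleton_mask(calls) & novel
    counts = {g: 0 for g in panel.groups}
    for i in np.flatnonzero(singles):
        carrier = calls.samples[int(np.argmax(calls.genotypes[i] > 0))]
        g = group_of.get(carrier)
        if g in counts:
            counts[g] += 1
    sizes = panel.frame.groupby("group")["sample"].count()
    rates = {
        g: (counts[g] / sizes[g]) if sizes.get(g, 0) else float("nan")
        for g in panel.groups
    }
    return pd.Series(rates, name="novel_singletons_per_individual")


@dataclass
class TransductionEvent:
    """A host-sequence segment co-mobilized by an active source LINE-1."""

    insertion_chrom: str
    insertion_pos: int
    insertion_feature: str
    source_chrom: str
    source_pos: int
    length_bp: int
    source_reference: str  # "Ref" or "NonRef"

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise MEIError("transduced length must be positive")


def transduction_summary(
    events: list[TransductionEvent], n_genomes: int
) -> tuple[float, float]:
    """Total kb of transduced host sequence and genomes per event.

    Returns ``(total_kb, genomes_per_event)`` rounded to 2 and 1 decimal
    places respectively, matching how such rates are conventionally
    reported.
    """
    if not events:
        raise MEIError("no transduction events supplied")
    total_kb = round(sum(e.length_bp for e in events) / 1000.0, 2)
    genomes_per_event = round(n_genomes / len(events), 1)
    return total_kb, genomes_per_event


def read_transduction_tsv(path: str | os.PathLike) -> list[TransductionEvent]:
    """Read a transduction event table (insertion, feature, source, length)."""
    frame = pd.read_csv(path, sep="\t")
    events = []
    for row in frame.itertuples(index=False):
        ins_chrom, ins_pos = str(row.insertion).split(":")
        src_chrom, src_pos = str(row.source).split(":")
        events.append(
            TransductionEvent(
                insertion_chrom=ins_chrom,
                insertion_pos=int(ins_pos),
                insertion_feature=str(row.feature),
                source_chrom=src_chrom,
                source_pos=int(src_pos),
                length_bp=int(row.length_bp),
                source_reference=str(row.source_reference),
            )
        )
    return events


def write_transduction_tsv(
    events: list[TransductionEvent], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        {
            "insertion": [f"{e.insertion_chrom}:{e.insertion_pos}" for e in events],
            "feature": [e.insertion_feature for e in events],
            "source": [f"{e.source_chrom}:{e.source_pos}" for e in events],
            "length_bp": [e.length_bp for e in events],
            "source_reference": [e.source_reference for e in events],
        }
    ).to_csv(path, sep="\t", index=False)
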