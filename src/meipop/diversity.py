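"""Diversity statistics for MEI genotypes: individual heterozygosity,
private alleles, group heterozygosity, and Weir-Cockerham F_ST.

F_ST follows the Weir & Cockerham (1984) variance-component estimator
for diploid biallelic loci: per-locus components ``a`` (among groups),
``b`` (among individuals within groups) and ``c`` (within individuals),
combined across loci as a ratio of sums (the "weighted" multi-locus
estimator).  Negative per-locus components are retained before
summation; loci monomorphic over the groups analysed are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MEIError, MEICallSet, MISSING, SamplePanel

logger = logging.getLogger(__name__)


def individual_heterozygosity(calls: MEICallSet) -> pd.Series:
    """Observed fraction of heterozygous sites per sample.

    ``het / called`` over that sample's non-missing genotypes; samples
    with no called locus yield NaN with a warning.
    """
    g = calls.genotypes
    called = (g != MISSING).sum(axis=0)
    het = (g == 1).sum(axis=0)
    out = np.full(calls.n_samples, np.nan)
    ok = called > 0
    out[ok] = het[ok] / called[ok]
    if (~ok).any():
        bad = [s for s, o in zip(calls.samples, ok) if not o]
        logger.warning("samples with zero called loci: %s", bad)
    return pd.Series(out, index=calls.samples, name="het_fraction")


def private_alleles(calls: MEICallSet) -> pd.Series:
    """Number of loci whose nonreference alleles are unique to each sample.

    A locus is private to a sample when that sample carries dosage 1 or 2
    and every other sample carries dosage 0 (singleton heterozygotes and
    homozygous doubletons both count).
    """
    carriers = (calls.genotypes > 0).sum(axis=1)
    counts = np.zeros(calls.n_samples, dtype=int)
    for i in np.flatnonzero(carriers == 1):
        counts[int(np.argmax(calls.genotypes[i] > 0))] += 1
    return pd.Series(counts, index=calls.samples, name="n_private")


def group_heterozygosity(calls: MEICallSet, panel: SamplePanel) -> pd.Series:
    """Average observed heterozygote fraction over all loci, per group."""
    group_of = panel.group_of()
    out = {}
    for g in panel.groups:
        cols = [i for i, s in enumerate(calls.samples) if group_of.get(s) == g]
        if not cols:
            out[g] = float("nan")
            continue
        geno = calls.genotypes[:, cols]
        called = geno != MISSING
        with np.errstate(invalid="ignore"):
            per_locus = (geno == 1).sum(axis=1) / called.sum(axis=1)
        out[g] = float(np.nanmean(per_locus))
    return pd.Series(out, name="group_het")


def diversity_table(calls: MEICallSet, panel: SamplePanel) -> pd.DataFrame:
    """Per-sample diversity record: group, heterozygosity, private count."""
    het = individual_heterozygosity(calls)
    priv = private_alleles(calls)
    group_of = panel.group_of()
    return pd.DataFrame(
        {
            "sample": calls.samples,
            "group": [group_of.get(s) for s in calls.samples],
            "het_fraction": het.values,
            "n_private": priv.values,
        }
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST


@dataclass
class FstEstimate:
    """Multi-locus Weir-Cockerham theta for a set of groups."""

    groups: tuple[str, ...]
    theta: float
    n_loci: int


def _wc_components(
    geno_by_group: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus W&C (1984) variance components for diploid biallelic data.

    ``geno_by_group`` holds one loci x samples dosage matrix per group
    (missing = MISSING).  Returns (a, b, c, usable) arrays over loci;
    ``usable`` marks loci with >= 2 groups having >= 2 called samples and
    overall polymorphism.
    """
    r = len(geno_by_group)
    n_loci = geno_by_group[0].shape[0]
    n_i = np.zeros((r, n_loci))
    p_i = np.zeros((r, n_loci))
    h_i = np.zeros((r, n_loci))
    for k, geno in enumerate(geno_by_group):
        called = geno != MISSING
        n = called.sum(axis=1).astype(float)
        alt = np.where(called, geno, 0).sum(axis=1)
        het = ((geno == 1) & called).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, alt / (2 * n), np.nan)
            h_i[k] = np.where(n > 0, het / n, np.nan)
        n_i[k] = n
    enough = (n_i >= 2).sum(axis=0) >= 2
    # treat groups with <2 called samples as absent at that locus
    ok = n_i >= 2
    n_i = np.where(ok, n_i, 0.0)
    p_i = np.where(ok, p_i, 0.0)
    h_i = np.where(ok, h_i, 0.0)
    r_l = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_i.sum(axis=0) / r_l
        n_tot = r_l * n_bar
        nc = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r_l - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r_l - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_tot
        a = (n_bar / nc) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r_l - 1) / r_l - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - s2 * (r_l - 1) / r_l
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2
    polymorphic = (p_bar > 0) & (p_bar < 1)
    usable = enough & polymorphic & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, usable


def weir_cockerham_fst(
    calls: MEICallSet,
    panel: SamplePanel,
    groups: list[str] | None = None,
) -> FstEstimate:
    """Multi-locus Weir-Cockerham theta over the given (default: all) groups.

    theta = sum(a) / sum(a + b + c) over usable loci.
    """
    if groups is None:
        groups = panel.groups
    if len(groups) < 2:
        raise MEIError("F_ST requires at least two groups")
    group_of = panel.group_of()
    geno_by_group = []
    for g in groups:
        cols = [i for i, s in enumerate(calls.samples) if group_of.get(s) == g]
        if not cols:
            raise MEIError(f"group {g!r} has no samples in the call set")
        geno_by_group.append(calls.genotypes[:, cols])
    a, b, c, usable = _wc_components(geno_by_group)
    denom = (a + b + c)[usable].sum()
    if denom == 0:
        raise MEIError("zero total variance; cannot estimate F_ST")
    theta = float(a[usable].sum() / denom)
    return FstEstimate(groups=tuple(groups), theta=theta, n_loci=int(usable.sum()))


def pairwise_fst(calls: MEICallSet, panel: SamplePanel) -> pd.DataFrame:
    """Weir-Cockerham theta for every pair of major groups."""
    rows = []
    groups = panel.groups
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            est = weir_cockerham_fst(calls, panel, [groups[i], groups[j]])
            rows.append(
                {
                    "group_a": groups[i],
                    "group_b": groups[j],
                    "theta": est.theta,
                    "n_loci": est.n_loci,
                }
            )
    return pd.DataFrame(rows)
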