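"""Core data model for mobile element insertion (MEI) call sets.

Nonreference MEIs (Alu, LINE-1, SVA copies absent from the reference
genome) are treated as biallelic presence/absence polymorphisms.  A call
set is a loci x samples matrix of alternate-allele dosages together with
per-locus metadata (element class, subfamily, insertion orientation,
target site duplication length, caller quality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Dosage code for a missing genotype in the matrix (int8 storage).
MISSING = -1

ME_CLASSES = ("ALU", "LINE1", "SVA")

MAJOR_GROUPS = (
    "Africa",
    "West Eurasia",
    "South Asia",
    "Central Asia/Siberia",
    "East Asia",
    "Oceania",
    "Americas",
)

#: Cohort design of the diversity panel this package targets: seven major
#: population groups with these sample counts (296 genomes total).
GROUP_SIZES = {
    "Africa": 49,
    "West Eurasia": 75,
    "South Asia": 49,
    "Central Asia/Siberia": 26,
    "East Asia": 46,
    "Oceania": 25,
    "Americas": 26,
}


class MEIError(ValueError):
    """Domain error raised for invalid MEI data."""


@dataclass
class MEILocus:
    """A single nonreference insertion site.

    ``pos`` is the 1-based insertion point.  ``tsd_len`` is the target
    site duplication length in bp (0 when the caller reported none).
    ``assess`` is the caller's 0-5 evidence tier; 5 means a TSD was
    resolved on both sides.  ``orientation`` is the strand of the
    inserted element relative to the reference.
    """

    chrom: str
    pos: int
    me_class: str
    subfamily: str = "indeterminate"
    orientation: str = "+"
    tsd_len: int = 0
    assess: int = 0
    filter_status: str = "PASS"
    is_reference_insertion: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MEIError(f"locus position must be >= 1, got {self.pos}")
        if self.me_class not in ME_CLASSES:
            raise MEIError(
                f"me_class must be one of {ME_CLASSES}, got {self.me_class!r}"
            )
        if not 0 <= self.tsd_len <= 50:
            raise MEIError(f"tsd_len out of range 0-50: {self.tsd_len}")
        if self.orientation not in ("+", "-"):
            raise MEIError(f"orientation must be + or -, got {self.orientation!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class MEICallSet:
    """Loci x samples dosage matrix plus locus metadata.

    ``genotypes`` counts nonreference alleles per sample: 0, 1, 2, or
    :data:`MISSING`.  Row order follows ``loci``; column order follows
    ``samples``.
    """

    loci: list[MEILocus]
    samples: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.loci), len(self.samples)):
            raise MEIError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise MEIError("genotypes must be 0, 1, 2 or missing")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def called_mask(self) -> np.ndarray:
        """Boolean matrix, True where the genotype is called."""
        return self.genotypes != MISSING

    def subset_loci(self, index: Sequence[int] | np.ndarray) -> "MEICallSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return MEICallSet(
            loci=[self.loci[i] for i in index],
            samples=list(self.samples),
            genotypes=self.genotypes[index, :],
        )

    def subset_samples(self, names: Iterable[str]) -> "MEICallSet":
        names = list(names)
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in pos]
        if missing:
            raise MEIError(f"unknown samples: {missing}")
        cols = [pos[s] for s in names]
        return MEICallSet(
            loci=list(self.loci), samples=names, genotypes=self.genotypes[:, cols]
        )

    def by_class(self, me_class: str) -> "MEICallSet":
        idx = [i for i, l in enumerate(self.loci) if l.me_class == me_class]
        return self.subset_loci(idx)

    def allele_frequencies(self) -> np.ndarray:
        """Overall alternate allele frequency per locus (missing excluded)."""
        g = self.genotypes
        called = g != MISSING
        n_called = called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def locus_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [l.chrom for l in self.loci],
                "pos": [l.pos for l in self.loci],
                "me_class": [l.me_class for l in self.loci],
                "subfamily": [l.subfamily for l in self.loci],
                "orientation": [l.orientation for l in self.loci],
                "tsd_len": [l.tsd_len for l in self.loci],
                "assess": [l.assess for l in self.loci],
                "filter_status": [l.filter_status for l in self.loci],
            }
        )


@dataclass
class SamplePanel:
    """Sample metadata: population, major group and sampling coordinates."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample", "population", "group", "lat", "lon")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise MEIError(f"sample panel missing columns: {missing}")
        lat = self.frame["lat"].to_numpy(float)
        lon = self.frame["lon"].to_numpy(float)
        if ((lat < -90) | (lat > 90)).any():
            raise MEIError("latitude out of range [-90, 90]")
        if ((lon <= -180) | (lon > 180)).any():
            raise MEIError("longitude out of range (-180, 180]")
        unknown = set(self.frame["group"]) - set(MAJOR_GROUPS)
        if unknown:
            raise MEIError(f"unknown major groups: {sorted(unknown)}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample"])

    @property
    def groups(self) -> list[str]:
        """Major groups present, in canonical order."""
        present = set(self.frame["group"])
        return [g for g in MAJOR_GROUPS if g in present]

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.frame["sample"], self.frame["group"]))

    def members(self, group: str) -> list[str]:
        sel = self.frame["group"] == group
        return list(self.frame.loc[sel, "sample"])

    def coordinates(self) -> pd.DataFrame:
        return self.frame.set_index("sample")[["lat", "lon"]]
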