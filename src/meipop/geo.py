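"""Geographic analyses: great-circle distances, Beringian two-segment
routing, and the spherical centroid of a shared-ancestry component.

New World migration distances are routed through Naukan (Chukotka), the
former eastern-most settlement of Eurasia, to model the Beringian
corridor.  The geographic origin of a shared-ancestry component is
summarised by the spherical centroid (3D unit-vector mean) of all Old
World individuals whose component fraction exceeds a threshold; a
spherical rather than planar mean is essential near the antimeridian,
where Siberian and Beringian longitudes wrap.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MEIError, SamplePanel

EARTH_RADIUS_KM = 6371.0088

#: Naukan, Chukotka: (lat, lon) waypoint for the Beringian route.
NAUKAN = (66.027222, 169.7077782)


def _check_point(lat: float, lon: float) -> None:
    if not -90 <= lat <= 90:
        raise MEIError(f"latitude out of range: {lat}")
    if not -180 < lon <= 180:
        raise MEIError(f"longitude out of range: {lon}")


def haversine(
    a: tuple[float, float],
    b: tuple[float, float],
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Great-circle distance in km between two (lat, lon) points."""
    _check_point(*a)
    _check_point(*b)
    lat1, lon1, lat2, lon2 = map(np.radians, (*a, *b))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0, 1))))


def beringian_distance(
    origin: tuple[float, float],
    destination_new_world: tuple[float, float],
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Two-segment great-circle distance routed through Naukan.

    Models the entry path into the Americas: origin -> Naukan -> New
    World destination.  Always at least the direct distance.
    """
    return haversine(origin, NAUKAN, radius_km) + haversine(
        NAUKAN, destination_new_world, radius_km
    )


@dataclass
class AncestryTable:
    """Per-individual ancestry fractions for K model components."""

    frame: pd.DataFrame  # index: sample; columns k1..kK

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(float)
        if ((vals < -1e-9) | (vals > 1 + 1e-9)).any():
            raise MEIError("ancestry fractions must lie in [0, 1]")
        sums = vals.sum(axis=1)
        if np.abs(sums - 1).max() > 1e-6:
            bad = self.frame.index[np.abs(sums - 1) > 1e-6][:3]
            raise MEIError(f"ancestry fractions must sum to 1 (first bad: {list(bad)})")

    @property
    def k(self) -> int:
        return self.frame.shape[1]

    def component(self, component: int | str) -> pd.Series:
        """Fraction of one component (by column name or 0-based index)."""
        if isinstance(component, int):
            return self.frame.iloc[:, component]
        return self.frame[component]

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "AncestryTable":
        frame = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(frame)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample")


def _to_unit_vectors(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    lat_r, lon_r = np.radians(lat), np.radians(lon)
    return np.column_stack(
        [
            np.cos(lat_r) * np.cos(lon_r),
            np.cos(lat_r) * np.sin(lon_r),
            np.sin(lat_r),
        ]
    )


def spherical_centroid(points: np.ndarray) -> tuple[float, float]:
    """Spherical centroid of (lat, lon) rows: unit-vector mean renormalised."""
    points = np.atleast_2d(np.asarray(points, float))
    vecs = _to_unit_vectors(points[:, 0], points[:, 1])
    mean = vecs.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-12:
        raise MEIError("degenerate centroid: points cancel on the sphere")
    mean /= norm
    lat = float(np.degrees(np.arcsin(np.clip(mean[2], -1, 1))))
    lon = float(np.degrees(np.arctan2(mean[1], mean[0])))
    return lat, lon


def ancestry_centroid(
    panel: SamplePanel,
    anc: AncestryTable,
    threshold: float = 0.01,
    component: int | str = 0,
    old_world_only: bool = True,
    weighted: bool = False,
) -> tuple[float, float, pd.DataFrame]:
    """Geographic centroid of individuals carrying a shared-ancestry component.

    Selects individuals whose fraction of ``component`` is strictly
    greater than ``threshold`` (Old World individuals only by default,
    i.e. every major group except Americas), and returns the spherical
    centroid of their sampling coordinates plus the passing-individual
    table.  ``weighted=True`` weights each unit vector by the ancestry
    fraction instead of counting each individual once.
    """
    frac = anc.component(component)
    meta = panel.frame.set_index("sample")
    shared = meta.index.intersection(frac.index)
    meta = meta.loc[shared]
    frac = frac.loc[shared]
    if old_world_only:
        keep = meta["group"] != "Americas"
        meta, frac = meta[keep], frac[keep]
    passing = frac > threshold
    if not passing.any():
        raise MEIError(f"no individual exceeds the ancestry threshold {threshold}")
    meta = meta[passing]
    frac = frac[passing]
    vecs = _to_unit_vectors(meta["lat"].to_numpy(float), meta["lon"].to_numpy(float))
    w = frac.to_numpy(float) if weighted else np.ones(len(meta))
    mean = (vecs * w[:, None]).sum(axis=0) / w.sum()
    norm = np.linalg.norm(mean)
    if norm < 1e-12:
        raise MEIError("degenerate centroid: points cancel on the sphere")
    mean /= norm
    lat = float(np.degrees(np.arcsin(np.clip(mean[2], -1, 1))))
    lon = float(np.degrees(np.arctan2(mean[1], mean[0])))
    table = pd.DataFrame(
        {
            "group": meta["group"],
            "lat": meta["lat"],
            "lon": meta["lon"],
            "ancestry_fraction": frac,
        }
    )
    return lat, lon, table
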