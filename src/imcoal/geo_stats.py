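"""Geographic analyses: isolation by distance and climate correlations.

Regions are summarized by the arithmetic mean of their member samples'
coordinates; pairwise geographic distances are great-circle (haversine,
Earth radius 6371 km).  Isolation by distance is the Pearson correlation of
distance (km) against pairwise F_ST over region pairs, computed separately
within the western cluster, within the eastern cluster, and between
clusters, with named outlier regions excluded.  Climate association is the
Pearson correlation of the eastern admixture proportion against each of the
19 bioclimatic variables, Bonferroni-corrected across the family of 19.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EARTH_RADIUS_KM",
    "N_BIOCLIM",
    "RegionGeo",
    "CorrelationResult",
    "centroid",
    "haversine_km",
    "ibd_correlation",
    "climate_correlation",
]

EARTH_RADIUS_KM = 6371.0
N_BIOCLIM = 19


@dataclass(frozen=True)
class RegionGeo:
    """A region's centroid and cluster membership."""

    region: str
    latitude: float
    longitude: float
    n_samples: int
    cluster: str | None = None  # "west" / "east"
    outlier: bool = False

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} out of range")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} out of range")


@dataclass(frozen=True)
class CorrelationResult:
    label: str
    r: float
    p_value: float
    p_adjusted: float
    n: int


def centroid(samples: pd.DataFrame, cluster: dict[str, str] | None = None,
             outliers: tuple[str, ...] = ()) -> dict[str, RegionGeo]:
    """Regional centroids: mean latitude and longitude of member samples.

    ``samples`` needs columns region, lat, lon.  Empty regions are an error
    by construction (they simply do not appear); an explicitly requested
    empty region raises KeyError downstream.
    """
    required = {"region", "lat", "lon"}
    if not required <= set(samples.columns):
        raise ValueError(f"sample table needs columns {sorted(required)}")
    out: dict[str, RegionGeo] = {}
    for region, grp in samples.groupby("region", sort=False):
        out[str(region)] = RegionGeo(
            region=str(region),
            latitude=float(grp["lat"].mean()),
            longitude=float(grp["lon"].mean()),
            n_samples=int(len(grp)),
            cluster=None if cluster is None else cluster.get(str(region)),
            outlier=str(region) in outliers,
        )
    if not out:
        raise ValueError("no samples given")
    return out


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    lat1, lon1 = np.radians(a)
    lat2, lon2 = np.radians(b)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h))))


def ibd_correlation(fst: pd.DataFrame, geo: dict[str, RegionGeo],
                    scope: str, exclusions: tuple[str, ...] = ()
                    ) -> CorrelationResult:
    """Isolation by distance: Pearson r of km distance vs pairwise F_ST.

    ``fst`` needs columns region_a, region_b, fst; ``scope`` is one of
    "within-west", "within-east", "between" and is resolved against the
    cluster labels carried by the RegionGeo entries.  Regions listed in
    ``exclusions`` (and flagged outliers) are dropped.  At least three
    region pairs must remain; zero variance in either vector is an error.
    """
    if scope not in ("within-west", "within-east", "between"):
        raise ValueError(f"unknown scope {scope!r}")
    excluded = set(exclusions) | {g.region for g in geo.values() if g.outlier}

    dists, values = [], []
    for _, row in fst.iterrows():
        ra, rb = str(row["region_a"]), str(row["region_b"])
        if ra in excluded or rb in excluded:
            continue
        ga, gb = geo[ra], geo[rb]
        pair_scope = {
            ("west", "west"): "within-west",
            ("east", "east"): "within-east",
        }.get((ga.cluster, gb.cluster), "between"
              if {ga.cluster, gb.cluster} == {"west", "east"} else None)
        if pair_scope != scope:
            continue
        dists.append(haversine_km((ga.latitude, ga.longitude),
                                  (gb.latitude, gb.longitude)))
        values.append(float(row["fst"]))

    if len(dists) < 3:
        raise ValueError(f"scope {scope!r} has {len(dists)} pairs; need >= 3")
    dists = np.asarray(dists)
    values = np.asarray(values)
    if np.ptp(dists) == 0 or np.ptp(values) == 0:
        raise ValueError("zero variance in distances or F_ST values")
    res = sps.pearsonr(dists, values)
    return CorrelationResult(label=scope, r=float(res.statistic),
                             p_value=float(res.pvalue),
                             p_adjusted=float(res.pvalue), n=len(dists))


def climate_correlation(table: pd.DataFrame,
                        admixture_col: str = "admixture",
                        family_size: int = N_BIOCLIM) -> list[CorrelationResult]:
    """Eastern-admixture vs bioclim correlations, Bonferroni-corrected.

    ``table`` holds one row per sample with the admixture proportion and the
    bio1..bio19 columns; samples missing a variable are dropped for that
    variable.  Adjusted p = min(1, family_size * raw p).
    """
    if admixture_col not in table.columns:
        raise ValueError(f"missing column {admixture_col!r}")
    adm_all = table[admixture_col].to_numpy(dtype=float)
    if np.nanmin(adm_all) < 0 or np.nanmax(adm_all) > 1:
        raise ValueError("admixture proportions must lie in [0, 1]")
    bio_cols = [c for c in table.columns if c.lower().startswith("bio")]
    out: list[CorrelationResult] = []
    for col in bio_cols:
        v = table[col].to_numpy(dtype=float)
        ok = np.isfinite(v) & np.isfinite(adm_all)
        if ok.sum() < 3:
            continue
        res = sps.pearsonr(adm_all[ok], v[ok])
        p = float(res.pvalue)
        out.append(CorrelationResult(
            label=col, r=float(res.statistic), p_value=p,
            p_adjusted=min(1.0, family_size * p), n=int(ok.sum())))
    return out
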