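"""Explanatory distance matrices: time, diet, language, geography.

The four explanatory variables are encoded as symmetric nonnegative
distance matrices over individuals, following rule-based definitions tied
to five historical regions of South Patagonia:

* Western Archipelago and Beagle Channel — maritime subsistence, language
  isolates (Kaweskar and Yamana, possibly related to each other);
* Mitre Peninsula — mixed subsistence, Chonan language (Haush);
* North Tierra del Fuego — terrestrial, Chonan (Selk'nam);
* South Continent — terrestrial, Chonan (Aonikenk/Tehuelche).

Geography follows plausible movement routes: straight lines within a
region, shortest paths through a waypoint network between regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from popkit.genotype_io import IndividualRecord

EARTH_RADIUS_KM = 6371.0

REGIONS = (
    "WesternArchipelago",
    "BeagleChannel",
    "MitrePeninsula",
    "NorthTierraDelFuego",
    "SouthContinent",
)

_MARITIME = {"WesternArchipelago", "BeagleChannel"}
_TERRESTRIAL = {"NorthTierraDelFuego", "SouthContinent"}
_MIXED = {"MitrePeninsula"}

# marine-diet calibration anchors: delta-15N of ~11.5 permil marks a wholly
# terrestrial diet, ~22.0 permil a ~90% marine diet
D15N_TERRESTRIAL = 11.5
D15N_MARINE = 22.0
MARINE_FRACTION_AT_MARINE_ANCHOR = 0.9
MARINE_CATEGORIES = (0, 20, 40, 60, 80)  # percent
MARINE_CATEGORY_UNCERTAINTY = 10  # percent, +/-
# marine reservoir correction for radiocarbon calibration (stored for
# metadata provenance; calibration itself happens upstream)
DELTA_R = (221.0, 40.0)  # (mean, 1 SD)


@dataclass
class LabeledDistanceMatrix:
    """Symmetric nonnegative distance matrix over individual labels."""

    labels: list[str]
    values: np.ndarray
    variable: str  # genetic | geography | diet | language | time

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, variable: str) -> "LabeledDistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), variable)


def _check_region(region: str) -> None:
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r} (expected one of {REGIONS})")


def temporal_distance(ind1: IndividualRecord, ind2: IndividualRecord) -> float:
    """|midpoint difference| of the 95.4% calibrated date ranges, in years.

    Modern individuals count as date 0.
    """
    return abs(ind1.date_midpoint_calbp - ind2.date_midpoint_calbp)


def diet_distance(region1: str, region2: str) -> float:
    """Ordinal subsistence distance between two regions.

    Terrestrial vs maritime primary resources = 2; the mixed-resource
    Mitre Peninsula is at distance 1 from everything else; regions with
    similar procurement strategies are at 0.
    """
    _check_region(region1)
    _check_region(region2)
    if region1 == region2:
        return 0.0
    c1m, c2m = region1 in _MIXED, region2 in _MIXED
    if c1m or c2m:
        return 0.0 if (c1m and c2m) else 1.0
    same_class = (region1 in _MARITIME) == (region2 in _MARITIME)
    return 0.0 if same_class else 2.0


def language_distance(region1: str, region2: str) -> float:
    """Ordinal linguistic distance between two regions.

    Within the Chonan family: Mitre Peninsula (Haush) and North Tierra del
    Fuego (Selk'nam) are closest (1); either to the South Continent
    (Aonikenk) is 2. The Western Archipelago and Beagle Channel speak
    language isolates: 3 between each other (possibly related), 4 to any
    Chonan-speaking region. Same region = 0.
    """
    _check_region(region1)
    _check_region(region2)
    if region1 == region2:
        return 0.0
    pair = {region1, region2}
    if pair == {"MitrePeninsula", "NorthTierraDelFuego"}:
        return 1.0
    if "SouthContinent" in pair and pair & {"MitrePeninsula", "NorthTierraDelFuego"}:
        return 2.0
    if pair == {"WesternArchipelago", "BeagleChannel"}:
        return 3.0
    return 4.0


def haversine(
    lat1: float, lon1: float, lat2: float, lon2: float,
    earth_radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(lon2) - np.deg2rad(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * earth_radius_km * np.arcsin(np.sqrt(a)))


@dataclass
class RouteNetwork:
    """Waypoint polyline network for between-region travel distances.

    ``waypoints`` maps waypoint id -> (lat, lon); ``edges`` are undirected
    waypoint pairs whose lengths are the great-circle distances of their
    endpoints. Sites attach to their nearest waypoint by a straight spur.
    """

    waypoints: dict[str, tuple[float, float]]
    edges: list[tuple[str, str]]
    _graph: nx.Graph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.Graph()
        for wid, (lat, lon) in self.waypoints.items():
            g.add_node(wid, lat=lat, lon=lon)
        for a, b in self.edges:
            g.add_edge(a, b, km=haversine(*self.waypoints[a], *self.waypoints[b]))
        self._graph = g

    def nearest_waypoint(self, lat: float, lon: float) -> tuple[str, float]:
        best, best_d = None, np.inf
        for wid, (wlat, wlon) in self.waypoints.items():
            dd = haversine(lat, lon, wlat, wlon)
            if dd < best_d:
                best, best_d = wid, dd
        return best, best_d

    def path_km(self, wp1: str, wp2: str) -> float:
        try:
            return nx.shortest_path_length(self._graph, wp1, wp2, weight="km")
        except nx.NetworkXNoPath:
            raise ValueError(f"route network disconnected between {wp1} and {wp2}")

    @classmethod
    def read_tsv(cls, waypoints_path, edges_path) -> "RouteNetwork":
        wdf = pd.read_csv(waypoints_path, sep="\t")
        edf = pd.read_csv(edges_path, sep="\t")
        wps = {
            str(r.waypoint_id): (float(r.latitude), float(r.longitude))
            for r in wdf.itertuples(index=False)
        }
        edges = [(str(r.a), str(r.b)) for r in edf.itertuples(index=False)]
        return cls(wps, edges)


@dataclass
class Site:
    name: str
    region: str
    latitude: float
    longitude: float


def geographic_distance(
    site1: Site, site2: Site, network: RouteNetwork | None = None
) -> float:
    """Rule-based travel distance in km between two sites.

    Same site = 0; same region = straight great-circle line; different
    regions = spur to the nearest route waypoint, shortest path through
    the route network, spur to the destination.
    """
    if site1.name == site2.name:
        return 0.0
    if site1.region == site2.region:
        return haversine(site1.latitude, site1.longitude, site2.latitude, site2.longitude)
    if network is None:
        raise ValueError(
            f"sites {site1.name} and {site2.name} are in different regions "
            "and no route network was supplied"
        )
    w1, spur1 = network.nearest_waypoint(site1.latitude, site1.longitude)
    w2, spur2 = network.nearest_waypoint(site2.latitude, site2.longitude)
    return spur1 + network.path_km(w1, w2) + spur2


def marine_fraction_from_d15N(delta15N: float) -> tuple[float, int]:
    """Marine diet fraction and calibration category from a δ15N value.

    Linear between the anchors (11.5 permil -> 0, 22.0 permil -> 0.9),
    clamped to [0, 1]. The category is the nearest of the five calibration
    mixing classes {0, 20, 40, 60, 80}% (ties round down); each class
    carries a +/-10% uncertainty by convention.
    """
    frac = 0.9 * (delta15N - D15N_TERRESTRIAL) / (D15N_MARINE - D15N_TERRESTRIAL)
    frac = float(np.clip(frac, 0.0, 1.0))
    pct = frac * 100.0
    cats = np.asarray(MARINE_CATEGORIES, dtype=float)
    dists = np.abs(cats - pct)
    best = dists.min()
    # ties round down: among categories at the minimal distance, take smallest
    category = int(cats[dists <= best + 1e-12][0])
    return frac, category


def build_distance_matrix(
    individuals: Sequence[IndividualRecord],
    variable: str,
    *,
    sites: Mapping[str, Site] | None = None,
    network: RouteNetwork | None = None,
) -> LabeledDistanceMatrix:
    """Assemble one explanatory LabeledDistanceMatrix over individuals.

    ``variable`` is one of time / diet / language / geography. Geography
    needs ``sites`` (site name -> Site) and, for between-region pairs, a
    route network.
    """
    labels = [ind.individual_id for ind in individuals]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = individuals[i], individuals[j]
            if variable == "time":
                d = temporal_distance(a, b)
            elif variable == "diet":
                d = diet_distance(a.region, b.region)
            elif variable == "language":
                d = language_distance(a.region, b.region)
            elif variable == "geography":
                if sites is None:
                    raise ValueError("geography needs a site table")
                d = geographic_distance(sites[a.site], sites[b.site], network)
            else:
                raise ValueError(f"unknown variable {variable!r}")
            mat[i, j] = mat[j, i] = d
    return LabeledDistanceMatrix(labels, mat, variable)
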