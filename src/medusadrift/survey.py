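"""Field-observation analytics: stranding biomass, size classes, abundance
coding, observed-vs-modeled comparison, and habitat statistics.

Biomass of a stranded jellyfish follows the local allometric power law
W = 0.0002 * D**2.8786, with W the wet weight in grammes and D the bell
diameter in millimetres.  Seasons are meteorological quarters
(DJF / MAM / JJA / SON).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .timeutil import SEASON_OF_MONTH, SEASON_ORDER

BIOMASS_COEFF = 0.0002
BIOMASS_EXPONENT = 2.8786

#: Bell-diameter size classes (mm), half-open [lo, hi).
SIZE_CLASS_EDGES = (20.0, 30.0, 50.0, 70.0, 90.0)
SIZE_CLASS_LABELS = ("20-30", "30-50", "50-70", "70-90")


@dataclass
class SurveyRecord:
    """One beach-survey observation of stranded jellyfish."""

    date: _dt.date
    site: str
    coast: str  # "sicily" | "calabria"
    count: int
    diameters: Sequence[float] = field(default_factory=tuple)  # bell, mm
    reference_diameter: Optional[float] = None  # imputation for damaged ones

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if any(d <= 0 for d in self.diameters):
            raise ValueError("diameters must be positive")
        if len(self.diameters) > self.count:
            raise ValueError("cannot measure more individuals than counted")

    @property
    def season(self) -> str:
        return SEASON_OF_MONTH[self.date.month]


def read_survey_csv(path) -> list:
    """Load survey records from CSV.

    Columns: date, site, coast, count, diameters (semicolon-separated mm,
    may be empty), reference_diameter (optional).
    """
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        raw = row.get("diameters")
        if pd.isna(raw) or str(raw).strip() == "":
            diam = ()
        else:
            diam = tuple(float(v) for v in str(raw).split(";") if v.strip())
        ref = row.get("reference_diameter")
        ref = None if pd.isna(ref) else float(ref)
        records.append(SurveyRecord(
            date=pd.Timestamp(row["date"]).date(), site=str(row["site"]),
            coast=str(row["coast"]), count=int(row["count"]),
            diameters=diam, reference_diameter=ref))
    return records


def biomass(diameter_mm):
    """Wet weight (g) of a jellyfish from its bell diameter (mm).

    W = 0.0002 * D**2.8786; strictly increasing in D.
    """
    d = np.asarray(diameter_mm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    w = BIOMASS_COEFF * d ** BIOMASS_EXPONENT
    return float(w) if np.ndim(diameter_mm) == 0 else w


def abundance_class(count: int, large_aggregation: bool = False):
    """Eye-count abundance coding: 0, 1 (1-10), 2 (10-100), 3 (>100).

    Boundary counts go to the lower class (10 -> 1, 100 -> 2).  The
    'large_aggregation' label (events of several hundred individuals) is
    assigned only by explicit flag, never inferred from the count.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if large_aggregation:
        return "large_aggregation"
    if count == 0:
        return 0
    if count <= 10:
        return 1
    if count <= 100:
        return 2
    return 3


def seasonal_size_table(records: Sequence[SurveyRecord],
                        by_coast: bool = False) -> pd.DataFrame:
    """Relative incidence (%) of each bell-diameter class per season.

    Classes are half-open bins [20,30), [30,50), [50,70), [70,90) mm;
    diameters outside 20-90 mm go to an explicit 'other' column rather
    than being dropped.  Seasons with no measured diameters are absent
    (undefined), not rows of zeros.  Each present row sums to 100%.
    """
    if not any(len(r.diameters) for r in records):
        raise ValueError("need at least one measured diameter")
    rows = []
    for r in records:
        for d in r.diameters:
            rows.append({"season": r.season, "coast": r.coast, "diameter": d})
    df = pd.DataFrame(rows)
    edges = list(SIZE_CLASS_EDGES)
    labels = list(SIZE_CLASS_LABELS)
    df["size_class"] = pd.cut(df["diameter"], bins=edges, labels=labels,
                              right=False)
    df["size_class"] = df["size_class"].cat.add_categories(["other"])
    df.loc[df["size_class"].isna(), "size_class"] = "other"
    keys = ["coast", "season"] if by_coast else ["season"]
    counts = (df.groupby(keys + ["size_class"], observed=False)
                .size().unstack("size_class"))
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    order = [s for s in SEASON_ORDER
             if s in pct.index.get_level_values("season")]
    pct = pct.reindex(order, level="season") if by_coast else pct.loc[order]
    return pct


def seasonal_biomass(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    """Cumulated stranded biomass (g) per coast and season, with % of total.

    Each measured diameter contributes its allometric weight; unmeasured
    individuals (count beyond the measured list, e.g. specimens too
    damaged to measure) are imputed at the record's explicit reference
    diameter.  A record with unmeasured individuals and no reference
    diameter is an error - imputation is never a hidden default.
    """
    if not records:
        return pd.DataFrame(columns=["coast", "season", "biomass_g", "pct"])
    rows = []
    for r in records:
        w = float(np.sum(biomass(np.asarray(r.diameters))) if r.diameters else 0.0)
        unmeasured = r.count - len(r.diameters)
        if unmeasured > 0:
            if r.reference_diameter is None:
                raise ValueError(
                    f"record {r.site} {r.date}: {unmeasured} unmeasured "
                    "individuals but no reference_diameter for imputation")
            w += unmeasured * biomass(r.reference_diameter)
        rows.append({"coast": r.coast, "season": r.season, "biomass_g": w})
    df = (pd.DataFrame(rows).groupby(["coast", "season"], as_index=False)
          ["biomass_g"].sum())
    total = df["biomass_g"].sum()
    df["pct"] = 100.0 * df["biomass_g"] / total if total > 0 else 0.0
    df["season"] = pd.Categorical(df["season"], categories=SEASON_ORDER,
                                  ordered=True)
    return df.sort_values(["coast", "season"]).reset_index(drop=True)


def stranding_rate_comparison(observed_calabria: float, observed_sicily: float,
                              modeled_calabria: float, modeled_sicily: float):
    """Observed and modeled Calabria:Sicily stranding ratios.

    Each ratio is truncated (not rounded) to one decimal, matching the
    'about'-level precision the per-coast estimates carry.  A zero Sicily
    total makes the corresponding ratio undefined (NaN).
    """
    def ratio(cal, sic):
        if sic <= 0:
            return float("nan")
        return np.floor(10.0 * cal / sic) / 10.0

    return (ratio(observed_calabria, observed_sicily),
            ratio(modeled_calabria, modeled_sicily))


@dataclass
class SpeedDistribution:
    """Summary of a current-speed record set."""

    bin_edges: np.ndarray
    counts: np.ndarray
    fraction_below: float
    threshold: float
    mean_speed_flood: float  # along-component > 0 (northward)
    mean_speed_ebb: float  # along-component < 0 (southward)


def speed_distribution(speeds, along_component=None, threshold: float = 0.05,
                       bin_width: float = 0.05) -> SpeedDistribution:
    """Current-intensity histogram, calm fraction and tidal-phase means.

    ``fraction_below`` is the fraction of records with speed below the
    threshold (default 5 cm/s, the routine jellyfish swimming speed).
    When a signed along-channel component is supplied, mean speeds are
    also reported conditioned on its sign (flood = positive/northward,
    ebb = negative/southward).
    """
    s = np.asarray(speeds, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one record")
    if np.any(s < 0):
        raise ValueError("speeds must be >= 0")
    edges = np.arange(0.0, s.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    counts, edges = np.histogram(s, bins=edges)
    frac = float(np.mean(s < threshold))
    flood = ebb = float("nan")
    if along_component is not None:
        a = np.asarray(along_component, dtype=float)
        if a.shape != s.shape:
            raise ValueError("along_component must match speeds")
        if np.any(a > 0):
            flood = float(s[a > 0].mean())
        if np.any(a < 0):
            ebb = float(s[a < 0].mean())
    return SpeedDistribution(bin_edges=edges, counts=counts,
                             fraction_below=frac, threshold=threshold,
                             mean_speed_flood=flood, mean_speed_ebb=ebb)


def read_current_csv(path) -> pd.DataFrame:
    """Load a current-meter series (time, u, v) and derive speed/along."""
    df = pd.read_csv(path)
    df["speed"] = np.hypot(df["u"], df["v"])
    df["along_component"] = df["v"]  # +v = northward = flood
    return df


@dataclass
class UpwellingDepth:
    """Shallowest depth at which the density-anomaly threshold is reached."""

    depth_m: Optional[float]  # None if never reached
    surface_reached: bool  # dense water occupies the whole column


def upwelling_depth(depths, sigma_t, threshold: float = 28.5) -> UpwellingDepth:
    """Depth of the upwelled-water upper limit from a density profile.

    Scans the profile from the surface for the first sample at or above
    the sigma-t threshold and interpolates linearly within that depth
    interval.  If the surface value already meets the threshold the dense
    water occupies the whole column (``surface_reached``); if no sample
    does, the depth is None.
    """
    d = np.asarray(depths, dtype=float)
    s = np.asarray(sigma_t, dtype=float)
    if d.size == 0 or d.size != s.size:
        raise ValueError("profile must be non-empty with matching lengths")
    if np.any(np.diff(d) <= 0) or np.any(d < 0):
        raise ValueError("depths must be non-negative and strictly increasing")
    above = np.flatnonzero(s >= threshold)
    if len(above) == 0:
        return UpwellingDepth(depth_m=None, surface_reached=False)
    i = above[0]
    if i == 0:
        return UpwellingDepth(depth_m=float(d[0]), surface_reached=True)
    # linear interpolation within the crossing interval
    frac = (threshold - s[i - 1]) / (s[i] - s[i - 1])
    return UpwellingDepth(depth_m=float(d[i - 1] + frac * (d[i] - d[i - 1])),
                          surface_reached=False)
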