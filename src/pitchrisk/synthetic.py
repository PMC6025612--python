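"""Synthetic site, soil, water and questionnaire generators.

Emulates the statistical structure of an arsenic-contaminated sports club:
a ~47,000 m^2 site split into irrigated pitches (IA) and surrounding
non-irrigated ground (NIA); right-skewed topsoil arsenic with zone means
near 138 (IA) and 59.5 (NIA) mg/kg; a single extreme concentration inside
a small fenced farm plot within the NIA; cores whose arsenic decays
roughly exponentially with depth; irrigation water near 6.6-6.7 mg As/L;
and a questionnaire population whose clothing, game frequency, visit
frequency and membership duration span the observed exposure-parameter
ranges.

Everything is driven by one master seed; sub-generators derive child
streams deterministically, so a fixed seed reproduces every table
byte-for-byte.  The generators exist so the full pipeline is testable
without any field data; they emulate the *statistics* of such a site, not
its actual geometry or raw measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box
from shapely.geometry.base import BaseGeometry

from .io import CLOTHING_CATEGORIES, SOIL_COLUMNS, WATER_COLUMNS

__all__ = [
    "SiteSpec",
    "SoilPopulationSpec",
    "SurveySpec",
    "default_site",
    "generate_soil_samples",
    "generate_depth_cores",
    "generate_water_samples",
    "generate_survey",
]


@dataclass(frozen=True)
class SiteSpec:
    """Site geometry and sampling design (planar projected metres, y north).

    ``zones`` maps the labels IA/NIA to polygons that are interior-disjoint
    and contained in ``boundary``; ``restricted`` (the fenced farm plot)
    lies inside the NIA.  ``n_per_zone`` is the stratified design: how many
    primary sampling locations each zone receives.  ``grid_spacing`` sets
    the candidate sampling lattice.
    """

    boundary: BaseGeometry
    zones: Mapping[str, BaseGeometry]
    restricted: BaseGeometry
    grid_spacing: float = 15.0
    n_per_zone: Mapping[str, int] = field(default_factory=lambda: {"IA": 23, "NIA": 16})
    seed: int = 0

    def validate(self) -> None:
        for label, geom in self.zones.items():
            if geom.is_empty or geom.area == 0:
                raise ValueError(f"zone {label!r} polygon is empty")
            if not self.boundary.buffer(1e-6).contains(geom):
                raise ValueError(f"zone {label!r} extends outside the site boundary")
        labels = list(self.zones)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                inter = self.zones[a].intersection(self.zones[b])
                if inter.area > 1e-6:
                    raise ValueError(f"zones {a!r} and {b!r} overlap")
        if "NIA" in self.zones and not self.zones["NIA"].buffer(1e-6).contains(self.restricted):
            raise ValueError("restricted sub-area must lie inside the NIA")


@dataclass(frozen=True)
class SoilPopulationSpec:
    """Concentration law per zone plus outlier, depth and duplicate policy.

    Zone concentrations follow a lognormal matched to (mean, sd) -- the
    minimal positive right-skewed law consistent with reported moments --
    truncated at mean + ``truncate_sigmas``*sd (draws beyond are resampled)
    so that only the injected outlier can cross the combined-set Tukey
    outer fence.  Cores decay exponentially from a zone-specific surface
    concentration at ``depth_decay`` per cm with multiplicative noise.
    QA duplicates are re-measurements with small multiplicative noise
    taken at every ``duplicate_every``-th location.
    """

    zone_mean: Mapping[str, float] = field(
        default_factory=lambda: {"IA": 138.1, "NIA": 59.5})
    zone_sd: Mapping[str, float] = field(
        default_factory=lambda: {"IA": 82.9, "NIA": 37.7})
    outlier_mg_kg: float = 591.31
    depth_decay_per_cm: float = math.log(5.0) / 10.0
    core_surface: Mapping[str, float] = field(
        default_factory=lambda: {"IA": 206.0, "NIA": 44.37})
    depth_noise_cv: float = 0.10
    max_core_depth_cm: float = 60.0
    duplicate_every: int = 5
    duplicate_cv: float = 0.05
    truncate_sigmas: float = 3.5

    def lognormal_params(self, zone: str) -> tuple[float, float]:
        """(mu, sigma) of the lognormal matching the zone's mean and sd."""
        m, s = self.zone_mean[zone], self.zone_sd[zone]
        sigma2 = math.log1p((s / m) ** 2)
        return math.log(m) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class SurveySpec:
    """Questionnaire population: clothing, games, visits, membership.

    Defaults reflect a club of mostly weekly adult players: visits cluster
    near once a week (about 52/yr) with occasional and intensive tails
    bounded by [3, 80]; membership duration is right-skewed on
    [1 month, 13 yr] (the club's age); games per visit are 1-3 with most
    players playing a single game.
    """

    n: int = 179
    clothing_probs: Mapping[str, float] = field(default_factory=lambda: {
        "long_sleeves-pants-long_socks": 0.04,
        "long_sleeves-pants-short_socks": 0.02,
        "long_sleeves-shorts-long_socks": 0.06,
        "long_sleeves-shorts-short_socks": 0.03,
        "short_sleeves-pants-long_socks": 0.06,
        "short_sleeves-pants-short_socks": 0.04,
        "short_sleeves-shorts-long_socks": 0.45,
        "short_sleeves-shorts-short_socks": 0.30,
    })
    ev_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.30, 3: 0.15})
    ef_range: tuple[float, float] = (3.0, 80.0)
    ed_range: tuple[float, float] = (0.083, 13.0)
    ed_beta: tuple[float, float] = (0.7, 1.6)
    ef_point: float | None = None   # degenerate override for EF
    ed_point: float | None = None   # degenerate override for ED

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("survey sample size must be > 0")
        for name, probs in (("clothing", self.clothing_probs), ("EV", self.ev_probs)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{name} category probabilities must sum to 1, got {total!r}")
        unknown = set(self.clothing_probs) - set(CLOTHING_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown clothing category(ies): {sorted(unknown)}")
        if not set(self.ev_probs) <= {1, 2, 3}:
            raise ValueError("EV support must be a subset of {1, 2, 3}")


def default_site(seed: int = 0) -> SiteSpec:
    """A synthetic ~47,000 m^2 club: three half-hectare pitches plus a farm plot.

    Boundary 250 m x 188 m; three 100 x 50 m pitches form the IA; the NIA
    is the remainder, with a 20 x 20 m fenced farm plot in its NE corner.
    """
    boundary = box(0.0, 0.0, 250.0, 188.0)
    pitches = [
        box(20.0, 15.0, 120.0, 65.0),
        box(20.0, 80.0, 120.0, 130.0),
        box(135.0, 15.0, 235.0, 65.0),
    ]
    ia = shapely.union_all(pitches)
    nia = boundary.difference(ia)
    farm = box(222.0, 160.0, 242.0, 180.0)
    return SiteSpec(boundary=boundary, zones={"IA": ia, "NIA": nia},
                    restricted=farm, seed=seed)


def _candidate_grid(zone: BaseGeometry, spacing: float) -> np.ndarray:
    """Lattice points strictly inside a polygon, offset half a spacing."""
    minx, miny, maxx, maxy = zone.bounds
    xs = np.arange(minx + spacing / 2.0, maxx, spacing)
    ys = np.arange(miny + spacing / 2.0, maxy, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(zone, pts[:, 0], pts[:, 1])
    return pts[inside]


def _truncated_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                         cap: float, n: int) -> np.ndarray:
    """Lognormal draws resampled until all fall at or below ``cap``."""
    out = rng.lognormal(mu, sigma, size=n)
    for _ in range(1000):
        bad = out > cap
        if not bad.any():
            return out
        out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
    raise RuntimeError("truncated lognormal failed to converge")  # pragma: no cover


def _append_duplicates(df: pd.DataFrame, every: int, cv: float,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Add a noisy re-measurement row for every ``every``-th location."""
    if not every or every <= 0:
        return df
    dup_rows = []
    for pos in range(every - 1, len(df), every):
        row = df.iloc[pos].copy()
        row["tAs"] = float(row["tAs"]) * (1.0 + cv * rng.standard_normal())
        row["tAs"] = max(row["tAs"], 1e-6)
        row["is_duplicate"] = True
        row["duplicate_of"] = row["sample_id"]
        row["sample_id"] = row["sample_id"] + "D"
        dup_rows.append(row)
    if dup_rows:
        df = pd.concat([df, pd.DataFrame(dup_rows)], ignore_index=True)
    return df


def generate_soil_samples(site: SiteSpec, pop: SoilPopulationSpec) -> pd.DataFrame:
    """Surface (0-5 cm) soil table for the stratified design.

    One sample per selected lattice location in each zone (``n_per_zone``,
    default 23 IA + 16 NIA = 39 primaries), plus a QA duplicate at every
    ``duplicate_every``-th location; exactly one NIA location falls inside
    the restricted farm plot and carries the injected extreme concentration
    ``outlier_mg_kg``, which by construction is the only value beyond the
    combined set's Tukey outer fence.
    """
    site.validate()
    ss = np.random.SeedSequence(site.seed)
    rngs = {label: np.random.default_rng(child)
            for label, child in zip(("loc", "IA", "NIA", "dup"), ss.spawn(4))}

    frames = []
    for zone in ("IA", "NIA"):
        n = site.n_per_zone[zone]
        poly = site.zones[zone]
        if zone == "NIA":
            cands = _candidate_grid(poly.difference(site.restricted), site.grid_spacing)
            n_random = n - 1  # one location reserved for the farm plot
        else:
            cands = _candidate_grid(poly, site.grid_spacing)
            n_random = n
        if len(cands) < n_random:
            raise ValueError(
                f"zone {zone!r}: only {len(cands)} candidate locations at "
                f"spacing {site.grid_spacing} for {n_random} samples")
        pick = rngs["loc"].choice(len(cands), size=n_random, replace=False)
        xy = cands[pick]
        mu, sigma = pop.lognormal_params(zone)
        cap = pop.zone_mean[zone] + pop.truncate_sigmas * pop.zone_sd[zone]
        conc = _truncated_lognormal(rngs[zone], mu, sigma, cap, n_random)
        if zone == "NIA":
            farm_xy = np.asarray(site.restricted.centroid.coords[0])
            xy = np.vstack([xy, farm_xy])
            conc = np.append(conc, pop.outlier_mg_kg)
        frames.append(pd.DataFrame({
            "x": xy[:, 0], "y": xy[:, 1], "zone": zone, "tAs": conc,
        }))

    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "sample_id", [f"S{i + 1:02d}" for i in range(len(df))])
    df["depth_top"] = 0.0
    df["depth_bottom"] = 5.0
    df["is_duplicate"] = False
    df["duplicate_of"] = pd.NA
    df = _append_duplicates(df, pop.duplicate_every, pop.duplicate_cv, rngs["dup"])
    return df[SOIL_COLUMNS]


def generate_depth_cores(
    site: SiteSpec,
    pop: SoilPopulationSpec,
    n_cores: int = 4,
    n_segments: int = 6,
    duplicate_every: int | None = None,
) -> pd.DataFrame:
    """Soil-core table: contiguous 10-cm bands with exponential As decay.

    Cores are placed on zone lattice points (IA-heavy by default: cores
    alternate IA, IA, IA, NIA, ...).  Segment concentration is
    ``core_surface[zone] * exp(-decay * depth_top)`` with multiplicative
    lognormal noise (CV ``depth_noise_cv``), so expected concentration
    strictly decreases with depth for any positive decay rate.
    ``duplicate_every`` optionally adds QA duplicates on the segment rows.
    """
    site.validate()
    if n_segments < 2:
        raise ValueError("cores need at least 2 segments")
    if n_segments * 10.0 > pop.max_core_depth_cm:
        raise ValueError(
            f"{n_segments} x 10 cm segments exceed the maximum core depth "
            f"of {pop.max_core_depth_cm} cm")
    ss = np.random.SeedSequence(site.seed + 104729)  # offset core stream
    rng_loc, rng_conc, rng_dup = (np.random.default_rng(c) for c in ss.spawn(3))

    zones_cycle = ["IA", "IA", "IA", "NIA"]
    rows = []
    for c in range(n_cores):
        zone = zones_cycle[c % len(zones_cycle)]
        cands = _candidate_grid(site.zones[zone], site.grid_spacing)
        xy = cands[rng_loc.integers(len(cands))]
        surface = pop.core_surface[zone]
        cv = pop.depth_noise_cv
        sigma = math.sqrt(math.log1p(cv ** 2)) if cv > 0 else 0.0
        for seg in range(n_segments):
            top, bottom = seg * 10.0, (seg + 1) * 10.0
            expected = surface * math.exp(-pop.depth_decay_per_cm * top)
            noise = rng_conc.lognormal(-sigma ** 2 / 2.0, sigma) if sigma else 1.0
            rows.append({
                "sample_id": f"C{c + 1}-{seg + 1}", "x": xy[0], "y": xy[1],
                "zone": zone, "depth_top": top, "depth_bottom": bottom,
                "tAs": expected * noise, "is_duplicate": False,
                "duplicate_of": pd.NA,
            })
    df = pd.DataFrame(rows)
    if duplicate_every:
        df = _append_duplicates(df, duplicate_every, pop.duplicate_cv, rng_dup)
    return df[SOIL_COLUMNS]


def generate_water_samples(seed: int = 0, n_replicates: int = 3) -> pd.DataFrame:
    """Irrigation-water table: channel and faucet locations in replicate.

    Arsenic is drawn per replicate around 6.7 mg/L (channel, broad) and
    6.6 mg/L (faucet, tight); physicochemistry (alkaline, oxidising,
    brackish water) is jittered mildly around typical values.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    specs = {
        "channel": {"As": (6.7, 1.6), "T": 29.5, "pH": 8.33, "EC": 2567.0,
                    "TDS": 1283.0, "ORP": 434.3, "DO": 2.11, "alkalinity": 124.0},
        "faucet": {"As": (6.6, 0.2), "T": 31.2, "pH": 8.34, "EC": 2601.0,
                   "TDS": 1300.0, "ORP": 433.6, "DO": 1.05, "alkalinity": 103.0},
    }
    rows = []
    for location, spec in specs.items():
        mean, sd = spec["As"]
        for rep in range(1, n_replicates + 1):
            as_val = -1.0
            while as_val <= 0:
                as_val = rng.normal(mean, sd)
            rows.append({
                "location": location, "replicate": rep, "As": as_val,
                **{k: spec[k] * (1.0 + 0.01 * rng.standard_normal())
                   for k in ("T", "EC", "TDS", "ORP", "DO", "alkalinity")},
                "pH": spec["pH"] + 0.05 * rng.standard_normal(),
            })
    return pd.DataFrame(rows)[WATER_COLUMNS]


def generate_survey(spec: SurveySpec, seed: int = 0) -> pd.DataFrame:
    """Questionnaire table of ``spec.n`` respondents.

    Visits per year are a three-part mixture (occasional 3-30, weekly
    regulars centred on 52, intensive 60-80) rounded to whole visits;
    membership duration is ``lo + (hi-lo) * Beta(a, b)`` (right-skewed,
    bounded).  All draws respect the configured ranges.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(6)[5])
    n = spec.n

    categories = list(spec.clothing_probs)
    clothing = rng.choice(categories, size=n, p=[spec.clothing_probs[c] for c in categories])
    ev_vals = np.array(sorted(spec.ev_probs))
    ev = rng.choice(ev_vals, size=n, p=[spec.ev_probs[v] for v in ev_vals])

    lo, hi = spec.ef_range
    if spec.ef_point is not None:
        ef = np.full(n, float(spec.ef_point))
    else:
        component = rng.choice(3, size=n, p=[0.35, 0.55, 0.10])
        ef = np.empty(n)
        occ = component == 0
        ef[occ] = rng.integers(int(lo), 31, size=int(occ.sum()))
        weekly = component == 1
        ef[weekly] = np.clip(np.round(rng.normal(52.0, 6.0, size=int(weekly.sum()))), 31, 60)
        heavy = component == 2
        ef[heavy] = rng.integers(61, int(hi) + 1, size=int(heavy.sum()))
        ef = np.clip(ef, lo, hi)

    dlo, dhi = spec.ed_range
    if spec.ed_point is not None:
        ed = np.full(n, float(spec.ed_point))
    else:
        a, b = spec.ed_beta
        ed = dlo + (dhi - dlo) * rng.beta(a, b, size=n)

    return pd.DataFrame({
        "respondent_id": [f"R{i + 1:03d}" for i in range(n)],
        "clothing": clothing,
        "games_per_visit": ev.astype(int),
        "visits_per_year": ef,
        "years_member": ed,
    })
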