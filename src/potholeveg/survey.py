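"""Zoned quadrat vegetation surveys for pothole wetlands.

A pothole wetland is surveyed by concentric vegetation zone: both hydrologic
classes have an exterior low-prairie zone and a wet-meadow zone (the central
zone for temporarily ponded wetlands); seasonally ponded wetlands add a
central shallow-marsh zone.  Quadrat counts are fixed by class — 8 in low
prairie, 7 in wet meadow, 5 in shallow marsh, each 1 m² — with ring
placement in the interior/exterior zones and a spiral in the central zone.
Species seen between quadrats are recorded with a zone label and enter the
condition index exactly like quadrat species.

Presence/absence drives every metric; per-quadrat cover notes (standing
dead, open water, bare ground, litter, water depth) are stored and
round-tripped but feed no metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .traits import TraitTable, canonical_name, warn_unknown

__all__ = [
    "HydroClass",
    "Zone",
    "BETWEEN",
    "LEGAL_ZONES",
    "QUADRAT_COUNTS",
    "WetlandSite",
    "Observation",
    "LayoutPlan",
    "QuadratPlacement",
    "WetlandSurvey",
    "SurveyValidationError",
    "generate_layout",
    "read_surveys",
    "write_surveys",
    "wetland_species_list",
    "zone_species_list",
]

#: Sentinel quadrat id for species recorded between, not within, quadrats.
BETWEEN = "BETWEEN"


class HydroClass(str, Enum):
    TEMPORARILY_PONDED = "temporarily_ponded"
    SEASONALLY_PONDED = "seasonally_ponded"


class Zone(str, Enum):
    LOW_PRAIRIE = "low_prairie"
    WET_MEADOW = "wet_meadow"
    SHALLOW_MARSH = "shallow_marsh"


#: Zones legal for each hydrologic class, exterior to center.
LEGAL_ZONES: dict[HydroClass, tuple[Zone, ...]] = {
    HydroClass.TEMPORARILY_PONDED: (Zone.LOW_PRAIRIE, Zone.WET_MEADOW),
    HydroClass.SEASONALLY_PONDED: (
        Zone.LOW_PRAIRIE,
        Zone.WET_MEADOW,
        Zone.SHALLOW_MARSH,
    ),
}

#: Protocol quadrat counts per zone (1 m² quadrats).
QUADRAT_COUNTS: dict[Zone, int] = {
    Zone.LOW_PRAIRIE: 8,
    Zone.WET_MEADOW: 7,
    Zone.SHALLOW_MARSH: 5,
}


class SurveyValidationError(ValueError):
    pass


@dataclass(frozen=True)
class WetlandSite:
    site_id: str
    hydro_class: HydroClass
    grassland_type: str  # "native" | "reseeded"
    sample_year: int
    x: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        if self.grassland_type not in ("native", "reseeded"):
            raise SurveyValidationError(
                f"{self.site_id}: grassland_type must be native|reseeded, "
                f"got {self.grassland_type!r}"
            )

    @property
    def zones(self) -> tuple[Zone, ...]:
        return LEGAL_ZONES[self.hydro_class]


@dataclass(frozen=True)
class Observation:
    """One species occurrence in one zone, in a quadrat or between quadrats."""

    species: str
    zone: Zone
    quadrat_id: Union[int, str]  # integer id or BETWEEN
    pct_standing_dead: Optional[float] = None
    pct_open_water: Optional[float] = None
    pct_bare_ground: Optional[float] = None
    litter_cm: Optional[float] = None
    water_depth_cm: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", canonical_name(self.species))
        for attr in ("pct_standing_dead", "pct_open_water", "pct_bare_ground"):
            v = getattr(self, attr)
            if v is not None and not (0.0 <= v <= 100.0):
                raise SurveyValidationError(f"{attr}={v} outside [0, 100]")

    @property
    def is_between(self) -> bool:
        return self.quadrat_id == BETWEEN


@dataclass(frozen=True)
class QuadratPlacement:
    quadrat_id: int
    zone: Zone
    x: float
    y: float
    substrate: str = "emergent"  # "emergent" | "open_water"


@dataclass
class LayoutPlan:
    """Planned quadrat placements for one wetland.

    ``central_arrangement`` tags how the central zone was laid out:
    ``"spiral"`` (no open water) or ``"proportional-split"`` (quadrats split
    between open-water and emergent placements by largest-remainder
    rounding).
    """

    hydro_class: HydroClass
    placements: list[QuadratPlacement]
    central_arrangement: str = "spiral"
    quadrat_area_m2: float = 1.0

    @property
    def counts(self) -> dict[Zone, int]:
        out: dict[Zone, int] = {}
        for p in self.placements:
            out[p.zone] = out.get(p.zone, 0) + 1
        return out

    @property
    def quadrat_ids(self) -> set[int]:
        return {p.quadrat_id for p in self.placements}

    def central_split(self) -> dict[str, int]:
        """Open-water vs emergent counts in the central zone."""
        central = LEGAL_ZONES[self.hydro_class][-1]
        out = {"open_water": 0, "emergent": 0}
        for p in self.placements:
            if p.zone is central:
                out[p.substrate] += 1
        return out


def largest_remainder_split(total: int, fractions: Sequence[float]) -> list[int]:
    """Apportion ``total`` among categories by largest-remainder rounding."""
    quotas = [total * f for f in fractions]
    base = [math.floor(q) for q in quotas]
    short = total - sum(base)
    order = sorted(
        range(len(quotas)), key=lambda i: (quotas[i] - base[i], -i), reverse=True
    )
    for i in order[:short]:
        base[i] += 1
    return base


def generate_layout(
    hydro_class: HydroClass,
    zone_radii: Sequence[float],
    open_water_fraction: float = 0.0,
    seed: int = 0,
) -> LayoutPlan:
    """Generate the protocol quadrat layout on concentric circular zones.

    ``zone_radii`` are the outer radii of the zones from center outward and
    must be strictly increasing (e.g. seasonal ``[10, 20, 30]`` puts shallow
    marsh inside radius 10, wet meadow in the 10-20 band, low prairie in the
    20-30 band).  Interior/exterior zones get quadrats evenly spaced in angle
    on the band's mid-radius ring, starting at a seeded random angle; the
    central zone gets an Archimedean spiral with centers at equal arc-length
    steps.  When ``open_water_fraction`` > 0 on a seasonally ponded wetland,
    the five central quadrats are split between open-water and emergent
    placements proportionally by largest remainder.
    """
    zones = LEGAL_ZONES[hydro_class]
    if len(zone_radii) != len(zones):
        raise ValueError(
            f"{hydro_class.value} needs {len(zones)} radii, got {len(zone_radii)}"
        )
    radii = list(zone_radii)
    if not all(radii[i] < radii[i + 1] for i in range(len(radii) - 1)):
        raise ValueError(f"zone radii must be strictly increasing: {radii}")
    if not 0.0 <= open_water_fraction <= 1.0:
        raise ValueError(f"open_water_fraction {open_water_fraction} outside [0, 1]")

    rng = np.random.default_rng(seed)
    # zones tuple is exterior→center; radii are center→outward
    bands = list(zip(zones, reversed(range(len(zones)))))
    placements: list[QuadratPlacement] = []
    qid = 1
    central = zones[-1]
    for zone, idx in bands:
        n = QUADRAT_COUNTS[zone]
        outer = radii[idx]
        inner = radii[idx - 1] if idx > 0 else 0.0
        if zone is central:
            # Archimedean spiral r = b*theta from center to the zone edge,
            # quadrat centers at equal arc-length steps.
            theta_max = 3.0 * math.pi
            b = outer / theta_max
            total_len = 0.5 * b * theta_max**2  # arc length ≈ ∫ b·θ dθ
            steps = [(k + 0.5) * total_len / n for k in range(n)]
            phase = rng.uniform(0, 2 * math.pi)
            for s in steps:
                theta = math.sqrt(2 * s / b)
                r = b * theta
                placements.append(
                    QuadratPlacement(
                        qid, zone, r * math.cos(theta + phase),
                        r * math.sin(theta + phase),
                    )
                )
                qid += 1
        else:
            mid = 0.5 * (inner + outer)
            start = rng.uniform(0, 2 * math.pi)
            for k in range(n):
                ang = start + 2 * math.pi * k / n
                placements.append(
                    QuadratPlacement(qid, zone, mid * math.cos(ang), mid * math.sin(ang))
                )
                qid += 1

    arrangement = "spiral"
    if (
        hydro_class is HydroClass.SEASONALLY_PONDED
        and open_water_fraction > 0.0
    ):
        n_central = QUADRAT_COUNTS[central]
        n_open, n_emergent = largest_remainder_split(
            n_central, [open_water_fraction, 1.0 - open_water_fraction]
        )
        new = []
        assigned = 0
        for p in placements:
            if p.zone is central:
                sub = "open_water" if assigned < n_open else "emergent"
                assigned += 1
                new.append(QuadratPlacement(p.quadrat_id, p.zone, p.x, p.y, sub))
            else:
                new.append(p)
        placements = new
        arrangement = "proportional-split"
    return LayoutPlan(hydro_class, placements, central_arrangement=arrangement)


@dataclass
class WetlandSurvey:
    site: WetlandSite
    observations: list[Observation] = field(default_factory=list)
    layout: Optional[LayoutPlan] = None

    def __post_init__(self) -> None:
        if self.layout is None:
            self.layout = generate_layout(
                self.site.hydro_class, _default_radii(self.site.hydro_class)
            )
        self.validate()

    def validate(self) -> None:
        legal = set(self.site.zones)
        ids = self.layout.quadrat_ids
        for obs in self.observations:
            if obs.zone not in legal:
                raise SurveyValidationError(
                    f"{self.site.site_id}: zone {obs.zone.value} illegal for "
                    f"{self.site.hydro_class.value}"
                )
            if not obs.is_between and obs.quadrat_id not in ids:
                raise SurveyValidationError(
                    f"{self.site.site_id}: quadrat {obs.quadrat_id} not in layout"
                )


def _default_radii(hydro_class: HydroClass) -> list[float]:
    return [10.0, 20.0, 30.0][: len(LEGAL_ZONES[hydro_class])]


def wetland_species_list(survey: WetlandSurvey) -> set[str]:
    """All species identified at the wetland, within and between quadrats."""
    return {obs.species for obs in survey.observations}


def zone_species_list(survey: WetlandSurvey, zone: Zone) -> set[str]:
    """Species attributed to one zone (between-quadrat records included)."""
    if zone not in survey.site.zones:
        raise SurveyValidationError(
            f"zone {zone.value} illegal for {survey.site.hydro_class.value}"
        )
    return {obs.species for obs in survey.observations if obs.zone is zone}


SURVEY_COLUMNS = [
    "site_id", "hydro_class", "grassland_type", "sample_year", "zone",
    "quadrat_id", "species", "pct_standing_dead", "pct_open_water",
    "pct_bare_ground", "litter_cm", "water_depth_cm",
]


def _opt_float(v: str) -> Optional[float]:
    v = str(v).strip()
    return None if v == "" else float(v)


def read_surveys(
    path: Union[str, Path], traits: Optional[TraitTable] = None
) -> list[WetlandSurvey]:
    """Read surveys from the delimited schema; one survey per site_id.

    Zone legality is enforced per hydrologic class; species missing from
    ``traits`` (when given) pass through with a warning per the
    unknown-species policy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"{path}: missing columns {missing}")
    surveys: list[WetlandSurvey] = []
    for site_id, grp in df.groupby("site_id", sort=False):
        head = grp.iloc[0]
        try:
            site = WetlandSite(
                site_id=str(site_id),
                hydro_class=HydroClass(head["hydro_class"].strip().lower()),
                grassland_type=head["grassland_type"].strip().lower(),
                sample_year=int(head["sample_year"]),
            )
        except ValueError as exc:
            raise SurveyValidationError(f"{path}, site {site_id}: {exc}") from exc
        obs = []
        for i, row in grp.iterrows():
            qid_raw = str(row["quadrat_id"]).strip()
            qid: Union[int, str]
            qid = BETWEEN if qid_raw in ("", BETWEEN) else int(qid_raw)
            try:
                obs.append(
                    Observation(
                        species=row["species"],
                        zone=Zone(row["zone"].strip().lower()),
                        quadrat_id=qid,
                        pct_standing_dead=_opt_float(row["pct_standing_dead"]),
                        pct_open_water=_opt_float(row["pct_open_water"]),
                        pct_bare_ground=_opt_float(row["pct_bare_ground"]),
                        litter_cm=_opt_float(row["litter_cm"]),
                        water_depth_cm=_opt_float(row["water_depth_cm"]),
                    )
                )
            except ValueError as exc:
                raise SurveyValidationError(f"{path}, row {i + 2}: {exc}") from exc
        try:
            survey = WetlandSurvey(site=site, observations=obs)
        except SurveyValidationError as exc:
            raise SurveyValidationError(f"{path}: {exc}") from exc
        if traits is not None:
            warn_unknown(wetland_species_list(survey), traits)
        surveys.append(survey)
    return surveys


def write_surveys(surveys: Sequence[WetlandSurvey], path: Union[str, Path]) -> None:
    """Write surveys in the canonical delimited schema (round-trips)."""
    rows = []
    for sv in surveys:
        for obs in sv.observations:
            rows.append(
                {
                    "site_id": sv.site.site_id,
                    "hydro_class": sv.site.hydro_class.value,
                    "grassland_type": sv.site.grassland_type,
                    "sample_year": sv.site.sample_year,
                    "zone": obs.zone.value,
                    "quadrat_id": obs.quadrat_id,
                    "species": obs.species,
                    "pct_standing_dead": _fmt(obs.pct_standing_dead),
                    "pct_open_water": _fmt(obs.pct_open_water),
                    "pct_bare_ground": _fmt(obs.pct_bare_ground),
                    "litter_cm": _fmt(obs.litter_cm),
                    "water_depth_cm": _fmt(obs.water_depth_cm),
                }
            )
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(path, index=False)


def _fmt(v: Optional[float]) -> str:
    return "" if v is None else repr(float(v))
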