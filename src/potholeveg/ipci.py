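"""The Index of Plant Community Integrity (IPCI).

Nine presence/absence plant-community metrics summarize a pothole wetland's
species richness, composition, disturbance tolerance and floristic quality:

m1  species richness of native perennials
m2  number of genera of native perennials
m3  number of native grass and grass-like species
m4  percentage of annual, biennial, and introduced species
m5  number of native perennial species in the wet-meadow zone
m6  number of species with C-value >= 5
m7  number of species in the wet-meadow zone with C-value >= 4
m8  average C-value over scored natives
m9  Floristic Quality Index, FQI = mean C x sqrt(number of native species)

Each metric maps through class-specific value ranges to an ordinal score in
{0, 4, 7, 11}; the nine scores sum to a 0-99 total which is mapped to a
condition category (Very poor ... Very good; the temporarily ponded class
uses only Poor/Fair/Good).

Rounding policy: metric values are rounded half-away-from-zero to the
printed precision of the scoring table (integers; one decimal for m4; two
decimals for m8 and m9) before range lookup, so the printed ranges tile the
achievable domain with no gaps.  The FQI uses the unrounded mean C
internally and rounds only the final product.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from math import sqrt
from typing import Mapping, Optional, Sequence, Union

import yaml

from .survey import WetlandSurvey, Zone, wetland_species_list, zone_species_list
from .traits import TraitTable

__all__ = [
    "METRIC_IDS",
    "SCORE_SET",
    "MetricVector",
    "ScoringTable",
    "CategoryTable",
    "IPCIResult",
    "round_half_up",
    "load_scoring_config",
    "default_scoring_table",
    "default_category_table",
    "compute_metrics",
    "fqi",
    "score_metric",
    "total_score",
    "categorize",
    "assess",
]

METRIC_IDS = (
    "richness_native_perennial",
    "genera_native_perennial",
    "native_grass_grasslike",
    "pct_annual_biennial_introduced",
    "wetmeadow_native_perennial",
    "count_c_ge_5",
    "wetmeadow_count_c_ge_4",
    "avg_c",
    "fqi",
)

SCORE_SET = frozenset({0, 4, 7, 11})

#: decimal places at which each metric is printed and scored
METRIC_PRECISION = {
    "richness_native_perennial": 0,
    "genera_native_perennial": 0,
    "native_grass_grasslike": 0,
    "pct_annual_biennial_introduced": 1,
    "wetmeadow_native_perennial": 0,
    "count_c_ge_5": 0,
    "wetmeadow_count_c_ge_4": 0,
    "avg_c": 2,
    "fqi": 2,
}


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricVector:
    richness_native_perennial: int
    genera_native_perennial: int
    native_grass_grasslike: int
    pct_annual_biennial_introduced: float
    wetmeadow_native_perennial: int
    count_c_ge_5: int
    wetmeadow_count_c_ge_4: int
    avg_c: float
    fqi: float

    def __post_init__(self) -> None:
        for mid in METRIC_IDS:
            v = getattr(self, mid)
            if v < 0:
                raise ValueError(f"{mid} = {v} < 0")
        if not 0.0 <= self.pct_annual_biennial_introduced <= 100.0:
            raise ValueError("percentage metric outside [0, 100]")
        if self.avg_c > 10.0:
            raise ValueError("average C-value above 10")
        if self.wetmeadow_native_perennial > self.richness_native_perennial:
            raise ValueError("wet-meadow native perennials exceed wetland total")

    def as_dict(self) -> dict[str, Union[int, float]]:
        return {mid: getattr(self, mid) for mid in METRIC_IDS}


class ScoringTableError(ValueError):
    """A value fell in no range — indicates a mis-encoded scoring table."""


def _to_units(value: float, precision: int) -> int:
    """Scale to integer units at the table's precision (exact comparisons)."""
    return int(round(value * 10**precision))


@dataclass(frozen=True)
class _Range:
    score: int
    lo: int  # integer units at metric precision
    hi: Optional[int]  # None = unbounded above

    def contains(self, units: int) -> bool:
        return units >= self.lo and (self.hi is None or units <= self.hi)


class ScoringTable:
    """Metric value ranges -> ordinal score {0,4,7,11}, per hydrologic class."""

    def __init__(self, ranges: Mapping[str, Mapping[str, Sequence[_Range]]]):
        self._ranges = ranges

    def score(self, metric_id: str, value: float, hydro_class: str) -> int:
        if metric_id not in METRIC_PRECISION:
            raise KeyError(f"unknown metric {metric_id!r}")
        prec = METRIC_PRECISION[metric_id]
        units = _to_units(round_half_up(value, prec), prec)
        for rng in self._ranges[hydro_class][metric_id]:
            if rng.contains(units):
                return rng.score
        raise ScoringTableError(
            f"{metric_id}={value} ({hydro_class}) falls in no scoring range"
        )

    def ranges(self, hydro_class: str, metric_id: str) -> list[tuple[int, float, Optional[float]]]:
        """(score, lo, hi) triples on the printed scale, for inspection."""
        prec = METRIC_PRECISION[metric_id]
        scale = 10**prec
        return [
            (r.score, r.lo / scale, None if r.hi is None else r.hi / scale)
            for r in self._ranges[hydro_class][metric_id]
        ]


class CategoryTable:
    """Total-score ranges -> condition category, per hydrologic class."""

    def __init__(self, ranges: Mapping[str, Sequence[tuple[str, int, int]]]):
        self._ranges = {k: list(v) for k, v in ranges.items()}

    def categorize(self, total: int, hydro_class: str) -> str:
        if not 0 <= total <= 99:
            raise ValueError(f"total {total} outside [0, 99]")
        for cat, lo, hi in self._ranges[hydro_class]:
            if lo <= total <= hi:
                return cat
        raise ScoringTableError(f"total {total} ({hydro_class}) in no category")

    def categories(self, hydro_class: str) -> list[str]:
        return [cat for cat, _, _ in self._ranges[hydro_class]]

    def all_categories(self) -> list[str]:
        """Category labels in worst-to-best order across classes."""
        seen: list[str] = []
        for cls in self._ranges:
            for cat in self.categories(cls):
                if cat not in seen:
                    seen.append(cat)
        order = ["Very poor", "Poor", "Fair", "Good", "Very good"]
        return [c for c in order if c in seen]


def load_scoring_config(path=None) -> tuple[ScoringTable, CategoryTable]:
    """Load the scoring/category configuration (packaged YAML by default)."""
    if path is None:
        text = (
            resources.files("potholeveg").joinpath("data/ipci_scoring.yaml").read_text()
        )
    else:
        text = open(path).read()
    cfg = yaml.safe_load(text)
    ranges: dict[str, dict[str, list[_Range]]] = {}
    for cls, metrics in cfg["scoring"].items():
        ranges[cls] = {}
        for mid, rows in metrics.items():
            prec = METRIC_PRECISION[mid]
            rs = [
                _Range(
                    score=int(r["score"]),
                    lo=_to_units(float(r["lo"]), prec),
                    hi=None if r["hi"] is None else _to_units(float(r["hi"]), prec),
                )
                for r in rows
            ]
            if {r.score for r in rs} != SCORE_SET:
                raise ScoringTableError(f"{cls}/{mid}: scores must be {{0,4,7,11}}")
            ranges[cls][mid] = rs
    cats = {
        cls: [(str(r["category"]), int(r["lo"]), int(r["hi"])) for r in rows]
        for cls, rows in cfg["categories"].items()
    }
    return ScoringTable(ranges), CategoryTable(cats)


_DEFAULTS: Optional[tuple[ScoringTable, CategoryTable]] = None


def _defaults() -> tuple[ScoringTable, CategoryTable]:
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = load_scoring_config()
    return _DEFAULTS


def default_scoring_table() -> ScoringTable:
    return _defaults()[0]


def default_category_table() -> CategoryTable:
    return _defaults()[1]


def fqi(mean_c: float, n_native: int) -> float:
    """Floristic Quality Index: mean C-value times sqrt(native richness)."""
    if mean_c < 0 or n_native < 0:
        raise ValueError("FQI inputs must be non-negative")
    return mean_c * sqrt(n_native)


def compute_metrics(survey: WetlandSurvey, traits: TraitTable) -> MetricVector:
    """Compute the nine metric values from a wetland's species lists.

    All species identified at the wetland enter the total-richness
    denominator, including between-quadrat finds and species absent from the
    trait table; trait-dependent numerators count only species with known
    traits.  Natives lacking a C-value count toward richness metrics but are
    excluded from the average-C / C-threshold metrics.  An empty survey
    yields the all-zero vector.
    """
    species = wetland_species_list(survey)
    known = {s: traits.lookup(s) for s in species}
    typed = {s: t for s, t in known.items() if t is not None}

    native_perennial = {s for s, t in typed.items() if t.is_native_perennial}
    genera = {typed[s].genus for s in native_perennial}
    grasses = {s for s, t in typed.items() if t.is_native_grass_or_grasslike}
    abi = {s for s, t in typed.items() if t.is_annual_biennial_or_introduced}
    pct_abi = 100.0 * len(abi) / len(species) if species else 0.0

    if Zone.WET_MEADOW in survey.site.zones:
        wm = zone_species_list(survey, Zone.WET_MEADOW)
    else:  # pragma: no cover - both classes have a wet-meadow zone
        wm = set()
    wm_typed = {s: typed[s] for s in wm if s in typed}
    wm_native_perennial = {s for s, t in wm_typed.items() if t.is_native_perennial}

    scored = traits.natives_with_c(species)
    c_ge_5 = sum(1 for t in scored if t.c_value >= 5)
    wm_scored = traits.natives_with_c(wm)
    wm_c_ge_4 = sum(1 for t in wm_scored if t.c_value >= 4)

    mean_c = sum(t.c_value for t in scored) / len(scored) if scored else 0.0
    n_native = sum(1 for t in typed.values() if t.is_native)
    fqi_val = fqi(mean_c, n_native)

    return MetricVector(
        richness_native_perennial=len(native_perennial),
        genera_native_perennial=len(genera),
        native_grass_grasslike=len(grasses),
        pct_annual_biennial_introduced=round_half_up(pct_abi, 1),
        wetmeadow_native_perennial=len(wm_native_perennial),
        count_c_ge_5=c_ge_5,
        wetmeadow_count_c_ge_4=wm_c_ge_4,
        avg_c=round_half_up(mean_c, 2),
        fqi=round_half_up(fqi_val, 2),
    )


def score_metric(
    metric_id: str,
    value: float,
    hydro_class: Union[str, "HydroClass"],
    table: Optional[ScoringTable] = None,
) -> int:
    """Score one metric value through the class-specific range table."""
    table = table or default_scoring_table()
    cls = getattr(hydro_class, "value", hydro_class)
    return table.score(metric_id, value, cls)


def total_score(scores: Sequence[int]) -> int:
    """Sum the nine ordinal metric scores (0-99)."""
    if len(scores) != len(METRIC_IDS):
        raise ValueError(f"expected {len(METRIC_IDS)} scores, got {len(scores)}")
    bad = [s for s in scores if s not in SCORE_SET]
    if bad:
        raise ValueError(f"illegal metric scores {bad}; must be in {{0,4,7,11}}")
    return int(sum(scores))


def categorize(
    total: int,
    hydro_class: Union[str, "HydroClass"],
    table: Optional[CategoryTable] = None,
) -> str:
    """Map a total score to its condition category for the class."""
    table = table or default_category_table()
    cls = getattr(hydro_class, "value", hydro_class)
    return table.categorize(total, cls)


@dataclass(frozen=True)
class IPCIResult:
    site_id: str
    hydro_class: str
    grassland_type: str
    metrics: MetricVector
    scores: tuple[int, ...]
    total: int
    category: str

    def __post_init__(self) -> None:
        if self.total != sum(self.scores):
            raise ValueError("total does not equal the sum of metric scores")
        if not 0 <= self.total <= 99:
            raise ValueError(f"total {self.total} outside [0, 99]")


def assess(
    survey: WetlandSurvey,
    traits: TraitTable,
    scoring: Optional[ScoringTable] = None,
    categories: Optional[CategoryTable] = None,
) -> IPCIResult:
    """Full assessment of one wetland: metrics -> scores -> total -> category."""
    scoring = scoring or default_scoring_table()
    categories = categories or default_category_table()
    cls = survey.site.hydro_class.value
    mv = compute_metrics(survey, traits)
    if wetland_species_list(survey):
        scores = tuple(
            scoring.score(mid, getattr(mv, mid), cls) for mid in METRIC_IDS
        )
    else:
        # a wetland with no recorded plants has no community to credit: the
        # 0.0% short-lived/introduced share must not earn the top class
        scores = (0,) * len(METRIC_IDS)
    total = total_score(scores)
    return IPCIResult(
        site_id=survey.site.site_id,
        hydro_class=cls,
        grassland_type=survey.site.grassland_type,
        metrics=mv,
        scores=scores,
        total=total,
        category=categories.categorize(total, cls),
    )
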