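"""Composition of the full synthetic case study.

Reproduces the shape of a regional pothole condition assessment: a
candidate frame of wetland points stratified by hydrologic class and
sample year; a spatially balanced draw of 250 sites (200 primaries + 50
alternates, equal primaries per stratum); 24 field replacements of
primaries deemed unsampleable; synthetic vegetation surveys of the 200
active primaries along a disturbance gradient (48 sites in native
prairie, 152 in reseeded grassland, reseeded sites carrying a baseline
disturbance offset); assessment of every survey; and unweighted category
summaries.  Everything is deterministic given one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reporting
from .grts import SelectionDraw, SiteFrame, StratumConfig, grts_draw, replace_site
from .ipci import IPCIResult, assess
from .survey import HydroClass, WetlandSite, WetlandSurvey
from .synthetic import (
    GradientConfig,
    PoolSpecies,
    SpeciesPoolConfig,
    generate_site_frame,
    generate_species_pool,
)
from .synthetic import generate_survey
from .traits import TraitTable

__all__ = ["StudyConfig", "SyntheticStudy", "run_study"]

#: stratum label -> (hydrologic class, sample year)
STRATA = {
    "temporary_2020": (HydroClass.TEMPORARILY_PONDED, 2020),
    "temporary_2021": (HydroClass.TEMPORARILY_PONDED, 2021),
    "seasonal_2020": (HydroClass.SEASONALLY_PONDED, 2020),
    "seasonal_2021": (HydroClass.SEASONALLY_PONDED, 2021),
}

#: equal primaries per stratum; the 50 alternates split 13/13/12/12
SAMPLE_SIZES = {
    "temporary_2020": (50, 13),
    "temporary_2021": (50, 13),
    "seasonal_2020": (50, 12),
    "seasonal_2021": (50, 12),
}


@dataclass
class StudyConfig:
    seed: int = 0
    frame_size: int = 1000
    n_replacements: int = 24
    n_native_sites: int = 48  # of the 200 active primaries
    base_disturbance_max: float = 0.55
    pool: SpeciesPoolConfig | None = None
    gradient: GradientConfig | None = None


@dataclass
class SyntheticStudy:
    frame: SiteFrame
    draw: SelectionDraw
    traits: TraitTable
    pool: list[PoolSpecies]
    surveys: list[WetlandSurvey]
    results: list[IPCIResult]

    def summary(self, group_by=()) -> pd.DataFrame:
        return reporting.summarize(self.results, group_by)


def build_frame(cfg: StudyConfig) -> SiteFrame:
    props = {k: 1.0 / len(STRATA) for k in STRATA}
    return generate_site_frame(cfg.frame_size, props, seed=cfg.seed)


def select_sites(frame: SiteFrame, cfg: StudyConfig) -> SelectionDraw:
    return grts_draw(frame, StratumConfig(sizes=dict(SAMPLE_SIZES), seed=cfg.seed))


def apply_field_replacements(draw: SelectionDraw, cfg: StudyConfig) -> None:
    """Swap out primaries deemed unsampleable, evenly across strata."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    per_stratum, extra = divmod(cfg.n_replacements, len(SAMPLE_SIZES))
    for i, stratum in enumerate(sorted(SAMPLE_SIZES)):
        k = per_stratum + (1 if i < extra else 0)
        prims = [p for p in draw.primaries() if p.stratum == stratum]
        for idx in rng.choice(len(prims), size=k, replace=False):
            replace_site(draw, prims[int(idx)].site_id,
                         "misclassified or inaccessible")


def survey_active_sites(
    draw: SelectionDraw, cfg: StudyConfig
) -> tuple[TraitTable, list[PoolSpecies], list[WetlandSurvey]]:
    """Generate surveys for the active primaries along the gradient."""
    pool_cfg = cfg.pool or SpeciesPoolConfig(seed=cfg.seed)
    table, pool = generate_species_pool(pool_cfg)
    base_gradient = cfg.gradient or GradientConfig(seed=cfg.seed)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    active = sorted(draw.primaries(), key=lambda s: (s.stratum, s.order_rank))
    native_idx = set(
        rng.choice(len(active), size=cfg.n_native_sites, replace=False).tolist()
    )
    surveys = []
    for i, sel in enumerate(active):
        hydro, year = STRATA[sel.stratum]
        gtype = "native" if i in native_idx else "reseeded"
        d = float(rng.uniform(0.0, cfg.base_disturbance_max))
        if gtype == "reseeded":
            d = min(1.0, d + base_gradient.reseeded_d_offset)
        gcfg = GradientConfig(
            disturbance=d,
            richness_d0=base_gradient.richness_d0,
            richness_d1=base_gradient.richness_d1,
            c_decay=base_gradient.c_decay,
            invasive_gain=base_gradient.invasive_gain,
            occupancy_sigma=base_gradient.occupancy_sigma,
            zone_spread=base_gradient.zone_spread,
            between_prob=base_gradient.between_prob,
            quadrat_occupancy=base_gradient.quadrat_occupancy,
            reseeded_d_offset=base_gradient.reseeded_d_offset,
            seed=cfg.seed,
        )
        site = WetlandSite(sel.site_id, hydro, gtype, year)
        surveys.append(generate_survey(pool, site, gcfg))
    return table, pool, surveys


def run_study(cfg: StudyConfig) -> SyntheticStudy:
    """Run the whole pipeline: frame -> draw -> replacements -> surveys ->
    assessments.  Deterministic given ``cfg.seed``."""
    frame = build_frame(cfg)
    draw = select_sites(frame, cfg)
    apply_field_replacements(draw, cfg)
    table, pool, surveys = survey_active_sites(draw, cfg)
    results = [assess(sv, table) for sv in surveys]
    return SyntheticStudy(frame, draw, table, pool, surveys, results)
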