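"""Survey the selected wetlands (synthetically).

Generates the synthetic regional species pool (70 native perennials with
C-values, 15 short-lived natives, 25 introduced species including 8
invasive mimics) and a zoned quadrat survey for each of the 200 active
primary sites.  48 sites sit in native prairie; the rest are reseeded
grassland and carry a baseline disturbance offset, so reseeded communities
skew toward short-lived, introduced and invasive species.  Writes the
trait table and the survey records to results/.

Run:  python analysis/02_simulate_surveys.py [--seed 1]
(The seed must match 01_select_sites.py so surveys attach to the drawn
sites.)
"""

import argparse
from pathlib import Path

from potholeveg.study import StudyConfig, apply_field_replacements, build_frame, select_sites, survey_active_sites
from potholeveg.survey import wetland_species_list, write_surveys
from potholeveg.traits import write_trait_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    cfg = StudyConfig(seed=args.seed)
    draw = select_sites(build_frame(cfg), cfg)
    apply_field_replacements(draw, cfg)
    table, pool, surveys = survey_active_sites(draw, cfg)

    write_trait_table(table, RESULTS / "species_traits.csv")
    write_surveys(surveys, RESULTS / "surveys.csv")

    richness = [len(wetland_species_list(sv)) for sv in surveys]
    print(f"species pool: {len(table)} species")
    print(f"surveys: {len(surveys)} wetlands; per-wetland richness "
          f"{min(richness)}-{max(richness)} "
          f"(median {sorted(richness)[len(richness)//2]})")
    print(f"wrote {RESULTS/'species_traits.csv'}, {RESULTS/'surveys.csv'}")


if __name__ == "__main__":
    main()
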