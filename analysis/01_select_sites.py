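"""Select the study wetlands.

Builds a 1000-point candidate frame stratified by hydrologic class and
sample year, draws a spatially balanced stratified sample of 250 sites
(200 primaries + 50 alternates, equal primaries per stratum), and swaps
out 24 primaries deemed unsampleable for ordered alternates.  Writes the
frame and the final draw (with its replacement log) to results/.

Run:  python analysis/01_select_sites.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from potholeveg.grts import write_draw, write_frame
from potholeveg.study import StudyConfig, apply_field_replacements, build_frame, select_sites

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    cfg = StudyConfig(seed=args.seed)
    frame = build_frame(cfg)
    draw = select_sites(frame, cfg)
    apply_field_replacements(draw, cfg)

    write_frame(frame, RESULTS / "site_frame.csv")
    write_draw(draw, RESULTS / "site_selection.csv")
    pd.DataFrame(draw.replacement_log,
                 columns=["replaced", "replacement", "reason"]).to_csv(
        RESULTS / "replacement_log.csv", index=False)

    print(f"frame: {len(frame.points)} candidate wetlands over "
          f"{len(frame.strata())} strata")
    print(f"draw: {len(draw.sites)} sites "
          f"({len(draw.primaries())} active primaries, "
          f"{len(draw.alternates())} alternates remaining)")
    print(f"replacements: {len(draw.replacement_log)} primaries swapped "
          f"for alternates")
    print(f"wrote {RESULTS/'site_frame.csv'}, {RESULTS/'site_selection.csv'}, "
          f"{RESULTS/'replacement_log.csv'}")


if __name__ == "__main__":
    main()
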