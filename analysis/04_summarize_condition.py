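"""Summarize condition by category, grassland type and hydrologic class.

Reads the per-wetland assessments from 03_assess_condition.py and writes
the unweighted summaries: percent of wetlands per condition category
(overall, by grassland type, by hydrologic class) and mean ± SD of index
totals per group.  No confidence intervals attach to these category
counts by design.

Run:  python analysis/04_summarize_condition.py
"""

from pathlib import Path

import pandas as pd

from potholeveg.reporting import format_summary, summarize_frame

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = pd.read_csv(RESULTS / "ipci_results.csv")
    specs = {
        "summary_overall.csv": (),
        "summary_by_grassland_type.csv": ("grassland_type",),
        "summary_by_hydro_class.csv": ("hydro_class",),
    }
    for fname, group_by in specs.items():
        s = summarize_frame(df, list(group_by))
        s.to_csv(RESULTS / fname, index=False)
        label = " x ".join(group_by) if group_by else "overall"
        print(f"--- {label} ---")
        print(format_summary(s))
        print()
    print(f"wrote {', '.join(str(RESULTS / f) for f in specs)}")


if __name__ == "__main__":
    main()
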