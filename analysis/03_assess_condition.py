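"""Assess wetland condition with the nine-metric index.

Reads the trait table and surveys written by 02_simulate_surveys.py,
computes the nine metric values, ordinal scores, 0-99 total and condition
category for every wetland, and writes the per-wetland assessment table.

Run:  python analysis/03_assess_condition.py
"""

from pathlib import Path

from potholeveg.ipci import assess
from potholeveg.reporting import write_results
from potholeveg.survey import read_surveys
from potholeveg.traits import load_trait_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = load_trait_table(RESULTS / "species_traits.csv")
    surveys = read_surveys(RESULTS / "surveys.csv", table)
    results = [assess(sv, table) for sv in surveys]
    write_results(results, RESULTS / "ipci_results.csv")

    cats = {}
    for r in results:
        cats[r.category] = cats.get(r.category, 0) + 1
    print(f"assessed {len(results)} wetlands")
    for cat in ("Very poor", "Poor", "Fair", "Good", "Very good"):
        if cat in cats:
            print(f"  {cat:>10}: {cats[cat]}")
    print(f"wrote {RESULTS/'ipci_results.csv'}")


if __name__ == "__main__":
    main()
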