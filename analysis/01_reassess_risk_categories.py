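#!/usr/bin/env python
"""Re-assess every taxon's extinction-risk category under climate change.

Loads the bundled 52-taxon factor table, applies the 4-arrow transition rule,
and writes the per-taxon results plus the cohort summaries (category-change
histogram, per-factor response counts, revised-category distribution) to
results/.
"""

from pathlib import Path

import pandas as pd

from shorebird_risk.assessment import (
    assess_all,
    category_distribution,
    delta_histogram,
    factor_response_summary,
)
from shorebird_risk.species_table import load_packaged_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    profiles = load_packaged_table()
    results = assess_all(profiles, threshold=4)

    frame = pd.DataFrame(
        {
            "taxon": [r.display_name for r in results],
            "current_category": [int(r.current_category) for r in results],
            "net_arrows": [r.net_arrows for r in results],
            "total_score": [r.total_score for r in results],
            "revised_category": [int(r.revised_category) for r in results],
            "delta": [r.delta for r in results],
        }
    )
    frame.to_csv(OUT / "reassessment.csv", index=False, lineterminator="\n")

    hist = delta_histogram(results)
    increased = sum(v for d, v in hist.items() if d > 0)
    print(f"Assessed {len(results)} taxa at the 4-arrow criterion.")
    print(f"  {increased} taxa ({increased / len(results):.0%}) increase extinction risk:")
    for d, v in hist.items():
        label = "unchanged" if d == 0 else f"up {d} level{'s' if abs(d) > 1 else ''}"
        print(f"    delta {d:+d} ({label}): {v} taxa")

    revised = category_distribution(r.revised_category for r in results)
    high = revised.at_or_above(4)
    critical = revised.counts[6]
    print(f"  {high} taxa now at High Concern or above; {critical} in the new Critical category.")

    summary = factor_response_summary(profiles)
    rows = []
    for kind, resp in summary.items():
        rows.append(
            {
                "factor": kind.column,
                "increased": resp.increased,
                "maximal": resp.maximal,
                "none_or_positive": resp.none_or_positive,
            }
        )
    pd.DataFrame(rows).to_csv(OUT / "factor_summary.csv", index=False, lineterminator="\n")
    print("Per-factor counts of taxa with increased risk "
          "(breeding/wintering/migration habitat): "
          + "/".join(str(summary[k].increased) for k in list(summary)[:3]))


if __name__ == "__main__":
    main()
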