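#!/usr/bin/env python
"""Concordance between this framework and the external State of the Birds scores.

The bundled table carries each taxon's independent State of the Birds 2010
climate-vulnerability score (0-5).  This driver computes the squared Pearson
correlation between that external score and the framework's outputs under
the two natural pairings (net arrows; realized category change), since the
published figure (r² = 0.27) does not state which pairing it used.
"""

import json
from pathlib import Path

from shorebird_risk.assessment import assess_all, concordance_r2, net_arrows
from shorebird_risk.species_table import load_packaged_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    profiles = load_packaged_table()
    external = [p.external_score for p in profiles]
    results = assess_all(profiles, 4)

    r2 = {
        "external_vs_net_arrows": round(concordance_r2(external, [net_arrows(p) for p in profiles]), 4),
        "external_vs_delta": round(concordance_r2(external, [r.delta for r in results]), 4),
    }
    (OUT / "external_concordance.json").write_text(json.dumps(r2, indent=2) + "\n")
    print("Squared Pearson correlation with State of the Birds scores:")
    for pairing, value in r2.items():
        print(f"  {pairing}: {value}")
    print("Agreement is loose under either pairing: the two frameworks rank "
          "climate vulnerability similarly in broad strokes but not per taxon.")


if __name__ == "__main__":
    main()
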