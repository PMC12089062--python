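#!/usr/bin/env python
"""Range-wide citizen-science comparison of morph-specific road mortality.

Builds the 2x2 morph x dead/alive table from the published classification
totals (12,705 melanic with 174 dead; 96,025 gray with 1,581 dead), tests
association with the Yates-corrected chi-square, sizes the effect with
Cramer's V, and intervals each morph's DOR proportion with the
Agresti-Coull method.  Writes results/citizen/citizen_stats.json.
"""

import json
import sys
from pathlib import Path

import roadcline as rc

OUT = Path("results/citizen")


def main() -> None:
    table = rc.make_citizen_table(12_705, 174, 96_025, 1_581)
    stat, p = rc.yates_chi2_test(table)
    e = rc.expected_counts(table)
    ci_mel = rc.agresti_coull_interval(174, 12_705)
    ci_gray = rc.agresti_coull_interval(1_581, 96_025)

    print(f"N = {table.n:,} squirrel photographs")
    print(f"melanic DOR: observed 174, expected {e[0, 0]:.1f} (underrepresented)")
    print(f"gray DOR:    observed 1581, expected {e[1, 0]:.1f} (overrepresented)")
    print(f"chi2(1, Yates) = {stat:.2f}, p = {p:.3f}, Cramer's V = "
          f"{rc.cramers_v(table):.2f}")
    print(f"DOR proportion (95% Agresti-Coull): melanic {174 / 12_705:.4f} "
          f"({ci_mel[0]:.4f}, {ci_mel[1]:.4f}); gray {1_581 / 96_025:.4f} "
          f"({ci_gray[0]:.4f}, {ci_gray[1]:.4f})")

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "citizen_stats.json").write_text(json.dumps({
        "n": table.n,
        "chi2_yates": stat,
        "p_value": p,
        "cramers_v": rc.cramers_v(table),
        "expected": e.tolist(),
        "observed": table.cells.tolist(),
        "dor_proportion_ci": {"melanic": ci_mel, "gray": ci_gray},
    }, indent=2))
    print(f"wrote {OUT / 'citizen_stats.json'}")


if __name__ == "__main__":
    sys.exit(main())
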