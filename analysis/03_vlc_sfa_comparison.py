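#!/usr/bin/env python
"""Compare VLC-SFA profiles of control vs transgenic yeast.

Reads the simulated replicate peak tables, expresses every saturate at
or above C24 as an area percentage of the qualifying saturate pool, and
runs the one-way ANOVA + Tukey HSD comparison with compact letters per
fatty acid. The summary table (mean ± SE + letter per treatment) goes to
``results/sfa_comparison.tsv``; treatments sharing no letter for a
fatty acid differ significantly at alpha = 0.05.
"""

import argparse
from pathlib import Path

from vlcfa.conversion_stats import compare_groups, sfa_percentages
from vlcfa.fa_model import format_fa
from vlcfa.io_utils import read_peak_table, write_group_comparison

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--min-carbons", type=int, default=24)
    args = parser.parse_args()

    tables = read_peak_table(SIM / "sfa_peaks.csv")
    profiles = [sfa_percentages(t, min_carbons=args.min_carbons) for t in tables]
    comparison = compare_groups(profiles, alpha=args.alpha)

    out = OUT / "sfa_comparison.tsv"
    write_group_comparison(comparison, out,
                           config={"alpha": args.alpha,
                                   "min_carbons": args.min_carbons})
    print(f"wrote {out} (+ .json)\n")
    for fa, vc in comparison.variables.items():
        cells = ", ".join(
            f"{g}: {vc.means[g]:.2f}±{vc.sems[g]:.2f}{vc.letters[g]}"
            for g in vc.means
        )
        print(f"{format_fa(fa):>6}  {cells}")
    boosted = [
        format_fa(fa)
        for fa, vc in comparison.variables.items()
        if set(vc.letters["control"]).isdisjoint(vc.letters.get("elovl4a", ""))
    ]
    print(f"\nfatty acids where elovl4a differs from control: {', '.join(boosted)}")


if __name__ == "__main__":
    main()
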