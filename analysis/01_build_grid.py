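#!/usr/bin/env python
"""Enumerate the combined AE selection criteria observed across trial sources.

Five numerical thresholds (1, 2, 3, 5, 10 percent) crossed with three
participant-group scopes and three difference-between-groups rules give 45
combined criteria.  Writes results/criteria_grid.csv with one row per
criterion in canonical grid order.
"""

from pathlib import Path

import pandas as pd

from aeselect import observed_grid

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    grid = observed_grid()
    rows = [
        {
            "criterion": c.label,
            "threshold_pct": float(c.threshold * 100),
            "scope": str(c.scope),
            "diff_rule": c.diff.render(),
        }
        for c in grid
    ]
    OUT.mkdir(exist_ok=True)
    out = OUT / "criteria_grid.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"{len(rows)} combined selection criteria "
          f"({len(grid.thresholds)} thresholds x {len(grid.scopes)} scopes x "
          f"{len(grid.diffs)} difference rules) -> {out}")


if __name__ == "__main__":
    main()
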