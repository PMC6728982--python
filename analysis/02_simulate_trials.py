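#!/usr/bin/env python
"""Simulate a CSR corpus: eight placebo-controlled trials of one drug.

Each trial shares the same true AE incidence structure — 300 distinct AE
types with log-uniform background incidence spanning 0.05% to 20%, a tenth
of them elevated twofold in the active arm — and samples per-arm
participant counts independently.  Writes csv_long tables and the
ground-truth sidecar under results/simulated_trials/.
"""

import argparse
import json
from pathlib import Path

from aeselect import RateLaw, SyntheticConfig, simulate_trials, write_table

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated_trials"


def corpus_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_per_arm=(200, 200),
        n_terms=300,
        rate_law=RateLaw("log_uniform", 5e-4, 0.2),
        elevated_fraction=0.1,
        risk_ratio=2.0,
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--k", type=int, default=8)
    args = ap.parse_args()

    cfg = corpus_config()
    tables = simulate_trials(cfg, args.k, master_seed=args.seed)
    OUT.mkdir(parents=True, exist_ok=True)
    for t in tables:
        write_table(t, OUT / f"{t.trial_id}.csv")
    truth = tables[0].truth
    (OUT / "ground_truth.json").write_text(json.dumps(
        {
            "seed": args.seed,
            "terms": list(truth.terms),
            "elevated": [bool(e) for e in truth.elevated],
            "incidence": {
                name: [float(x) for x in truth.incidence[i]]
                for i, name in enumerate(cfg.arm_names)
            },
        },
        indent=1,
    ))
    sizes = [t.n_terms for t in tables]
    print(f"wrote {args.k} trials to {OUT}")
    print(f"stored AE types per trial: min {min(sizes)}, max {max(sizes)} "
          f"(of {cfg.n_terms} latent types; unobserved types are dropped)")


if __name__ == "__main__":
    main()
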