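#!/usr/bin/env python
"""Quantify how criterion-based selective reporting biases meta-analysis.

Two experiments over k=20 trials, 200 Monte-Carlo replicates each:

* a global-null drug (risk ratio 1 for every AE type) — any upward shift
  of the selective pooled log-RR is pure selection bias;
* a drug with a tenth of AE types truly elevated twofold — measures how
  many genuinely elevated (and how many rare) AE types survive censoring.

Writes results/bias_null.csv and results/bias_effect.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from aeselect import RateLaw, SyntheticConfig, bias_experiment, parse_criterion

OUT = Path(__file__).resolve().parents[1] / "results"

CRITERIA = [
    "thr=0%",
    "thr=1%",
    "thr=5%",
    "thr=10%",
    "thr=5%;scope=active;diff=higher",
    "thr=5%;scope=active;diff=ratio>=2",
]


def run(cfg: SyntheticConfig, seed: int, out: Path) -> pd.DataFrame:
    results = bias_experiment(cfg, 20, [parse_criterion(c) for c in CRITERIA], 200, seed)
    df = pd.DataFrame(
        {
            "criterion": r.criterion.label,
            "mean_selective_log_rr": r.mean_selective_log_rr,
            "mean_selective_minus_complete": r.mean_selective_minus_complete,
            "mean_bias_selective_vs_true": r.mean_bias_selective_vs_true,
            "frac_elevated_ever_reported": r.frac_elevated_ever_reported,
            "frac_terms_never_reported": r.frac_terms_never_reported,
        }
        for r in results
    )
    df.to_csv(out, index=False, float_format="%.4f")
    return df


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    base = dict(
        n_per_arm=(150, 150),
        n_terms=60,
        rate_law=RateLaw("log_uniform", 5e-4, 0.2),
    )
    null_cfg = SyntheticConfig(**base, elevated_fraction=0.0, risk_ratio=1.0)
    effect_cfg = SyntheticConfig(**base, elevated_fraction=0.1, risk_ratio=2.0)

    print("== global null (risk ratio 1 everywhere) ==")
    df = run(null_cfg, args.seed, OUT / "bias_null.csv")
    print(df.to_string(index=False))
    print("thr=0% censors nothing, so its selective-vs-complete discrepancy "
          "is exactly zero; difference-rule criteria condition on positive "
          "noise and push the selective pooled log-RR above zero.")

    print("\n== true effects (10% of AE types elevated, RR=2) ==")
    df = run(effect_cfg, args.seed + 1, OUT / "bias_effect.csv")
    print(df.to_string(index=False))
    print("raising the threshold hides a growing share of AE types "
          "(frac_terms_never_reported), including truly elevated ones.")


if __name__ == "__main__":
    main()
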