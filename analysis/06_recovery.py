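#!/usr/bin/env python
"""Parameter-recovery experiment for the fixed-links and latent-regression
models at the study's sample size.

Writes results/recovery.csv (true value, mean estimate, bias, empirical
SD, Monte-Carlo SE per parameter).
"""

import argparse
from pathlib import Path

from trpsem.models import recovery_experiment

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--reps", type=int, default=200)
    ap.add_argument("--n", type=int, default=273)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    tab = recovery_experiment(n_reps=args.reps, n=args.n, seed=args.seed,
                              include_latent_corr=True)
    args.out.mkdir(parents=True, exist_ok=True)
    tab.to_csv(args.out / "recovery.csv", index=False)
    print(f"Recovery over {args.reps} replicates at n = {args.n} "
          f"(non-convergence rate "
          f"{tab.attrs['nonconvergence_rate']:.1%}):")
    print(tab.round(5).to_string(index=False))
    if all(tab["abs_bias_within_2se"]):
        print("All parameters recovered without detectable bias "
              "(within 2 Monte-Carlo SEs).")


if __name__ == "__main__":
    main()
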