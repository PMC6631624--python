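#!/usr/bin/env python
"""Recover planted (D, tau) through the full pipeline in the developed-front regime.

Plants D = 300 um^2/h and tau = 6 h, images a wide wound (14 mm) for 60
population doublings so the Fisher-KPP fronts run at their asymptotic
speed for most of the record, then recovers both parameters through
render -> segment -> fit and the algebraic inversion D = tau v^2 / (4 ln2).
Within a short record (such as the 18 h protocol) the front is still
accelerating and the inversion yields an effective, regime-dependent D;
this driver demonstrates the regime where the inversion is exact.
Writes results/parameter_recovery.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from woundkinetics.validation import parameter_recovery_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/parameter_recovery.csv"))
    args = parser.parse_args()

    rec = parameter_recovery_experiment(seed=args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([rec]).to_csv(args.out, index=False)

    print(
        f"planted D = {rec['D_true']:.0f} um2/h -> recovered {rec['D_hat']:.1f} "
        f"({100 * rec['D_rel_error']:+.1f}%)"
    )
    print(
        f"planted tau = {rec['tau_true']:.1f} h -> recovered {rec['tau_hat']:.2f} "
        f"({100 * rec['tau_rel_error']:+.1f}%)"
    )
    print(f"alpha = {rec['alpha']:.5f} 1/h, b_hat = {rec['b_hat']:.0f} um, v_hat = {rec['v_hat']:.2f} um/h")


if __name__ == "__main__":
    main()
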