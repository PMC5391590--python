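#!/usr/bin/env python
"""Generate the default synthetic claims cohort.

Simulates the default population (50,000 women of childbearing age over
2007–2013 with an exponentially decaying postpartum PE hazard multiplier,
1 + 16 * exp(-t/25)) and writes the full claims table to scratch/ (it is
a few megabytes) plus a small summary to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from ppx import codes
from ppx.claims import write_claims
from ppx.config import SimulationConfig
from ppx.simulate import simulate_population

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    claims = simulate_population(cfg)

    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    write_claims(claims, scratch / "claims.csv")

    summary = pd.DataFrame([{
        "n_women": cfg.n_women,
        "n_stays": len(claims),
        "n_delivery_stays": int(claims["associated_dx"]
                                .str.contains(codes.DELIVERY_DX, regex=False)
                                .sum()),
        "n_pe_primary_stays": int(claims["primary_dx"]
                                  .isin(codes.DEFAULT_PE_DX).sum()),
        "n_negative_control_stays": int(claims["primary_dx"]
                                        .eq(codes.NEGATIVE_CONTROL_DX).sum()),
        "seed": args.seed,
    }])
    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "simulation_summary.csv", index=False,
                   lineterminator="\n")
    print(summary.to_string(index=False))
    print(f"\nclaims table written to {scratch / 'claims.csv'}")


if __name__ == "__main__":
    main()
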