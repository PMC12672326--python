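#!/usr/bin/env python
"""Probabilistic sensitivity analysis and acceptability curves.

Draws 1,000 joint parameter samples, reruns the full pipeline per draw, and
writes the draw table (results/psa_draws.csv) and the cost-effectiveness
acceptability curves (results/ceac.csv).
"""

import argparse
from pathlib import Path

from pcsk9cua import base_case, ceac, default_wtp_grid, prob_cost_effective, run_psa

OUT = Path(__file__).resolve().parents[1] / "results"
EVO = "Evolocumab 140 mg Q2W"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    params = base_case()
    psa = run_psa(params, n=args.n, seed=args.seed)
    OUT.mkdir(exist_ok=True)
    psa.to_frame().to_csv(OUT / "psa_draws.csv", index=False)
    curve = ceac(psa, default_wtp_grid(params))
    curve.to_frame().to_csv(OUT / "ceac.csv", index=False)

    wtp = params.settings.wtp_high
    p_ce = prob_cost_effective(psa, EVO, params.comparator.name, wtp)
    idx = int((curve.wtp_grid == wtp).nonzero()[0][0])
    print(f"{args.n} draws, seed {args.seed}")
    print(f"P({EVO} cost-effective vs statins at {wtp:,.0f}/QALY): "
          f"{100 * p_ce:.1f}%")
    print(f"CEAC at {wtp:,.0f}/QALY:")
    for s in psa.strategies:
        print(f"  {s:26s} {100 * curve.prob_cost_effective[s][idx]:6.1f}%")


if __name__ == "__main__":
    main()
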