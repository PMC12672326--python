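#!/usr/bin/env python
"""Value-based price-threshold analysis.

Solves, for each injectable regimen, the per-pen price at which its ICUR
versus statins alone equals the upper willingness-to-pay threshold
(3x per-capita GDP). Writes results/price_threshold.csv.
"""

from pathlib import Path

import pandas as pd

from pcsk9cua import base_case, price_threshold

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = base_case()
    wtp = params.settings.wtp_high
    rows = []
    for r in params.active_regimens:
        p_star = price_threshold(params, r.name, params.comparator.name, wtp)
        rows.append({
            "strategy": r.name,
            "current_price_per_pen": r.price_per_pen,
            "max_price_per_pen": p_star,
            "required_change_pct": 100.0 * (p_star - r.price_per_pen)
            / r.price_per_pen,
            "reduction_needed": p_star < r.price_per_pen,
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "price_threshold.csv", index=False)

    print(f"Per-pen price thresholds at WTP {wtp:,.0f}/QALY:")
    print(df.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
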