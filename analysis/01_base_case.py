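#!/usr/bin/env python
"""Base-case cost-utility analysis.

Runs the deterministic Markov cohort model for statins alone and the nine
PCSK9-inhibitor regimens, classifies dominance, and writes the headline
cost/QALY/ICUR table to results/base_case.csv.
"""

from pathlib import Path

from pcsk9cua import base_case, evaluate_all, frontier

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = base_case()
    res = frontier(evaluate_all(params), params.comparator.name)
    df = res.to_frame(params.comparator.name)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "base_case.csv", index=False)

    print(df.round(2).to_string(index=False))
    on_frontier = [s for s, st in res.status.items() if st == "frontier"]
    print(f"\nNon-dominated strategies: {on_frontier}")
    print("Every other regimen is dominated: it costs more and yields fewer "
          "QALYs than a frontier option.")


if __name__ == "__main__":
    main()
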