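#!/usr/bin/env python
"""Time-horizon scenario analysis.

Truncates the model at 5-30 years and tabulates how the ICUR of each
regimen versus statins alone falls as the preventive benefit accumulates.
Writes results/scenario_horizons.csv.
"""

from pathlib import Path

from pcsk9cua import base_case, scenario_horizons

OUT = Path(__file__).resolve().parents[1] / "results"
EVO = "Evolocumab 140 mg Q2W"


def main() -> None:
    params = base_case()
    df = scenario_horizons(params, [5, 10, 15, 20, 25, 30])
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "scenario_horizons.csv", index=False)

    evo = df[df.strategy == EVO]
    print(f"{EVO} vs statins alone by horizon:")
    print(evo[["horizon", "delta_cost", "delta_qaly",
               "icur_vs_reference"]].round(2).to_string(index=False))
    print("\nThe ICUR falls monotonically with the horizon: drug costs "
          "accrue from day one, while averted events and deaths pay off "
          "over decades.")


if __name__ == "__main__":
    main()
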