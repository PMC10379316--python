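#!/usr/bin/env python
"""Recompute the degradation summary statistics from the printed anchors.

SSP percent decreases, Ca2+-ATPase residual activity, SH percent decreases,
and the FFA warm/cold final ratios -- the numbers that summarize how much
faster quality is lost at warmer frozen temperatures.
"""

import json
from pathlib import Path

from carpfrost import (
    Indicator,
    anchor_table,
    carp_253K_fixture,
    percent_decrease,
    residual_fraction,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    anchors = anchor_table()
    fixture = carp_253K_fixture()
    out: dict[str, dict] = {}

    ssp = {f"{t:g}K": round(percent_decrease(anchors.get(Indicator.SSP, t).initial,
                                             anchors.get(Indicator.SSP, t).final), 2)
           for t in (261.0, 253.0, 245.0)}
    out["ssp_percent_decrease"] = ssp
    print(f"SSP decrease over 17 weeks: {ssp} (warmer = larger loss)")

    ca0 = anchors.get(Indicator.CA_ATPASE, 253.0).initial
    ca17 = fixture.value(253.0, 17.0, Indicator.CA_ATPASE)
    out["ca_atpase_residual_pct_253K"] = round(residual_fraction(ca0, ca17), 2)
    print(f"Ca2+-ATPase residual activity at 253 K: "
          f"{out['ca_atpase_residual_pct_253K']}% of the initial "
          f"{ca0} umol Pi/mg/min")

    sh = anchors.get(Indicator.SH, 253.0)
    out["sh_percent_decrease_253K"] = round(percent_decrease(sh.initial, sh.final), 2)
    print(f"SH decrease at 253 K: {out['sh_percent_decrease_253K']}% "
          f"({sh.initial} -> {sh.final} mol/10^5 g)")

    ffa261 = anchors.get(Indicator.FFA, 261.0).final
    ffa253 = anchors.get(Indicator.FFA, 253.0).final
    out["ffa_final_ratio_261_over_253"] = round(ffa261 / ffa253, 2)
    print(f"FFA week-17 ratio 261 K / 253 K: {out['ffa_final_ratio_261_over_253']} "
          f"({ffa261} vs {ffa253} g/100 g lipid)")

    path = RESULTS / "summary_statistics.json"
    path.write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
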