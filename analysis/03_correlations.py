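#!/usr/bin/env python
"""Pearson correlations between the five indicators.

Lipid indicators (TBARS, FFA) rise together while the protein-integrity
indicators (SSP, Ca2+-ATPase, SH) fall together, so the two blocks correlate
positively within themselves and negatively across. Computed on the published
253 K series alone and pooled over the hybrid three-temperature dataset.
"""

from pathlib import Path

from carpfrost import carp_253K_fixture, pearson_matrix
from carpfrost.pipeline import build_hybrid_dataset

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    fixture = pearson_matrix(carp_253K_fixture())
    fixture.r.round(3).to_csv(RESULTS / "correlations_253K.csv")
    print(f"253 K series only (n={fixture.n_rows} weeks):")
    print(fixture.r.round(2).to_string())
    print(f"  Ca2+-ATPase vs SH: r = {fixture.r.loc['CA_ATPASE', 'SH']:.2f}")

    pooled = pearson_matrix(build_hybrid_dataset(seed=1))
    pooled.r.round(3).to_csv(RESULTS / "correlations_pooled_seed1.csv")
    print(f"\npooled over three temperatures (n={pooled.n_rows} points, seed 1):")
    print(pooled.r.round(2).to_string())
    print(f"  TBARS vs FFA: r = {pooled.r.loc['TBARS', 'FFA']:.2f}; "
          f"Ca2+-ATPase vs SH: r = {pooled.r.loc['CA_ATPASE', 'SH']:.2f}")
    print(f"wrote {RESULTS / 'correlations_253K.csv'} and "
          f"{RESULTS / 'correlations_pooled_seed1.csv'}")


if __name__ == "__main__":
    main()
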