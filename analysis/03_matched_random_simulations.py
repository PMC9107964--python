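"""Matched-randomness test: can each field be told from a random mosaic?

For every synthetic field, simulate 99 random mosaics with the same cell
count, window and soma-diameter distribution (hard-core constraint) and rank
the field's NND regularity index among them (two-sided Monte-Carlo rank
test).  The test is run twice: on raw NNDs, and with a 7-μm floor censoring
the sub-contact distances that depth-projection overlap creates in the
(synthetic) segmentations but that a 2-D disc simulation cannot produce.

Writes results/matched_tests.csv.
"""

from pathlib import Path

import pandas as pd

from retmosaic import matched_simulation_test, read_field

ROOT = Path(__file__).resolve().parent.parent / "results"
TRIALS = 99
SEED = 11


def main() -> None:
    rows = []
    for csv_path in sorted((ROOT / "synthetic_retina").glob("*.csv")):
        field = read_field(csv_path)
        raw = matched_simulation_test(field, trials=TRIALS, seed=SEED)
        floored = matched_simulation_test(
            field, trials=TRIALS, seed=SEED, min_distance_floor=7.0
        )
        rows.append(
            {
                "field_id": field.field_id,
                "n_cells": field.n,
                "observed_ri": raw.observed_statistic,
                "simulated_ri_mean": raw.simulated_values.mean(),
                "rank_p_raw": raw.rank_p,
                "indistinguishable_raw": raw.indistinguishable,
                "rank_p_floor7": floored.rank_p,
                "indistinguishable_floor7": floored.indistinguishable,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "matched_tests.csv", index=False, float_format="%.4f")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    n_raw = df["indistinguishable_raw"].sum()
    n_floor = df["indistinguishable_floor7"].sum()
    print(
        f"\nindistinguishable from matched randomness: {n_raw}/16 on raw NNDs, "
        f"{n_floor}/16 with the 7-um floor. Depth-projection overlap widens the "
        "observed NND distribution (lower RI) relative to 2-D disc simulations; "
        "censoring below the contact distance removes part of that artifact."
    )


if __name__ == "__main__":
    main()
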