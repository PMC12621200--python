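#!/usr/bin/env python
"""Fit the bell-shaped dose-response model and extract the AC50.

Reads results/data/plate.csv, runs the end-to-end potency pipeline
(rates -> % activation -> bell fit -> rising-limb AC50 with censoring and
the 100-uM primary-hit rule) and writes results/ac50.csv.
"""

from pathlib import Path

from orcakit import dose_response, io, synthetic

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    plate = io.read_plate(ROOT / "data" / "plate.csv")
    res = dose_response.ac50_pipeline(io.traces_from_frame(plate))
    res.to_csv(ROOT / "ac50.csv", index=False)

    row = res.iloc[0]
    truth = synthetic.true_ac50(synthetic.MechanisticParams())
    print(f"{row.compound_id}: {row.classification}, "
          f"AC50 = {row.ac50_uM:.3f} uM (true {truth:.3f}), hit={bool(row.hit)}")
    print(f"bell fit: a_max {row.a_max:.1f}%, rising midpoint k_a {row.k_a:.3f} uM, "
          f"falling midpoint k_i {row.k_i:.1f} uM")
    print(f"wrote {ROOT / 'ac50.csv'}")


if __name__ == "__main__":
    main()
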