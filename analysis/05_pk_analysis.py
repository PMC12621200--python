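#!/usr/bin/env python
"""In-vitro PK: microsomal stability, Caco-2 permeability and efflux calls.

Reads results/data/microsomal.csv and results/data/transport.csv, fits the
log-linear decay (kel, t1/2, Clint at 0.42 mg protein/mL), computes Papp in
both directions, the efflux ratio with and without verapamil, and the
active-efflux / P-gp-substrate calls.  Also quantifies a kinetic-solubility
sample against a calibration line.  Writes results/pk.json.
"""

import json
from pathlib import Path

import pandas as pd

from orcakit import pk
from orcakit.types import TransportMeasurement

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    micro = pd.read_csv(ROOT / "data" / "microsomal.csv")
    nadph = micro[micro.series == "nadph"].groupby("time_min").remaining.mean()
    mres = pk.fit_microsomal(nadph.index.to_numpy(), nadph.to_numpy())
    print(f"microsomal: kel {mres.kel:.5f} 1/min, t1/2 {mres.t_half:.0f} min, "
          f"Clint {mres.clint:.1f} uL/min/mg (r2 {mres.r2:.3f})")

    tdf = pd.read_csv(ROOT / "data" / "transport.csv")
    ms = [TransportMeasurement(
        direction=r.direction, v_acceptor_uL=r.v_acceptor_uL, area_cm2=r.area_cm2,
        time_s=r.time_s, amount_acceptor_nmol=r.amount_acceptor_nmol,
        amount_donor_initial_nmol=r.amount_donor_initial_nmol,
        inhibitor=r.inhibitor) for r in tdf.itertuples()]
    tres = pk.transport_summary(ms)
    print(f"transport: Papp(AB) {tres.papp_ab:.1f}, Papp(BA) {tres.papp_ba:.1f} nm/s; "
          f"efflux ratio {tres.efflux_ratio:.1f} "
          f"(verapamil {tres.efflux_ratio_inhibited:.1f})")
    print(f"active efflux: {tres.active_efflux}; P-gp substrate: {tres.pgp_substrate}")

    calib = [(0.0, 0.001), (50.0, 0.101), (150.0, 0.301), (350.0, 0.701)]
    sol = pk.kinetic_solubility(calib, sample_abs=0.346, dilution_factor=2.0)
    print(f"solubility: {sol.concentration_uM:.0f} uM "
          f"(calibration r2 {sol.calibration_r2:.4f}, "
          f"{'outside' if sol.out_of_range else 'within'} the 2-350 uM range)")

    out = {
        "microsomal": {"kel_per_min": mres.kel, "t_half_min": mres.t_half,
                       "clint_uL_min_mg": mres.clint, "r2": mres.r2,
                       "censored": mres.censored},
        "transport": {"papp_ab_nm_s": tres.papp_ab, "papp_ba_nm_s": tres.papp_ba,
                      "efflux_ratio": tres.efflux_ratio,
                      "efflux_ratio_verapamil": tres.efflux_ratio_inhibited,
                      "active_efflux": tres.active_efflux,
                      "pgp_substrate": tres.pgp_substrate},
        "solubility_uM": sol.concentration_uM,
    }
    (ROOT / "pk.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {ROOT / 'pk.json'}")


if __name__ == "__main__":
    main()
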