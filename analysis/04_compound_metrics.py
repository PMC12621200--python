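#!/usr/bin/env python
"""Compound-efficiency metrics and the virtual-screening triage funnel.

Computes pAC50, AcLE, AcLLE, docking LE and fold-selectivity for a small
compound table (the screening hit and the optimized 5-hydroxy lead, using
their printed potencies and descriptors), then runs the ligand-efficiency
triage on a synthetic 1000-compound docking table.  Writes
results/compound_metrics.csv and results/triage.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from orcakit import metrics

ROOT = Path(__file__).resolve().parent.parent / "results"

COMPOUNDS = [
    # id, free-base formula, clogP, docking score, AC50 uM, panel (censored)
    ("hit-1", "C15H15N3", 3.1, -9.91, 4.1, (100.0,), (True,)),
    ("lead-30", "C15H15N3O", 0.84, None, 0.58, (100.0,), (True,)),
    ("TH10785", None, 4.54, None, 0.78, (100.0,), (True,)),
]


def main() -> None:
    ROOT.mkdir(exist_ok=True)
    rows = []
    for cid, formula, clogp, dock, ac50, panel, cens in COMPOUNDS:
        rec = metrics.CompoundRecord(
            id=cid, formula=formula or "", heavy_atoms=None if formula else 20,
            clogp=clogp, docking_score=dock, ac50=ac50,
            panel_ic50s=panel, panel_censored=cens)
        m = metrics.efficiency_metrics(rec)
        rows.append({
            "id": cid, "heavy_atoms": rec.heavy_atoms,
            "pac50": round(m.pac50, 3),
            "acle": round(m.acle, 3) if m.acle is not None else None,
            "aclle": round(m.aclle, 2) if m.aclle is not None else None,
            "le": round(m.le, 2) if m.le is not None else None,
            "selectivity": str(m.selectivity_fold),
        })
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "compound_metrics.csv", index=False)
    print(df.to_string(index=False))

    rng = np.random.default_rng(0)
    library = [metrics.CompoundRecord(
        id=f"vs{i}", heavy_atoms=int(rng.integers(10, 40)),
        docking_score=float(-rng.uniform(2, 14)),
        pains_flag=bool(rng.random() < 0.08),
        reos_flag=bool(rng.random() < 0.05)) for i in range(1000)]
    kept, report = metrics.le_triage(library, le_min=0.40)
    print(f"triage: {report.n_input} docked -> {report.n_kept} kept "
          f"(LE >= 0.40, PAINS/REOS clean); "
          f"failed LE {report.n_fail_le}, PAINS {report.n_fail_pains}, "
          f"REOS {report.n_fail_reos}")
    (ROOT / "triage.json").write_text(json.dumps(report.__dict__, indent=2))


if __name__ == "__main__":
    main()
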