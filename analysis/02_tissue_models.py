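#!/usr/bin/env python
"""Compartment volumes and sodium contributions for the three tissue states.

Builds the control, NAWM (demyelination + atrophy) and lesion
(demyelination + edema) white-matter models and tabulates volumes,
per-compartment sodium (mmol/L-tissue), TSC and tissue volume change.
Finding: control TSC is 37.9 mmol/L-tissue with myelin water
contributing more sodium (6.8) than the intracellular space (6.2); the
NAWM model shrinks tissue by 4.3% yet raises TSC by only 0.8%, while the
lesion model raises TSC by ~28% driven almost entirely by edema.
"""

from pathlib import Path

import pandas as pd

from na_contrast.compartments import (
    LESION_PARAMS,
    NAWM_PARAMS,
    apply_demyelination,
    control_volumes,
    sodium_contributions,
    tsc_percent_difference,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ctrl_vols = control_volumes()
    nawm_vols, d_nawm = apply_demyelination(ctrl_vols, NAWM_PARAMS)
    les_vols, d_les = apply_demyelination(ctrl_vols, LESION_PARAMS)
    ctrl = sodium_contributions(ctrl_vols)

    rows = []
    for name, vols, change in [
        ("control", ctrl_vols, 0.0),
        ("nawm", nawm_vols, d_nawm),
        ("lesion", les_vols, d_les),
    ]:
        q = sodium_contributions(vols)
        rows.append(
            {
                "state": name,
                "v_myelin_water": round(vols.v_myelin_water, 4),
                "v_intra": round(vols.v_intra, 4),
                "v_extra": round(vols.v_extra, 4),
                "v_edema": round(vols.v_edema, 4),
                "v_solids": round(vols.v_solids, 4),
                "volume_change_pct": round(100 * change, 2),
                "q_myelin": round(q.q_myelin, 2),
                "q_intra": round(q.q_intra, 2),
                "q_extra": round(q.q_extra, 2),
                "q_edema": round(q.q_edema, 2),
                "tsc": round(q.tsc, 2),
                "tsc_pct_vs_control": round(tsc_percent_difference(q, ctrl), 2),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "tissue_states.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
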