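#!/usr/bin/env python
"""Simulate the study cohort and run the group-statistics layer.

Generates a 9-control / 30-patient cohort with the forward-model tissue
effects, then: unpaired lesion-vs-control and NAWM-vs-control t-tests
with BH-FDR per sequence, paired lesion-vs-NAWM tests, the cross-
sequence regression of intra-patient lesion effects, and partial
correlations (age/sex controlled) of NAWM intensity with a synthetic
cognitive score.  Finding: lesion elevations on NaDW and NaPACMAN are
highly significant after FDR; at the default (low) noise level even the
small +1.1% / +4.4% NAWM elevations reach significance, while NaSIRFLA
shows no difference in either comparison; the NaPACMAN-vs-NaDW
lesion-effect slope comes out near the forward-model ratio of ~1.6.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from na_contrast.phantom import simulate_cohort
from na_contrast.stats import bh_fdr, paired_t, partial_pearson, regression_slope, unpaired_t

OUT = Path(__file__).resolve().parents[1] / "results"
SEQUENCES = ("NaDW", "NaPACMAN", "NaSIRFLA")
REGIONS = ("scc", "plic", "alic")


def main(seed: int = 2021) -> None:
    OUT.mkdir(exist_ok=True)
    df = simulate_cohort(n_controls=9, n_patients=30, seed=seed)

    rows = []
    for state in ("lesion", "nawm"):
        for seq in SEQUENCES:
            ps = []
            for region in REGIONS:
                sub = df[(df.sequence == seq) & (df.region == region)]
                res = unpaired_t(
                    sub.loc[sub.tissue_state == state, "mean_intensity"],
                    sub.loc[sub.group == "control", "mean_intensity"],
                )
                ps.append((region, res))
            adj, rej = bh_fdr([r.p for _, r in ps], q=0.05)
            for (region, res), q_adj, sig in zip(ps, adj, rej):
                rows.append(
                    {
                        "comparison": f"{state}_vs_control",
                        "sequence": seq,
                        "region": region,
                        "t": round(res.statistic, 3),
                        "p": res.p,
                        "q_adjusted": q_adj,
                        "significant": bool(sig),
                    }
                )
    group_df = pd.DataFrame(rows)
    group_df.to_csv(OUT / "cohort_group_tests.csv", index=False)
    sig = group_df.groupby(["comparison", "sequence"]).significant.sum()
    print("significant regions (of 3) after BH-FDR:")
    print(sig.to_string())

    piv = df[df.group == "patient"].pivot_table(
        index=["subject", "region"],
        columns=["sequence", "tissue_state"],
        values="mean_intensity",
    )
    paired = paired_t(piv[("NaDW", "lesion")], piv[("NaDW", "nawm")])
    print(f"\npaired lesion vs NAWM (NaDW): t = {paired.statistic:.2f}, p = {paired.p:.2e}")

    x = (piv[("NaDW", "lesion")] / piv[("NaDW", "nawm")] - 1).groupby("subject").mean()
    y = (piv[("NaPACMAN", "lesion")] / piv[("NaPACMAN", "nawm")] - 1).groupby("subject").mean()
    fit = regression_slope(x.to_numpy(), y.to_numpy())
    print(
        f"lesion-effect slope NaPACMAN vs NaDW: "
        f"{fit['slope']:.2f} +/- {fit['slope_halfwidth']:.2f}"
    )

    # partial correlation demo: synthetic score tied to NAWM NaSIRFLA signal
    rng = np.random.default_rng(seed)
    nawm = (
        df[(df.tissue_state == "nawm") & (df.sequence == "NaSIRFLA")]
        .groupby("subject")
        .agg({"mean_intensity": "mean", "age": "first", "sex": "first"})
    )
    score = 40 + 30 * (nawm.mean_intensity - nawm.mean_intensity.mean()) / nawm.mean_intensity.std()
    score = score - 0.1 * (nawm.age - nawm.age.mean()) + rng.normal(0, 5, len(nawm))
    res = partial_pearson(
        nawm.mean_intensity.to_numpy(),
        score.to_numpy(),
        np.column_stack([nawm.age, nawm.sex]),
    )
    print(f"partial correlation (age/sex controlled): r = {res.estimate:.2f}, p = {res.p:.3f}")
    pd.DataFrame(
        [{"slope": fit["slope"], "slope_halfwidth": fit["slope_halfwidth"],
          "paired_t": paired.statistic, "partial_r": res.estimate, "partial_p": res.p}]
    ).to_csv(OUT / "cohort_summary.csv", index=False)


if __name__ == "__main__":
    main()
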