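"""Regional peak-timing analysis of the long pattern across two groups.

Group A carries the canonical 20-frame two-lobe motif; group B is identical
except one region's waveform is delayed by 2 frames (1 s at TR 0.5).
Group A's pattern is projected onto group B, voxel significance is
calibrated against 50 occurrence-avoiding null patterns per group, and the
three timing-comparison tiers are run. Replicates under the group null
(no lag difference) measure false-flag rates. Writes the replicate summary
under results/.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

from qppdyn.workflows import timing_replicate


def main(seed: int = 400, n_replicates: int = 10) -> None:
    results = pathlib.Path("results")
    results.mkdir(exist_ok=True)

    rows = []
    for arm, lag in (("lagged_B", 2.0), ("group_null", 0.0)):
        base = seed if arm == "lagged_B" else seed + 1000
        for i in range(n_replicates):
            r = timing_replicate(base + i, lag)
            t1 = r["result"].tier1
            t3 = r["result"].tier3
            rows.append({
                "arm": arm, "seed": base + i,
                "lag_estimate_frames": r["lag_estimate"],
                "significance_sensitivity": r["sensitivity"],
                "tier1_flagged": ";".join(sorted(r["tier1_flagged"])) or "-",
                "tier1_flags": int(t1["significant"].sum()),
                "tier3_flags": int(t3["significant"].sum()),
            })
    df = pd.DataFrame(rows)
    df.to_csv(results / "peak_timing_replicates.csv", index=False)

    eff = df[df["arm"] == "lagged_B"]
    nul = df[df["arm"] == "group_null"]
    print(f"lagged arm: mean recovered lag "
          f"{eff['lag_estimate_frames'].mean():.2f} frames (embedded: 2.0); "
          f"tier-1 flags the lagged region alone in "
          f"{(eff['tier1_flagged'] == 'L2').sum()}/{len(eff)} replicates")
    print(f"group null: mean tier-1 flags/replicate "
          f"{nul['tier1_flags'].mean():.2f}, tier-3 "
          f"{nul['tier3_flags'].mean():.2f}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=400)
    ap.add_argument("--replicates", type=int, default=10)
    args = ap.parse_args()
    main(args.seed, args.replicates)
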