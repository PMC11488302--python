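"""Extract the short QPP from the flagship phantom and score the recovery.

Runs the full pipeline — preprocess, 50 random-start extraction, clustering
with robustness screening, representative selection — and reports how well
the representative QPP matches the embedded ground truth: spatial template
correlation, occurrence recall at a +/-2-frame tolerance, and the false
occurrence fraction. Writes the recovery scorecard and the representative's
occurrence list under results/.
"""

import argparse
import pathlib

import pandas as pd

from qppdyn import write_results
from qppdyn.workflows import short_qpp_recovery


def main(seed: int = 11, n_starts: int = 50) -> None:
    results = pathlib.Path("results")
    results.mkdir(exist_ok=True)

    rec = short_qpp_recovery(seed=seed, n_starts=n_starts)
    print(f"{n_starts} random starts -> {len(rec.report.robust)} robust cluster(s)")
    if rec.rqpp is None:
        print("no robust cluster: nothing to score")
        return
    scorecard = pd.DataFrame([{
        "seed": seed,
        "n_starts": n_starts,
        "n_robust_clusters": len(rec.report.robust),
        "template_correlation": rec.template_correlation,
        "occurrence_recall": rec.recall,
        "false_occurrence_fraction": rec.false_rate,
        "n_occurrences": rec.rqpp.n_occurrences,
    }])
    scorecard.to_csv(results / "short_qpp_recovery.csv", index=False)
    write_results(rec.rqpp, results / "short_rqpp", series=rec.series,
                  meta={"seed": seed, "n_starts": n_starts})
    print(scorecard.to_string(index=False))
    print("representative template correlates "
          f"{rec.template_correlation:.3f} with the embedded motif; "
          f"recall {rec.recall:.2f}, false fraction {rec.false_rate:.2f}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--starts", type=int, default=50)
    args = ap.parse_args()
    main(args.seed, args.starts)
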