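#!/usr/bin/env python
"""Route-compliance analysis across the cohort.

Pairwise R^2 of the distance-aligned profiles quantifies how strongly the
route (the only shared factor) drives each participant; the per-
participant medians are ranked per parameter, rank sums ordered, and
Kendall's W measures cross-parameter agreement of the ordering.

Writes r2_<param>.csv, compliance.csv and concordance.json under
results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import rollmetrics as rm
from rollmetrics.compliance import compliance_report

from importlib import import_module
import sys

sys.path.insert(0, str(Path(__file__).parent))
load_aligned = import_module("03_section_effects").load_aligned


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--runs", type=Path, default=Path("results/runs"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    runs = [load_aligned(p) for p in sorted(args.runs.iterdir()) if (p / "aligned.csv").exists()]
    args.out.mkdir(parents=True, exist_ok=True)

    report = compliance_report(runs)
    ids = list(report.participant_ids)

    for j, param in enumerate(report.parameters):
        m = rm.pairwise_r2(runs, param)
        pd.DataFrame(m.values, index=ids, columns=ids).to_csv(args.out / f"r2_{param}.csv")

    rows = []
    for i, pid in enumerate(ids):
        for j, param in enumerate(report.parameters):
            rows.append(
                {
                    "participant": pid,
                    "param": param,
                    "r2_median": round(report.medians[i, j], 4),
                    "r2_iqr": round(report.iqrs[i, j], 4),
                    "rank": report.ranks[i, j],
                    "low_outlier": bool(report.outliers[i, j]),
                }
            )
    pd.DataFrame(rows).to_csv(args.out / "compliance.csv", index=False)

    concordance = {
        "rank_sums": {pid: int(s) for pid, s in zip(ids, report.rank_sums)},
        "kendalls_w": report.kendalls_w,
        "friedman_chi2": report.friedman_chi2,
        "friedman_p": report.friedman_p,
    }
    (args.out / "concordance.json").write_text(json.dumps(concordance, indent=1))

    top = ids[int(np.argmax(report.rank_sums))]
    bottom = ids[int(np.argmin(report.rank_sums))]
    print(f"most route-driven: {top} (rank sum {report.rank_sums.max():.0f}); "
          f"most individualistic: {bottom} (rank sum {report.rank_sums.min():.0f})")
    print(f"Kendall's W = {report.kendalls_w:.3f} "
          f"(chi2 = {report.friedman_chi2:.2f}, p = {report.friedman_p:.4f})")


if __name__ == "__main__":
    main()
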