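#!/usr/bin/env python
"""Per-section statistics and the cohort effect-size networks.

For each participant and parameter (speed, COPx, COPy): per-section
mean +/- SD, one-way ANOVA over the 13 sections, all 78 Tukey-HSD pairs
with Cohen's d.  Pairs whose effect size averaged over the cohort reaches
d = 0.8 (and are Tukey-significant for at least half the cohort) form the
network edges; weights saturate at d = 2.

Writes sections.csv, pairs.csv and edges_<param>.csv under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

import rollmetrics as rm
from rollmetrics.sections import AlignedRun, compare_sections, effect_network, section_summary


def load_aligned(run_dir: Path) -> AlignedRun:
    df = pd.read_csv(run_dir / "aligned.csv")
    return AlignedRun(
        dist=df["dist_m"].to_numpy(),
        v=df["v_mps"].to_numpy(),
        copx=df["copx_mm"].to_numpy(),
        copy_=df["copy_mm"].to_numpy(),
        section=df["section"].to_numpy(),
        participant_id=run_dir.name,
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--runs", type=Path, default=Path("results/runs"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    runs = [load_aligned(p) for p in sorted(args.runs.iterdir()) if (p / "aligned.csv").exists()]
    args.out.mkdir(parents=True, exist_ok=True)

    sec_rows, pair_rows = [], []
    comps_by_param = {p: [] for p in ("v", "copx", "copy")}
    for run in runs:
        tab = section_summary(run)
        tab.insert(0, "participant", run.participant_id)
        sec_rows.append(tab)
        for param in comps_by_param:
            F, p_anova, comps = compare_sections(run, param)
            comps_by_param[param].append(comps)
            for c in comps:
                pair_rows.append(
                    {
                        "participant": run.participant_id,
                        "param": param,
                        "i": c.pair[0],
                        "j": c.pair[1],
                        "tukey_p": c.tukey_p,
                        "cohens_d": c.cohens_d,
                        "significant": c.significant,
                    }
                )
    pd.concat(sec_rows).to_csv(args.out / "sections.csv", index=False)
    pd.DataFrame(pair_rows).to_csv(args.out / "pairs.csv", index=False)

    for param, comps in comps_by_param.items():
        edges = effect_network(comps)
        pd.DataFrame(
            [
                {"i": e.pair[0], "j": e.pair[1], "mean_d": round(e.mean_d, 3),
                 "weight": round(e.weight, 3)}
                for e in edges
            ]
        ).to_csv(args.out / f"edges_{param}.csv", index=False)
        print(f"{param}: {len(edges)} network edges with cohort-mean d >= 0.8")


if __name__ == "__main__":
    main()
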