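#!/usr/bin/env python
"""Screening case study: injured athlete vs control group, and recovery.

Three analyses over the reliability-gated indices (02):

1. PRE vs CG: Welch t-test of the athlete's five pre-injury repetitions
   against the 12 control subjects' session means, per index.
2. Longitudinal: one-way ANOVA of the athlete's four sessions per index,
   with Bonferroni-corrected pairwise tests when the omnibus is significant.
3. Each POST session vs CG, to track return toward the reference band.

Writes results/case_study.csv (mean (SD) table with significance flags)
and results/longitudinal.json.
"""

import sys
from pathlib import Path

import pandas as pd

from aclscreen.group_stats import build_case_report, longitudinal_anova
from aclscreen.io import write_json_report
from aclscreen.reliability import session_average

RESULTS = Path(__file__).resolve().parent.parent / "results"


def gated_indices():
    rel = pd.read_csv(RESULTS / "reliability.csv")
    return [(r["task"], r["index"]) for _, r in rel.iterrows() if r["acceptable"]]


def main():
    cg_rep = pd.read_csv(RESULTS / "cg_per_rep.csv")
    ath_rep = pd.read_csv(RESULTS / "athlete_per_rep.csv")
    gated = gated_indices()

    def athlete_values(session, task, index):
        m = (ath_rep["session_id"] == session) & (ath_rep["task"] == task)
        return ath_rep.loc[m & ~ath_rep["flagged"], index].dropna().to_numpy()

    pre, posts, cg = {}, {"POST1": {}, "POST2": {}, "POST3": {}}, {}
    for task, index in gated:
        key = f"{task}:{index}"
        tbl = session_average(cg_rep[cg_rep["task"] == task], index)
        cg[key] = tbl.values.mean(axis=1).to_numpy()  # per-subject means
        pre[key] = athlete_values("PRE", task, index)
        for p in posts:
            posts[p][key] = athlete_values(p, task, index)

    report = build_case_report(pre, posts, cg)
    report.to_csv(RESULTS / "case_study.csv", index=False)
    print("PRE/POST vs control group, mean (SD); * = p < 0.05 vs CG")
    for index, block in report.groupby("index", sort=False):
        cells = [
            f"{r['group']} {r['mean']:.3g} ({r['sd']:.2g}){'*' if r['significant_vs_cg'] else ''}"
            for _, r in block.iterrows()
        ]
        print(f"  {index:14s} " + " | ".join(cells))

    longi = {}
    print("\nOne-way ANOVA across athlete sessions (Bonferroni post hoc when significant):")
    for task, index in gated:
        key = f"{task}:{index}"
        sessions = {s: athlete_values(s, task, index) for s in ("PRE", "POST1", "POST2", "POST3")}
        sessions = {s: v for s, v in sessions.items() if v.size >= 2}
        res = longitudinal_anova(sessions, key)
        longi[key] = [r.to_dict() for r in res]
        omni = res[0]
        n_pairs = sum(r.significant for r in res[1:])
        print(
            f"  {key:14s} F={omni.statistic:6.2f} p={omni.p_value:.4f}"
            + (f"  ({n_pairs} significant pairs)" if omni.significant else "")
        )
    write_json_report(longi, RESULTS / "longitudinal.json")
    print(f"\nwrote {RESULTS / 'case_study.csv'} and {RESULTS / 'longitudinal.json'}")


if __name__ == "__main__":
    sys.exit(main())
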