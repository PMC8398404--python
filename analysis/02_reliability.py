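#!/usr/bin/env python
"""Inter-session reliability of every index on the control cohort.

For each index and task, repetitions are averaged within subject-session
cells and the single-measure absolute-agreement ICC across the three
sessions is computed, banded (poor/fair/good/excellent) and gated at 0.60.
Indices passing the gate feed the case-study comparisons (03).
"""

import sys
from pathlib import Path

import pandas as pd

from aclscreen.io import write_json_report
from aclscreen.pipeline import MCMJ_INDICES, SLS_INDICES
from aclscreen.reliability import reliability_report

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    per_rep = pd.read_csv(RESULTS / "cg_per_rep.csv")
    reports = []
    for task, names in [("mcmj", MCMJ_INDICES), ("sls", SLS_INDICES)]:
        rep = reliability_report(per_rep[per_rep["task"] == task], names)
        rep.insert(0, "task", task)
        reports.append(rep)
    report = pd.concat(reports, ignore_index=True)
    report.to_csv(RESULTS / "reliability.csv", index=False)
    write_json_report(report, RESULTS / "reliability.json")

    print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    gated = report[report["acceptable"]]
    print(
        f"\n{len(gated)}/{len(report)} indices reach at least good reliability "
        f"(ICC >= 0.60) and enter the case study:"
    )
    for _, row in gated.iterrows():
        print(f"  {row['task']}:{row['index']}  ICC {row['icc']:.2f} ({row['band']})")


if __name__ == "__main__":
    sys.exit(main())
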