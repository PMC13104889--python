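#!/usr/bin/env python
"""Ensemble uncertainty decomposition, stratification and agreement.

Computes per-transcript predictive entropy H_pred, expected entropy H_exp
and the disagreement score I_dis = H_pred - H_exp; stratifies transcripts
per class into low / intermediate / high uncertainty by the 10th/90th
percentile rule; categorizes inter-tool agreement; and evaluates each tool's
macro metrics.
"""

import json
from pathlib import Path

from lncuncert.pipeline import RunConfig, stage_uncertainty

OUT = Path("results/analysis")


def main():
    cfg = RunConfig(outdir=str(OUT), seed=0)
    ids = (OUT / "cohort_ids.txt").read_text().split()
    profiles, thresholds, summary = stage_uncertainty(
        cfg, OUT / "cohort", OUT, ids)
    ex = summary["exclusions"]
    print(f"{ex['n_excluded']} transcripts lacked >=1 tool prediction and "
          f"were excluded; {ex['n_retained']} profiled")
    print("group sizes:", summary["group_counts"])
    print("agreement:", {k: f"{v:.1%}"
                         for k, v in summary["agreement_fractions"].items()})
    best = max(summary["per_tool_metrics"].items(),
               key=lambda kv: kv[1]["balanced_accuracy"])
    print(f"best tool: {best[0]} "
          f"(balanced accuracy {best[1]['balanced_accuracy']:.3f})")
    print("per-class thresholds:",
          json.dumps(thresholds.per_class, indent=1))


if __name__ == "__main__":
    main()
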