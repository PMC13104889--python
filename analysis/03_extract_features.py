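#!/usr/bin/env python
"""Extract repeat and non-B DNA features and merge them with the ML set.

Parses the RepeatMasker .out (overlap resolution + element aggregation +
transcript summaries) and the motif BED against gene bodies (overlaps
retained), then joins both with the classifier-style feature table.
"""

from pathlib import Path

from lncuncert.pipeline import RunConfig, stage_features

OUT = Path("results/analysis")


def main():
    cfg = RunConfig(outdir=str(OUT), seed=0)
    ids = (OUT / "cohort_ids.txt").read_text().split()
    features, kinds = stage_features(cfg, OUT / "cohort", OUT, ids)
    n_rep = sum(c.startswith("rep_") for c in features.columns)
    n_nbd = sum(c.startswith("nbd_") for c in features.columns)
    n_ml = features.shape[1] - n_rep - n_nbd - 1
    print(f"combined feature table: {features.shape[0]} transcripts x "
          f"{features.shape[1]} features "
          f"(ML {n_ml}, repeat {n_rep}, non-B DNA {n_nbd}, +length)")
    pres = features[[c for c in features.columns
                     if c.startswith("rep_presence_")]].gt(0).any(axis=1)
    print(f"transcripts with >=1 repeat: {pres.mean():.1%}")
    print(f"wrote {OUT / 'combined_features.tsv'} (+ schema sidecar)")


if __name__ == "__main__":
    main()
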