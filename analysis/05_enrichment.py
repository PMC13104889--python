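#!/usr/bin/env python
"""Feature redundancy clustering and univariate enrichment analyses.

Clusters continuous features on Spearman-derived distance (Ward linkage,
silhouette-chosen cut), keeps the highest-|cVDA| representative per cluster
(transcript length forced as its cluster's representative), and tests each
representative across low-vs-high entropy and lncRNA-vs-coding comparisons
(Mann-Whitney + cVDA, chi-squared + Cramer's V, BH within comparison).
"""

import json
from pathlib import Path

import pandas as pd

from lncuncert.pipeline import RunConfig, stage_enrich

OUT = Path("results/analysis")


def main():
    cfg = RunConfig(outdir=str(OUT), seed=0)
    features = pd.read_csv(OUT / "combined_features.tsv", sep="\t",
                           index_col="transcript_id")
    kinds = json.loads(
        (OUT / "combined_features.schema.json").read_text())["kinds"]
    profiles = pd.read_csv(OUT / "entropy_profiles.tsv", sep="\t",
                           index_col=0)
    results, clustering, reps = stage_enrich(cfg, OUT, features, kinds,
                                             profiles)
    print(f"{clustering.n_clusters} feature clusters "
          f"(cut at {clustering.chosen_threshold:.3f}); "
          f"{len(reps)} representatives tested")
    sig = results[results["significant"] & results["non_negligible"]]
    print(f"{len(sig)}/{len(results)} tests significant (BH p<{cfg.alpha}) "
          f"with non-negligible effect (>{cfg.effect_threshold})")
    for comp in results["comparison"].unique():
        top = (sig[sig["comparison"] == comp]
               .reindex(sig[sig["comparison"] == comp]["effect"].abs()
                        .sort_values(ascending=False).index).head(3))
        names = ", ".join(f"{r.feature} (effect {r.effect:+.2f})"
                          for r in top.itertuples())
        print(f"  {comp}: {names if names else 'no flagged features'}")


if __name__ == "__main__":
    main()
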