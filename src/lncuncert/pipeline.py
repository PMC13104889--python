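"""End-to-end orchestration of the uncertainty-aware benchmarking analysis.

Stages (each skippable when its inputs are supplied by the user):

    simulate -> cohort -> features -> uncertainty -> enrich -> explain -> report

Every stage is a plain function over files + DataFrames so the numbered
analysis scripts, the CLI and the tests all drive the same code.  A JSON run
manifest records the configuration, seeds, input digests and every file the
run produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import SimulationConfig, generate_cohort, write_cohort
from . import cohort as cohort_mod
from .repeats import parse_repeatmasker_out, repeat_feature_table, \
    REPEAT_FEATURE_SCHEMA
from .nbd import read_motif_bed, nbd_feature_table, NBD_FEATURE_SCHEMA
from . import uncertainty as unc
from . import stats
from .importance import ForestConfig, train_forests, explain, top_k_view, \
    summarize_importance, embed_2d

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline",
           "stage_simulate", "stage_cohort", "stage_features",
           "stage_uncertainty", "stage_enrich", "stage_explain"]


@dataclass
class RunConfig:
    outdir: str = "results/run"
    seed: int = 0
    k_folds: int = 5
    q_low: float = 0.10
    q_high: float = 0.90
    alpha: float = 0.01
    effect_threshold: float = 0.1
    n_trees: int = 300
    max_depth: int | None = None
    recalibrate_threshold: bool = False
    embedding: bool = False
    perplexity: float = 30.0
    tsne_iter: int = 1000
    simulate: bool = True
    input_dir: str | None = None      # pre-existing cohort dir when simulate=False
    simulation_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path):
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _digest(path):
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def stage_simulate(cfg: RunConfig, outdir: Path):
    sim = SimulationConfig(seed=cfg.seed, **cfg.simulation_overrides)
    cohort = generate_cohort(sim)
    paths = write_cohort(cohort, outdir / "cohort")
    return cohort, paths


def stage_cohort(cfg: RunConfig, indir: Path, outdir: Path):
    """Label-stable intersection, cluster representatives, fold splits."""
    rel_a = cohort_mod.read_biotype_table(indir / "release_a.tsv")
    rel_b = cohort_mod.read_biotype_table(indir / "release_b.tsv")
    stable = cohort_mod.intersect_releases(rel_a, rel_b)
    lengths = dict(zip(rel_a["transcript_id"], rel_a["length"]))
    clstr = (indir / "clusters.clstr").read_text()
    reps = cohort_mod.select_representatives(clstr, lengths)
    cohort_ids = sorted(set(stable) & reps)
    bio = rel_a.set_index("transcript_id")["biotype"]
    ids_by_class = {
        unc.CODING: [t for t in cohort_ids if bio[t] == "protein_coding"],
        unc.LNCRNA: [t for t in cohort_ids if bio[t] == "lncRNA"],
    }
    splits = cohort_mod.make_fold_splits(ids_by_class, k=cfg.k_folds,
                                         seed=cfg.seed)
    manifest = cohort_mod.fold_manifest(splits)
    manifest.to_csv(outdir / "fold_manifest.tsv", sep="\t", index=False)
    (outdir / "cohort_ids.txt").write_text("\n".join(cohort_ids) + "\n")
    summary = {
        "n_release_a": int(len(rel_a)), "n_release_b": int(len(rel_b)),
        "n_label_stable": len(stable),
        "n_cluster_representatives": len(reps),
        "n_cohort": len(cohort_ids),
        "per_class": {k: len(v) for k, v in ids_by_class.items()},
        "per_fold": [{
            "fold": s.fold_index,
            "train": {k: len(v) for k, v in s.train_ids_by_class.items()},
            "test": {k: len(v) for k, v in s.test_ids_by_class.items()},
        } for s in splits],
    }
    return cohort_ids, ids_by_class, splits, summary


def stage_features(cfg: RunConfig, indir: Path, outdir: Path, cohort_ids):
    """Repeat + non-B DNA feature extraction, merged with the ML features."""
    rel_a = cohort_mod.read_biotype_table(indir / "release_a.tsv")
    lengths = dict(zip(rel_a["transcript_id"], rel_a["length"]))
    hits = parse_repeatmasker_out((indir / "repeats.out").read_text())
    rep_table = repeat_feature_table(
        hits, {t: lengths[t] for t in cohort_ids})
    calls = read_motif_bed(indir / "motifs.bed")
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    nbd_table = nbd_feature_table(calls, genes)
    gene_of = dict(zip(genes["transcript_id"], genes["gene_id"]))
    nbd_tx = nbd_table.loc[[gene_of[t] for t in cohort_ids]]
    nbd_tx.index = pd.Index(cohort_ids, name="transcript_id")

    ml = pd.read_csv(indir / "features.tsv", sep="\t",
                     index_col="transcript_id").loc[cohort_ids]
    kinds = json.loads((indir / "feature_kinds.json").read_text())
    combined = ml.join(rep_table.add_prefix("rep_")) \
                 .join(nbd_tx.add_prefix("nbd_"))
    combined["transcript_length"] = [lengths[t] for t in combined.index]
    for c in combined.columns:
        if c in kinds:
            continue
        if c.startswith(("rep_presence_", "nbd_presence_")):
            kinds[c] = "categorical"
        else:
            kinds[c] = "continuous"
    combined.to_csv(outdir / "combined_features.tsv", sep="\t")
    sidecar = {
        "kinds": kinds,
        "sources": {c: ("ml_tool" if c in ml.columns else
                        "repeat" if c.startswith("rep_") else
                        "nbd" if c.startswith("nbd_") else "annotation")
                    for c in combined.columns},
        "repeat_schema": REPEAT_FEATURE_SCHEMA,
        "nbd_schema": NBD_FEATURE_SCHEMA,
    }
    (outdir / "combined_features.schema.json").write_text(
        json.dumps(sidecar, indent=1))
    return combined, kinds


def stage_uncertainty(cfg: RunConfig, indir: Path, outdir: Path, cohort_ids):
    """Entropy decomposition, stratification, agreement, global metrics."""
    preds = pd.read_csv(indir / "predictions.tsv", sep="\t",
                        index_col="transcript_id")
    preds = preds.loc[[t for t in cohort_ids if t in preds.index]]
    complete, excl_report = unc.exclude_incomplete(preds)
    prob_cols = unc.prob_columns(complete)
    profiles = unc.ensemble_profile(complete[prob_cols].to_numpy())
    profiles.index = complete.index
    labels = complete["reference"]
    thresholds = unc.compute_thresholds(profiles, labels,
                                        cfg.q_low, cfg.q_high)
    groups = unc.stratify(profiles, labels, thresholds)
    label_cols = unc.label_columns(complete)
    tool_names = [c.removeprefix("label_") for c in label_cols]
    agreement = unc.agreement_category(
        complete[label_cols].to_numpy(), labels.to_numpy(), tool_names)
    agreement.index = complete.index
    per_tool = {
        t: unc.evaluate(complete[f"label_{t}"], labels).as_dict()
        for t in tool_names
    }
    profile_out = profiles.copy()
    profile_out["reference"] = labels
    profile_out["group"] = groups
    profile_out["category"] = agreement["category"].to_numpy()
    profile_out["n_correct"] = agreement["n_correct"].to_numpy()
    profile_out.to_csv(outdir / "entropy_profiles.tsv", sep="\t")
    (outdir / "thresholds.json").write_text(json.dumps({
        "per_class": thresholds.per_class,
        "quantile_convention": thresholds.quantile_convention,
        "q_low": cfg.q_low, "q_high": cfg.q_high}, indent=1))
    counts = groups.groupby([labels, groups]).size()
    summary = {
        "exclusions": excl_report,
        "group_counts": {f"{c}|{g}": int(v)
                         for (c, g), v in counts.items()},
        "agreement_fractions": {
            k: float(v) for k, v in
            (agreement["category"].value_counts(normalize=True)).items()},
        "per_tool_metrics": per_tool,
    }
    (outdir / "metrics.json").write_text(json.dumps(summary, indent=1))
    return profile_out, thresholds, summary


def stage_enrich(cfg: RunConfig, outdir: Path, features, kinds, profiles):
    """Cluster redundant features and run the three enrichment comparisons."""
    features = features.loc[profiles.index]
    continuous, indicators, dropped = stats.preprocess(features, kinds)
    clustering = stats.cluster_features(continuous)
    low = profiles.index[profiles["group"] == "low"]
    high = profiles.index[profiles["group"] == "high"]
    lnc = profiles.index[profiles["reference"] == unc.LNCRNA]
    pc = profiles.index[profiles["reference"] == unc.CODING]

    effects = {}
    for f in continuous.columns:
        try:
            _, _, cvda = stats.mannwhitney_vda(
                continuous.loc[low, f].dropna(),
                continuous.loc[high, f].dropna())
        except ValueError:
            cvda = 0.0
        effects[f] = cvda
    forced = (["transcript_length"]
              if "transcript_length" in clustering.cluster_of else [])
    reps = stats.select_representatives(
        clustering, mode="max_effect", effect_fn=lambda f: effects[f],
        forced=forced)
    tested = pd.concat([continuous[sorted(reps)], indicators], axis=1)
    test_kinds = {c: ("continuous" if c in continuous.columns
                      else "categorical") for c in tested.columns}
    comparisons = {
        "low_vs_high": (low, high),
        "lnc_vs_pc_low": (lnc.intersection(low), pc.intersection(low)),
        "lnc_vs_pc_high": (lnc.intersection(high), pc.intersection(high)),
    }
    results = stats.run_enrichment(tested, test_kinds, comparisons,
                                   alpha=cfg.alpha,
                                   effect_threshold=cfg.effect_threshold)
    results.to_csv(outdir / "univariate_results.tsv", sep="\t", index=False)
    report = {
        "dropped_features": dropped,
        "n_continuous": int(continuous.shape[1]),
        "n_indicator": int(indicators.shape[1]),
        "n_clusters": clustering.n_clusters,
        "chosen_threshold": clustering.chosen_threshold,
        "threshold_grid": list(map(float, clustering.threshold_grid)),
        "silhouettes": [None if np.isnan(s) else float(s)
                        for s in clustering.silhouettes],
        "cluster_of": clustering.cluster_of,
        "representatives": sorted(reps),
        "skipped_comparisons": results.attrs.get("skipped", []),
    }
    (outdir / "clustering_report.json").write_text(
        json.dumps(report, indent=1))
    return results, clustering, reps


def stage_explain(cfg: RunConfig, outdir: Path, features, kinds, profiles,
                  splits, clustering):
    """Per-fold forests + SHAP attribution on the strict held-out folds."""
    features = features.loc[profiles.index]
    continuous, indicators, _ = stats.preprocess(features, kinds)
    reps = stats.select_representatives(clustering, mode="random",
                                        seed=cfg.seed)
    X = pd.concat([continuous[sorted(reps)], indicators], axis=1)
    labels = profiles["reference"]
    fconfig = ForestConfig(n_trees=cfg.n_trees, max_depth=cfg.max_depth,
                           seed=cfg.seed,
                           recalibrate_threshold=cfg.recalibrate_threshold)
    # folds may reference transcripts excluded upstream; restrict them
    kept = set(X.index)
    for s in splits:
        s.train_ids_by_class = {k: [t for t in v if t in kept]
                                for k, v in s.train_ids_by_class.items()}
        s.heldout_ids_by_class = {k: [t for t in v if t in kept]
                                  for k, v in s.heldout_ids_by_class.items()}
    models = train_forests(X, labels, splits, fconfig)
    phi_by_fold, oof_metrics = [], []
    examples = {}
    for split, fm in zip(splits, models):
        held = [t for ids in split.heldout_ids_by_class.values() for t in ids]
        expl, phi_df, baseline = explain(fm, X.loc[held])
        phi_by_fold.append(phi_df)
        pred = fm.model.predict_proba(X.loc[held].to_numpy(float))[:, 1]
        lab = np.where(pred >= fm.threshold, unc.CODING, unc.LNCRNA)
        oof_metrics.append(unc.evaluate(lab, labels.loc[held]).as_dict())
        if not examples and expl:
            e = expl[0]
            examples[e.transcript_id] = {
                "baseline": e.baseline, "prediction": e.prediction,
                "top10": top_k_view(e, k=10)}
    summary = summarize_importance(phi_by_fold)
    summary.to_csv(outdir / "shap_global_importance.tsv", sep="\t")
    (outdir / "shap_examples.json").write_text(
        json.dumps(examples, indent=1))
    (outdir / "rf_oof_metrics.json").write_text(
        json.dumps(oof_metrics, indent=1))
    if cfg.embedding and X.shape[0] >= 3 * cfg.perplexity:
        coords = embed_2d(X.to_numpy(float), cfg.perplexity, cfg.tsne_iter,
                          cfg.seed)
        pd.DataFrame(coords, index=X.index, columns=["tsne1", "tsne2"]) \
            .to_csv(outdir / "embedding.tsv", sep="\t")
    return summary, phi_by_fold, models


def run_pipeline(cfg: RunConfig):
    """Execute all stages in order; returns the run manifest dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": asdict(cfg), "stages": [],
                "outputs": [], "input_digests": {}}

    def done(stage, **info):
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s complete", stage)

    try:
        if cfg.simulate:
            _, paths = stage_simulate(cfg, outdir)
            indir = outdir / "cohort"
            manifest["outputs"].extend(paths.values())
            done("simulate", n_artifacts=len(paths))
        else:
            if cfg.input_dir is None:
                raise FileNotFoundError(
                    "simulate=False requires input_dir with cohort artifacts")
            indir = Path(cfg.input_dir)
            for name in ("predictions.tsv", "features.tsv", "release_a.tsv",
                         "release_b.tsv", "clusters.clstr", "repeats.out",
                         "motifs.bed", "genes.tsv"):
                if not (indir / name).exists():
                    raise FileNotFoundError(f"missing input: {indir / name}")
        for name in sorted(p.name for p in indir.iterdir()):
            manifest["input_digests"][name] = _digest(indir / name)

        cohort_ids, ids_by_class, splits, csum = stage_cohort(
            cfg, indir, outdir)
        done("cohort", **{k: v for k, v in csum.items() if k != "per_fold"})
        manifest["cohort_summary"] = csum

        features, kinds = stage_features(cfg, indir, outdir, cohort_ids)
        done("features", n_features=int(features.shape[1]))

        profiles, thresholds, usum = stage_uncertainty(
            cfg, indir, outdir, cohort_ids)
        done("uncertainty", n_profiled=int(len(profiles)))

        results, clustering, reps = stage_enrich(
            cfg, outdir, features, kinds, profiles)
        done("enrich", n_tests=int(len(results)),
             n_clusters=clustering.n_clusters)

        summary, phi_by_fold, _ = stage_explain(
            cfg, outdir, features, kinds, profiles, splits, clustering)
        done("explain", top_feature=summary.index[0])
    except Exception as exc:
        failing = manifest["stages"][-1]["stage"] if manifest["stages"] \
            else "simulate"
        raise RuntimeError(
            f"pipeline failed after stage {failing!r}: {exc}") from exc

    for p in sorted(outdir.glob("*")):
        if p.is_file():
            manifest["outputs"].append(str(p))
    manifest["outputs"].append(str(outdir / "run_manifest.json"))
    manifest["outputs"] = sorted(set(manifest["outputs"]))
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
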