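"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator stands in for the real inputs (a GENCODE-derived transcript set
and eight retrained coding-potential classifiers) so that every downstream
stage is testable without downloads.  It emulates:

* an M-tool ensemble: each transcript carries a latent class signal
  s = (2c-1) * kappa * u, with u ~ U(0.3, 1) for core transcripts and
  u ~ U(0, 0.1) for a "boundary" subpopulation that sits near the
  coding/non-coding frontier; tool m emits p = logistic(lambda_m * s + eps),
  eps ~ N(0, sigma_m).  Boundary transcripts therefore produce high
  predictive entropy and inter-tool disagreement, core transcripts a
  calibrated consensus;
* correlated continuous feature blocks with class-dependent shifts (to
  exercise redundancy clustering and enrichment), plus independent noise
  features and class-dependent Bernoulli categoricals;
* two annotation releases with a label-churn fraction, a CD-HIT .clstr
  with planted near-duplicate groups, RepeatMasker .out and non-B DNA
  motif BED artifacts with planted intervals whose per-transcript summaries
  are recorded as ground truth for round-trip tests.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawn keys, so each artifact is independently reproducible and identical
seeds give byte-identical outputs.

Class proportions, transcript length medians (1620 nt coding, 1028 nt
lncRNA), the 0.30 / 0.70 repeat presence rates and the ~0.5% ensemble
missingness mirror the real cohort's headline descriptive statistics at
desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .uncertainty import CODING, LNCRNA
from .repeats import RepeatHit, write_repeatmasker_out
from .nbd import MotifCall, write_motif_bed, MOTIF_TYPES

__all__ = ["SimulationConfig", "SyntheticCohort", "generate_predictions",
           "generate_features", "generate_annotations", "generate_cohort",
           "write_cohort"]

# spawn keys of the per-artifact generators
_KEY_PRED, _KEY_FEAT, _KEY_ANNOT, _KEY_REP, _KEY_MOTIF, _KEY_SEQ = range(6)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort (defaults are the
    desk-scale analogue of the benchmarked dataset)."""

    n_coding: int = 3000
    n_lnc: int = 2040                      # lncRNA/PC = 0.68
    n_tools: int = 8
    boundary_fraction: float = 0.08
    signal_scale: float = 5.0
    tool_gain: tuple = (1.3, 1.15, 1.0, 0.9, 1.1, 0.8, 0.95, 1.05)
    tool_noise: tuple = (0.4, 0.5, 0.6, 1.2, 0.7, 0.9, 0.8, 0.6)
    missing_fraction: float = 0.005
    n_feature_blocks: int = 12
    block_sizes: tuple = (6, 5, 5, 4, 4, 3, 3, 3, 2, 2, 2, 1)
    block_class_shift: tuple = (2.0, 1.5, 1.2, 1.0, 0.8, 0.6, 0.5, 0.4,
                                0.3, 0.2, 0.0, 0.0)
    n_independent: int = 8
    n_categorical: int = 6
    categorical_rates: tuple = ((0.30, 0.70), (0.70, 0.30), (0.25, 0.55),
                                (0.50, 0.50), (0.10, 0.30), (0.60, 0.20))
    churn_fraction: float = 0.05
    novel_fraction: float = 0.05
    duplicate_fraction: float = 0.10
    repeat_presence: tuple = (0.30, 0.70)   # (coding, lncRNA)
    length_median: tuple = (1620.0, 1028.0)
    length_sigma: float = 0.6
    seed: int = 0

    def validate(self):
        for name in ("n_coding", "n_lnc", "n_tools", "n_feature_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("boundary_fraction", "missing_fraction",
                     "churn_fraction", "novel_fraction",
                     "duplicate_fraction"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0 <= v <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if not np.isfinite(self.signal_scale) or self.signal_scale <= 0:
            raise ValueError("signal_scale must be a positive real")
        gains = np.asarray(self.tool_gain, float)
        noises = np.asarray(self.tool_noise, float)
        if gains.size != self.n_tools or noises.size != self.n_tools:
            raise ValueError("tool_gain / tool_noise must have n_tools entries")
        if not np.all(np.isfinite(gains)) or np.any(gains <= 0):
            raise ValueError("tool gains must be positive and finite")
        if not np.all(np.isfinite(noises)) or np.any(noises < 0):
            raise ValueError("tool noises must be nonnegative and finite")
        if len(self.block_sizes) != self.n_feature_blocks:
            raise ValueError("block_sizes inconsistent with n_feature_blocks")
        if len(self.block_class_shift) != self.n_feature_blocks:
            raise ValueError("block_class_shift inconsistent with "
                             "n_feature_blocks")
        if len(self.categorical_rates) != self.n_categorical:
            raise ValueError("categorical_rates inconsistent with "
                             "n_categorical")
        return self

    def _rng(self, key):
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,)))

    @property
    def n_transcripts(self):
        return self.n_coding + self.n_lnc

    def transcript_ids(self):
        return [f"tx_{i:06d}" for i in range(self.n_transcripts)]

    def labels(self):
        """Reference labels (coding first, then lncRNA), as a Series."""
        labs = [CODING] * self.n_coding + [LNCRNA] * self.n_lnc
        return pd.Series(labs, index=self.transcript_ids(), name="reference")


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    reference_labels: pd.Series
    predictions: pd.DataFrame
    features: pd.DataFrame
    feature_kinds: dict
    release_a: pd.DataFrame
    release_b: pd.DataFrame
    clstr_text: str
    repeat_out: str
    motif_bed: str
    genes: pd.DataFrame
    fasta_records: list
    ground_truth: dict = field(default_factory=dict)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def generate_predictions(config: SimulationConfig):
    """Per-transcript tool coding probabilities and labels.

    Returns a DataFrame with transcript_id index, a ``reference`` column and
    prob_tool*/label_tool* columns; transcripts planted as unclassifiable by
    some tool carry NaN there.
    """
    config.validate()
    rng = config._rng(_KEY_PRED)
    labels = config.labels()
    n = config.n_transcripts
    c = (labels == CODING).to_numpy().astype(int)
    boundary = rng.random(n) < config.boundary_fraction
    u = np.where(boundary, rng.uniform(0.0, 0.1, n),
                 rng.uniform(0.3, 1.0, n))
    s = (2 * c - 1) * config.signal_scale * u
    out = pd.DataFrame({"reference": labels}, index=labels.index)
    gains = np.asarray(config.tool_gain, float)
    noises = np.asarray(config.tool_noise, float)
    for m in range(config.n_tools):
        eps = rng.normal(0.0, noises[m], n)
        p = _logistic(gains[m] * s + eps)
        out[f"prob_tool{m + 1}"] = p
    # plant per-transcript missingness (tools unable to score a transcript)
    n_missing = int(round(config.missing_fraction * n))
    missing_idx = rng.choice(n, size=n_missing, replace=False)
    for i in missing_idx:
        k = int(rng.integers(1, 3))  # 1 or 2 tools fail
        tools = rng.choice(config.n_tools, size=k, replace=False)
        for m in tools:
            out.iloc[i, out.columns.get_loc(f"prob_tool{m + 1}")] = np.nan
    for m in range(config.n_tools):
        p = out[f"prob_tool{m + 1}"]
        out[f"label_tool{m + 1}"] = np.where(
            p.isna(), None, np.where(p >= 0.5, CODING, LNCRNA))
    out.index.name = "transcript_id"
    out.attrs["ground_truth"] = {
        "boundary_ids": list(labels.index[boundary]),
        "missing_ids": list(labels.index[np.sort(missing_idx)]),
    }
    return out


def generate_features(config: SimulationConfig, labels=None):
    """Correlated feature blocks + independent + categorical features.

    Block b has a latent g ~ N(shift_b * (2c-1), 1); each member feature is
    g + N(0, 0.2), so within-block features are strongly rank-correlated.
    Returns (features DataFrame, kinds dict); block memberships are recorded
    in ``features.attrs["ground_truth"]``.
    """
    config.validate()
    if labels is None:
        labels = config.labels()
    rng = config._rng(_KEY_FEAT)
    n = len(labels)
    c = (np.asarray(labels) == CODING).astype(int)
    sign = 2 * c - 1
    cols, kinds, blocks_truth = {}, {}, {}
    for b, (size, shift) in enumerate(zip(config.block_sizes,
                                          config.block_class_shift)):
        g = rng.normal(shift * sign, 1.0, n)
        names = []
        for j in range(size):
            name = f"blk{b:02d}_f{j}"
            cols[name] = g + rng.normal(0.0, 0.2, n)
            kinds[name] = "continuous"
            names.append(name)
        blocks_truth[f"block_{b:02d}"] = {"members": names, "shift": shift}
    for j in range(config.n_independent):
        name = f"ind_f{j}"
        cols[name] = rng.normal(0.0, 1.0, n)
        kinds[name] = "continuous"
    for j, (rate_c, rate_l) in enumerate(config.categorical_rates):
        name = f"cat_f{j}"
        rate = np.where(c == 1, rate_c, rate_l)
        cols[name] = (rng.random(n) < rate).astype(int)
        kinds[name] = "categorical"
    feats = pd.DataFrame(cols, index=labels.index)
    feats.index.name = "transcript_id"
    feats.attrs["ground_truth"] = {"blocks": blocks_truth}
    return feats, kinds


def _lengths(config, labels, rng):
    c = (np.asarray(labels) == CODING).astype(int)
    med = np.where(c == 1, config.length_median[0], config.length_median[1])
    L = np.exp(rng.normal(np.log(med), config.length_sigma))
    return np.maximum(201, L.astype(int))


def _plant_repeats(config, labels, lengths, rng):
    """Plant non-overlapping repeat elements; return hits + per-tx truth."""
    classes_lnc = [("LINE", "L1"), ("LTR", "ERVL"), ("SINE", "Alu"),
                   ("DNA", "hAT"), ("Simple_repeat", ""),
                   ("Low_complexity", "")]
    w_lnc = np.array([0.30, 0.25, 0.20, 0.10, 0.10, 0.05])
    w_cod = np.array([0.10, 0.05, 0.15, 0.10, 0.35, 0.25])
    hits, truth = [], {}
    element_id = 0
    pres = dict(zip((CODING, LNCRNA), config.repeat_presence))
    for tx, lab, L in zip(labels.index, np.asarray(labels), lengths):
        L = int(L)
        planted = []  # non-overlapping (begin, end) 1-based inclusive
        tx_elements = set()
        if rng.random() < pres[lab]:
            n_elem = 1 + rng.poisson(0.8)
            cursor = 1
            for _ in range(n_elem):
                max_len = max(60, min(400, L // 3))
                elen = int(rng.integers(60, max_len + 1))
                gap = int(rng.integers(20, 200))
                b = cursor + gap
                e = b + elen - 1
                if e > L - 10:
                    break
                element_id += 1
                w = w_cod if lab == CODING else w_lnc
                cls, fam = classes_lnc[rng.choice(len(classes_lnc), p=w)]
                frag = elen > 160 and rng.random() < 0.3
                score = int(rng.integers(250, 2500))
                div = float(np.round(rng.uniform(0.0, 30.0), 1))
                if frag:
                    mid = b + elen // 2
                    fgap = int(rng.integers(10, 40))
                    spans = [(b, mid - fgap // 2), (mid + fgap // 2, e)]
                else:
                    spans = [(b, e)]
                for sb, se in spans:
                    hits.append(RepeatHit(
                        query_id=tx, begin=sb, end=se,
                        strand="+" if rng.random() < 0.5 else "C",
                        repeat_name=f"{cls or 'rep'}_{element_id}",
                        repeat_class=cls, repeat_family=fam,
                        sw_score=score, pct_div=div, pct_del=0.0,
                        pct_ins=0.0, element_id=element_id))
                    planted.append((sb, se))
                tx_elements.add(element_id)
                cursor = e
        planted.sort()
        covered = sum(e - b + 1 for b, e in planted)
        gaps = [planted[i + 1][0] - planted[i][1] - 1
                for i in range(len(planted) - 1)]
        if planted:
            free = gaps + [planted[0][0] - 1, L - planted[-1][1]]
            longest_free = max(free)
        else:
            longest_free = L
        truth[tx] = {
            "length": L,
            "hit_count": len(planted),
            "element_count": len(tx_elements),
            "coverage_fraction": covered / L,
            "max_gap": max(gaps) if gaps else 0,
            "longest_repeat_free": longest_free,
            "spans": planted,
        }
    return hits, truth


_MOTIF_RATE_PER_KB = {  # coding genes carry more non-B motifs (low-entropy side)
    CODING: {"G4": 0.30, "Z": 0.20, "STR": 0.40, "APR": 0.10, "DR": 0.20,
             "IR": 0.10, "MR": 0.20, "TRI": 0.05},
    LNCRNA: {"G4": 0.15, "Z": 0.10, "STR": 0.25, "APR": 0.06, "DR": 0.12,
             "IR": 0.06, "MR": 0.12, "TRI": 0.03},
}


def _plant_motifs(config, labels, lengths, rng):
    """Lay gene bodies along a pseudo-chromosome and plant motif calls."""
    genes_rows, calls, truth = [], [], {}
    cursor = 1000
    for tx, lab, L in zip(labels.index, np.asarray(labels), lengths):
        gene_id = tx.replace("tx_", "gn_")
        glen = int(L) * 3            # gene body (exons + introns)
        start, end = cursor, cursor + glen
        genes_rows.append({"gene_id": gene_id, "chrom": "chrS1",
                           "start": start, "end": end,
                           "transcript_id": tx})
        per_type = {}
        total_bp = 0
        for t in MOTIF_TYPES:
            lam = _MOTIF_RATE_PER_KB[lab][t] * glen / 1000.0
            k = rng.poisson(lam)
            per_type[t] = int(k)
            for _ in range(k):
                mlen = int(rng.integers(20, 200))
                s0 = int(rng.integers(start, max(start + 1, end - mlen)))
                e0 = min(s0 + mlen, end)
                calls.append(MotifCall("chrS1", s0, e0, t,
                                       float(np.round(rng.uniform(0, 100), 2))))
                total_bp += e0 - s0
        truth[gene_id] = {
            "gene_length": glen,
            "counts": per_type,
            "total_count": int(sum(per_type.values())),
            "total_coverage": total_bp / glen,
            "diversity": int(sum(1 for v in per_type.values() if v > 0)),
        }
        cursor = end + 500
    return pd.DataFrame(genes_rows), calls, truth


def _make_clusters(config, ids, lengths, rng):
    """Group a fraction of transcripts into near-duplicate CD-HIT clusters."""
    ids = list(ids)
    n = len(ids)
    n_dup = int(round(config.duplicate_fraction * n))
    dup_members = set(rng.choice(n, size=n_dup, replace=False).tolist())
    singles = [i for i in range(n) if i not in dup_members]
    dups = sorted(dup_members)
    # attach each duplicate to a random singleton-led cluster
    base = {i: [ids[i]] for i in singles}
    for i in dups:
        host = singles[int(rng.integers(len(singles)))]
        base[host].append(ids[i])
    clusters = [sorted(v) for v in base.values()]
    clusters.sort(key=lambda m: m[0])
    lines = []
    for ci, members in enumerate(clusters):
        lines.append(f">Cluster {ci}")
        for j, m in enumerate(members):
            tail = "*" if j == 0 else "at +/95.00%"
            lines.append(f"{j}\t{lengths[m]}nt, >{m}... {tail}")
    text = "\n".join(lines) + "\n"
    expected = set()
    for members in clusters:
        expected.add(min(members, key=lambda m: (-lengths[m], m)))
    return text, expected


def generate_annotations(config: SimulationConfig, labels=None):
    """Two annotation releases, .clstr, RepeatMasker .out, motif BED, FASTA.

    Returns a dict with keys release_a, release_b, clstr_text, repeat_out,
    motif_bed, genes, fasta_records, lengths and ground_truth.
    """
    config.validate()
    if labels is None:
        labels = config.labels()
    rng = config._rng(_KEY_ANNOT)
    lengths = _lengths(config, labels, rng)
    biotype = np.where(np.asarray(labels) == CODING,
                       "protein_coding", "lncRNA")
    rel_a = pd.DataFrame({
        "transcript_id": labels.index,
        "gene_id": [t.replace("tx_", "gn_") for t in labels.index],
        "biotype": biotype,
        "length": lengths,
    })
    n = len(labels)
    n_churn = int(round(config.churn_fraction * n))
    churn_idx = np.sort(rng.choice(n, size=n_churn, replace=False))
    bio_b = biotype.copy()
    flip = {"protein_coding": "lncRNA", "lncRNA": "protein_coding"}
    for i in churn_idx:
        bio_b[i] = flip[bio_b[i]]
    rel_b = rel_a.copy()
    rel_b["biotype"] = bio_b
    n_novel = int(round(config.novel_fraction * n))
    if n_novel:
        novel = pd.DataFrame({
            "transcript_id": [f"tx_n{i:06d}" for i in range(n_novel)],
            "gene_id": [f"gn_n{i:06d}" for i in range(n_novel)],
            "biotype": "lncRNA",
            "length": np.maximum(201, np.exp(
                rng.normal(np.log(config.length_median[1]),
                           config.length_sigma, n_novel)).astype(int)),
        })
        rel_b = pd.concat([rel_b, novel], ignore_index=True)
    length_map = dict(zip(rel_a["transcript_id"], rel_a["length"]))
    clstr_text, expected_reps = _make_clusters(config, labels.index,
                                               length_map, rng)
    rep_rng = config._rng(_KEY_REP)
    hits, repeat_truth = _plant_repeats(config, labels, lengths, rep_rng)
    repeat_out = write_repeatmasker_out(hits, length_map)
    motif_rng = config._rng(_KEY_MOTIF)
    genes, calls, motif_truth = _plant_motifs(config, labels, lengths,
                                              motif_rng)
    motif_bed = write_motif_bed(calls)
    seq_rng = config._rng(_KEY_SEQ)
    records = []
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    for tx, L in zip(labels.index, lengths):
        seq = b"".join(alphabet[seq_rng.integers(0, 4, int(L))])
        records.append(SeqRecord(Seq(seq.decode()), id=tx, description=""))
    stable = [t for i, t in enumerate(labels.index) if i not in set(churn_idx)]
    ground_truth = {
        "churned_ids": [labels.index[i] for i in churn_idx],
        "stable_ids": stable,
        "expected_representatives": sorted(expected_reps),
        "repeats": repeat_truth,
        "motifs": motif_truth,
    }
    return {
        "release_a": rel_a, "release_b": rel_b, "clstr_text": clstr_text,
        "repeat_out": repeat_out, "motif_bed": motif_bed, "genes": genes,
        "fasta_records": records, "lengths": length_map,
        "ground_truth": ground_truth,
    }


def generate_cohort(config: SimulationConfig):
    """Full synthetic cohort: predictions + features + annotation artifacts."""
    config.validate()
    labels = config.labels()
    preds = generate_predictions(config)
    feats, kinds = generate_features(config, labels)
    annot = generate_annotations(config, labels)
    gt = {
        "predictions": preds.attrs.get("ground_truth", {}),
        "features": feats.attrs.get("ground_truth", {}),
        **annot["ground_truth"],
    }
    return SyntheticCohort(
        config=config, reference_labels=labels, predictions=preds,
        features=feats, feature_kinds=kinds,
        release_a=annot["release_a"], release_b=annot["release_b"],
        clstr_text=annot["clstr_text"], repeat_out=annot["repeat_out"],
        motif_bed=annot["motif_bed"], genes=annot["genes"],
        fasta_records=annot["fasta_records"], ground_truth=gt,
    )


def write_cohort(cohort: SyntheticCohort, outdir):
    """Write every cohort artifact under ``outdir``; returns path dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name, writer):
        p = out / name
        writer(p)
        paths[name.split(".")[0]] = str(p)

    _write("predictions.tsv",
           lambda p: cohort.predictions.to_csv(p, sep="\t"))
    _write("features.tsv", lambda p: cohort.features.to_csv(p, sep="\t"))
    _write("feature_kinds.json", lambda p: p.write_text(
        json.dumps(cohort.feature_kinds, indent=1, sort_keys=True)))
    _write("release_a.tsv",
           lambda p: cohort.release_a.to_csv(p, sep="\t", index=False))
    _write("release_b.tsv",
           lambda p: cohort.release_b.to_csv(p, sep="\t", index=False))
    _write("clusters.clstr", lambda p: p.write_text(cohort.clstr_text))
    _write("repeats.out", lambda p: p.write_text(cohort.repeat_out))
    _write("motifs.bed", lambda p: p.write_text(cohort.motif_bed))
    _write("genes.tsv",
           lambda p: cohort.genes.to_csv(p, sep="\t", index=False))
    _write("transcripts.fasta",
           lambda p: SeqIO.write(cohort.fasta_records, str(p), "fasta"))
    _write("ground_truth.json", lambda p: p.write_text(
        json.dumps(cohort.ground_truth, indent=1, default=str)))
    _write("config.json", lambda p: p.write_text(
        json.dumps(asdict(cohort.config), indent=1, default=list)))
    return paths
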