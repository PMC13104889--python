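"""Label-stable, redundancy-reduced benchmark cohort and cross-validation folds.

The benchmark keeps transcripts whose biotype (protein_coding or lncRNA) is
identical in two annotation releases, reduces sequence redundancy by keeping
the longest member of each CD-HIT cluster, and builds k balanced
cross-validation folds: the minority class (lncRNA) is partitioned into k
held-out folds; each fold trains on the other k-1 minority partitions plus an
equal-size seeded sample of the majority class drawn outside that fold's
majority partition, and tests on everything else.  Each transcript therefore
has exactly one strict held-out fold, giving out-of-fold predictions that
evaluate every transcript once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BIOTYPE_SYNONYMS", "normalize_biotype", "read_biotype_table",
    "parse_gtf_biotypes", "intersect_releases", "parse_clstr",
    "select_representatives", "FoldSplit", "make_fold_splits",
    "fold_manifest",
]

DEFAULT_BIOTYPE_SYNONYMS = {
    "protein_coding": "protein_coding",
    "lncrna": "lncRNA",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
}


def normalize_biotype(value, synonyms=None):
    """Map a raw biotype string to {protein_coding, lncRNA, other}."""
    table = dict(DEFAULT_BIOTYPE_SYNONYMS)
    if synonyms:
        table.update(synonyms)
    return table.get(value, table.get(value.lower(), "other"))


def read_biotype_table(path):
    """Read a transcript/biotype TSV (transcript_id, biotype[, gene_id, length])."""
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns or "biotype" not in df.columns:
        raise ValueError("expected columns transcript_id and biotype")
    return df


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def parse_gtf_biotypes(path, synonyms=None, attribute="transcript_type"):
    """Extract transcript biotypes and spans from a GTF.

    Uses ``transcript`` lines; the biotype comes from the given attribute
    (``transcript_biotype`` tried as a fallback) and is normalized through
    the synonym map.  Length is the transcript-line span (end - start + 1).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "transcript":
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            bt = attrs.get(attribute) or attrs.get("transcript_biotype")
            if bt is None:
                continue
            rows.append({
                "transcript_id": attrs.get("transcript_id"),
                "gene_id": attrs.get("gene_id"),
                "biotype": normalize_biotype(bt, synonyms),
                "length": int(parts[4]) - int(parts[3]) + 1,
            })
    return pd.DataFrame(rows)


def intersect_releases(rel_a: pd.DataFrame, rel_b: pd.DataFrame):
    """Label-stable transcript ids across two releases.

    Keeps ids present in both tables whose biotype is protein_coding or
    lncRNA in both and identical across releases.  Duplicated ids within a
    release raise an error naming the first offender.
    """
    keep = {"protein_coding", "lncRNA"}
    frames = {}
    for tag, rel in (("a", rel_a), ("b", rel_b)):
        dup = rel["transcript_id"][rel["transcript_id"].duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicate transcript_id {dup.iloc[0]!r} in release {tag}")
        frames[tag] = rel.set_index("transcript_id")["biotype"]
    joined = pd.concat(frames, axis=1, join="inner")
    stable = joined[(joined["a"] == joined["b"]) & joined["a"].isin(keep)]
    return sorted(stable.index.tolist())


_CLSTR_MEMBER_RE = re.compile(r"^\d+\s+\d+(?:nt|aa),\s+>(.+?)\.{3}")


def parse_clstr(text):
    """Parse CD-HIT .clstr text into {cluster_id: [member ids]}."""
    clusters = {}
    current = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith(">Cluster"):
            try:
                current = int(line.split()[1])
            except (IndexError, ValueError):
                raise ValueError(f"malformed cluster header at line {lineno}")
            clusters[current] = []
        else:
            m = _CLSTR_MEMBER_RE.match(line)
            if m is None or current is None:
                raise ValueError(f"malformed .clstr line {lineno}: {line!r}")
            clusters[current].append(m.group(1))
    return clusters


def select_representatives(clstr_text, lengths):
    """Longest member per CD-HIT cluster (ties: lexicographically smallest id)."""
    clusters = parse_clstr(clstr_text)
    reps = set()
    for members in clusters.values():
        missing = [m for m in members if m not in lengths]
        if missing:
            raise KeyError(f"no length known for clustered id {missing[0]!r}")
        reps.add(min(members, key=lambda m: (-lengths[m], m)))
    return reps


@dataclass
class FoldSplit:
    fold_index: int
    k: int
    seed: int
    train_ids_by_class: dict
    test_ids_by_class: dict
    heldout_ids_by_class: dict  # strict out-of-fold partition slots


def _partition(ids, k):
    """Split a list into k contiguous chunks, remainder to lowest-index folds."""
    n = len(ids)
    base, rem = divmod(n, k)
    out, start = [], 0
    for f in range(k):
        size = base + (1 if f < rem else 0)
        out.append(ids[start:start + size])
        start += size
    return out


def make_fold_splits(ids_by_class, k=5, seed=0):
    """Balanced k-fold splits with the minority class fully used for training.

    Each class is shuffled (seeded) and partitioned into k folds.  For fold
    f, the training set is the minority class outside partition f plus an
    equal-size sample of the majority class drawn (seeded, without
    replacement) outside the majority partition f; the test set is the
    held-out minority partition plus every majority transcript not sampled
    for training.
    """
    if len(ids_by_class) != 2:
        raise ValueError("exactly two classes expected")
    if k < 2:
        raise ValueError("k must be at least 2 (no held-out partition otherwise)")
    (c1, ids1), (c2, ids2) = sorted(ids_by_class.items())
    if len(ids1) <= len(ids2):
        minority, majority = c1, c2
    else:
        minority, majority = c2, c1
    min_ids = sorted(ids_by_class[minority])
    maj_ids = sorted(ids_by_class[majority])
    if k > len(min_ids):
        raise ValueError(f"k={k} exceeds minority class size {len(min_ids)}")
    rng = np.random.default_rng(seed)
    min_ids = list(np.array(min_ids)[rng.permutation(len(min_ids))])
    maj_ids = list(np.array(maj_ids)[rng.permutation(len(maj_ids))])
    min_parts = _partition(min_ids, k)
    maj_parts = _partition(maj_ids, k)
    splits = []
    for f in range(k):
        train_min = [t for g in range(k) if g != f for t in min_parts[g]]
        pool = [t for g in range(k) if g != f for t in maj_parts[g]]
        n_train = len(train_min)
        if n_train > len(pool):
            raise ValueError("majority pool too small to balance training set")
        pick = rng.choice(len(pool), size=n_train, replace=False)
        train_maj = [pool[i] for i in sorted(pick)]
        taken = set(train_maj)
        test_maj = [t for t in maj_ids if t not in taken]
        splits.append(FoldSplit(
            fold_index=f, k=k, seed=seed,
            train_ids_by_class={minority: train_min, majority: train_maj},
            test_ids_by_class={minority: list(min_parts[f]),
                               majority: test_maj},
            heldout_ids_by_class={minority: list(min_parts[f]),
                                  majority: list(maj_parts[f])},
        ))
    return splits


def fold_manifest(splits):
    """Long-format fold manifest: transcript_id, class, fold, role."""
    rows = []
    for s in splits:
        for role, byclass in (("train", s.train_ids_by_class),
                              ("test", s.test_ids_by_class)):
            for cls, ids in byclass.items():
                rows.extend({"transcript_id": t, "class": cls,
                             "fold": s.fold_index, "role": role}
                            for t in ids)
        for cls, ids in s.heldout_ids_by_class.items():
            rows.extend({"transcript_id": t, "class": cls,
                         "fold": s.fold_index, "role": "heldout"}
                        for t in ids)
    return pd.DataFrame(rows)
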