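"""Non-B DNA motif features over gene bodies.

Motif calls (A-phased repeats, direct/inverted/mirror repeats, short tandem
repeats, Z-DNA, triplex motifs and G-quadruplexes) are genomic intervals in
0-based half-open BED coordinates.  Each call is assigned to every gene body
it overlaps by at least 1 bp (strand ignored), clipped to the gene for length
statistics; overlapping calls are retained without resolution, so total
coverage may exceed 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "MOTIF_TYPES", "MotifCall", "read_motif_bed", "write_motif_bed",
    "intersect_motifs", "compute_nbd_features", "NBD_FEATURE_SCHEMA",
    "nbd_feature_table",
]

MOTIF_TYPES = ("APR", "DR", "IR", "MR", "STR", "Z", "TRI", "G4")

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class MotifCall:
    chrom: str
    start: int          # 0-based
    end: int            # half-open
    motif_type: str
    score: float = np.nan
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("motif interval must satisfy start < end")
        if self.motif_type not in MOTIF_TYPES:
            raise ValueError(f"unknown motif type {self.motif_type!r}")


def read_motif_bed(path, motif_type=None):
    """Read motif calls from BED3/BED6 (type in column 4 unless given)."""
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.rstrip("\n").split("\t")
            mtype = motif_type or p[3]
            score = float(p[4]) if len(p) > 4 and p[4] != "." else np.nan
            strand = p[5] if len(p) > 5 else "."
            calls.append(MotifCall(p[0], int(p[1]), int(p[2]), mtype,
                                   score, strand))
    return calls


def write_motif_bed(calls):
    """Render motif calls as BED6 text (name column = motif type)."""
    lines = []
    for c in calls:
        score = "." if np.isnan(c.score) else f"{c.score:g}"
        lines.append(f"{c.chrom}\t{c.start}\t{c.end}\t{c.motif_type}"
                     f"\t{score}\t{c.strand}")
    return "\n".join(lines) + "\n"


def intersect_motifs(calls, genes: pd.DataFrame):
    """Assign motif calls to the gene bodies they overlap.

    ``genes`` needs columns gene_id, chrom, start, end (0-based half-open).
    Each call is clipped to the gene interval; a call overlapping several
    genes is assigned to each.  Calls on chromosomes absent from the gene
    table are skipped with a warning and counted.

    Returns (per-gene dict of clipped MotifCall lists, n_skipped).
    """
    trees = {}
    for _, g in genes.iterrows():
        trees.setdefault(g["chrom"], IntervalTree()).addi(
            int(g["start"]), int(g["end"]), g["gene_id"])
    assigned = {g: [] for g in genes["gene_id"]}
    n_skipped = 0
    for c in calls:
        tree = trees.get(c.chrom)
        if tree is None:
            n_skipped += 1
            continue
        for iv in tree.overlap(c.start, c.end):
            assigned[iv.data].append(MotifCall(
                c.chrom, max(c.start, iv.begin), min(c.end, iv.end),
                c.motif_type, c.score, c.strand))
    if n_skipped:
        logger.warning("%d motif calls on unknown chromosomes skipped",
                       n_skipped)
    return assigned, n_skipped


def _schema():
    fields = [
        ("total_count", "calls", "all motif calls on the gene body"),
        ("total_coverage", "fraction", "sum of clipped call lengths / gene "
                                       "length (overlaps retained; may "
                                       "exceed 1)"),
        ("diversity", "types", "number of distinct motif types present"),
    ]
    for t in MOTIF_TYPES:
        fields += [
            (f"presence_{t}", "flag", f"any {t} call"),
            (f"count_{t}", "calls", f"number of {t} calls"),
            (f"total_length_{t}", "bp", f"summed clipped {t} length"),
            (f"mean_length_{t}", "bp", f"mean clipped {t} length"),
            (f"max_gap_{t}", "bp", f"largest gap between consecutive {t} "
                                   f"calls (0 when overlapping)"),
            (f"mean_gap_{t}", "bp", f"mean gap between consecutive {t} calls"),
        ]
    return fields


NBD_FEATURE_SCHEMA = {
    "version": SCHEMA_VERSION,
    "fields": [{"name": n, "units": u, "description": d}
               for n, u, d in _schema()],
}


def compute_nbd_features(calls, gene_length):
    """Fixed-schema non-B DNA feature vector for one gene body.

    Overlapping calls are all counted (no resolution); per-type gap
    statistics use calls sorted by start with negative gaps clamped to 0.
    """
    if gene_length < 1:
        raise ValueError("gene_length must be >= 1")
    f = {name: 0.0 for name, _, _ in _schema()}
    total_bp = 0
    present = set()
    by_type = {}
    for c in calls:
        by_type.setdefault(c.motif_type, []).append(c)
    for t, group in by_type.items():
        lengths = [c.end - c.start for c in group]
        total_bp += sum(lengths)
        present.add(t)
        f[f"presence_{t}"] = 1.0
        f[f"count_{t}"] = float(len(group))
        f[f"total_length_{t}"] = float(sum(lengths))
        f[f"mean_length_{t}"] = float(np.mean(lengths))
        starts = sorted((c.start, c.end) for c in group)
        gaps = [max(0, starts[i + 1][0] - starts[i][1])
                for i in range(len(starts) - 1)]
        f[f"max_gap_{t}"] = float(max(gaps)) if gaps else 0.0
        f[f"mean_gap_{t}"] = float(np.mean(gaps)) if gaps else 0.0
    f["total_count"] = float(len(calls))
    f["total_coverage"] = total_bp / gene_length
    f["diversity"] = float(len(present))
    return f


def nbd_feature_table(calls, genes: pd.DataFrame):
    """Per-gene feature table for all genes (zero rows for empty genes)."""
    assigned, _ = intersect_motifs(calls, genes)
    lengths = {g["gene_id"]: int(g["end"]) - int(g["start"])
               for _, g in genes.iterrows()}
    rows = {g: compute_nbd_features(assigned[g], lengths[g])
            for g in assigned}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"
    return table
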