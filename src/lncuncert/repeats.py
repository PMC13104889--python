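"""RepeatMasker .out parsing and transcript-level repeat features.

Hits are parsed from the standard 15-column .out layout, overlaps on a
transcript are resolved by a greedy score-ranked rule (drop fully covered
candidates, trim partial overlaps to their largest uncovered segment),
fragments sharing a RepeatMasker element ID are aggregated into elements,
and a fixed-schema per-transcript feature vector is computed: counts,
coverage, per-class summaries, presence flags, fragmentation, inter-hit gap
statistics and the longest repeat-free stretch.  Coordinates are 1-based
inclusive throughout, as in RepeatMasker output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatHit", "REPEAT_CLASSES", "parse_repeatmasker_out",
    "write_repeatmasker_out", "resolve_overlaps", "aggregate_elements",
    "compute_repeat_features", "REPEAT_FEATURE_SCHEMA", "repeat_feature_table",
]

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "DNA", "Retroposon", "Simple_repeat",
                  "Low_complexity", "Satellite", "pseudogene", "Other")

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class RepeatHit:
    query_id: str
    begin: int               # 1-based inclusive
    end: int
    strand: str              # "+" or "C"
    repeat_name: str
    repeat_class: str
    repeat_family: str
    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    element_id: int
    overlap_marker: bool = False

    def __post_init__(self):
        if self.begin > self.end:
            raise ValueError(f"begin > end in hit on {self.query_id}")

    @property
    def length(self):
        return self.end - self.begin + 1


_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def _split_class(token):
    cls, _, fam = token.partition("/")
    canonical = {c.lower(): c for c in REPEAT_CLASSES}
    cls = canonical.get(cls.lower(), cls if cls in REPEAT_CLASSES else "Other")
    return cls, fam


def parse_repeatmasker_out(text):
    """Parse RepeatMasker .out text into a list of RepeatHit.

    The three header lines are skipped; each body line must have 15 columns
    (plus an optional trailing ``*`` overlap marker).
    """
    hits = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("SW") or s.startswith("score"):
            continue
        parts = s.split()
        marker = False
        if parts and parts[-1] == "*":
            marker = True
            parts = parts[:-1]
        if len(parts) != 15:
            raise ValueError(
                f"line {lineno}: expected 15 columns, got {len(parts)}")
        cls, fam = _split_class(parts[10])
        hits.append(RepeatHit(
            query_id=parts[4],
            begin=int(parts[5]),
            end=int(parts[6]),
            strand=parts[8],
            repeat_name=parts[9],
            repeat_class=cls,
            repeat_family=fam,
            sw_score=int(parts[0]),
            pct_div=float(parts[1]),
            pct_del=float(parts[2]),
            pct_ins=float(parts[3]),
            element_id=int(parts[14]),
            overlap_marker=marker,
        ))
    return hits


def write_repeatmasker_out(hits, lengths=None):
    """Render hits as RepeatMasker .out text (standard header + 15 columns)."""
    lines = [_OUT_HEADER.rstrip("\n")]
    for h in hits:
        left = ""
        if lengths and h.query_id in lengths:
            left = f"({lengths[h.query_id] - h.end})"
        else:
            left = "(0)"
        cf = h.repeat_class + (f"/{h.repeat_family}" if h.repeat_family else "")
        star = " *" if h.overlap_marker else ""
        lines.append(
            f"{h.sw_score:5d} {h.pct_div:5.1f} {h.pct_del:4.1f} "
            f"{h.pct_ins:4.1f}  {h.query_id} {h.begin:9d} {h.end:9d} "
            f"{left:>9s} {h.strand} {h.repeat_name:15s} {cf:20s} "
            f"{1:5d} {h.length:5d} (0) {h.element_id:5d}{star}")
    return "\n".join(lines) + "\n"


def _uncovered_segments(begin, end, accepted):
    """Sub-intervals of [begin, end] not covered by accepted (sorted) spans."""
    segs = []
    cur = begin
    for b, e in accepted:
        if e < cur or b > end:
            continue
        if b > cur:
            segs.append((cur, min(b - 1, end)))
        cur = max(cur, e + 1)
        if cur > end:
            break
    if cur <= end:
        segs.append((cur, end))
    return segs


def resolve_overlaps(hits):
    """Greedy score-ranked overlap resolution on one transcript.

    Hits are ranked by Smith-Waterman score (ties: longer span, then smaller
    begin) and accepted greedily.  A candidate fully covered by accepted
    spans is dropped; a partially covered candidate is trimmed to its
    largest single uncovered segment.  The result is non-overlapping and
    sorted by begin; the operation is idempotent.
    """
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("resolve_overlaps expects hits from one transcript")
    ranked = sorted(hits, key=lambda h: (-h.sw_score, -h.length, h.begin))
    accepted = []
    for h in ranked:
        spans = sorted((a.begin, a.end) for a in accepted)
        segs = _uncovered_segments(h.begin, h.end, spans)
        if not segs:
            continue
        b, e = max(segs, key=lambda s: (s[1] - s[0], -s[0]))
        accepted.append(h if (b, e) == (h.begin, h.end)
                        else replace(h, begin=b, end=e))
    return sorted(accepted, key=lambda h: h.begin)


def aggregate_elements(resolved):
    """Aggregate resolved fragments by RepeatMasker element ID.

    Returns a DataFrame (one row per element) with total length, fragment
    count, span, and the class/family/name of the highest-scoring fragment.
    Conflicting classes within an element keep the top-scoring one and log
    a warning.
    """
    rows = {}
    for h in resolved:
        key = h.element_id
        if key not in rows:
            rows[key] = {"element_id": key, "length": 0, "fragments": 0,
                         "begin": h.begin, "end": h.end, "best": h}
        r = rows[key]
        r["length"] += h.length
        r["fragments"] += 1
        r["begin"] = min(r["begin"], h.begin)
        r["end"] = max(r["end"], h.end)
        if h.repeat_class != r["best"].repeat_class:
            logger.warning("element %s mixes classes %s/%s; keeping top score",
                           key, r["best"].repeat_class, h.repeat_class)
        if (h.sw_score, h.length) > (r["best"].sw_score, r["best"].length):
            r["best"] = h
    out = []
    for r in rows.values():
        b = r["best"]
        out.append({"element_id": r["element_id"], "length": r["length"],
                    "fragments": r["fragments"], "begin": r["begin"],
                    "end": r["end"], "repeat_class": b.repeat_class,
                    "repeat_family": b.repeat_family,
                    "repeat_name": b.repeat_name, "sw_score": b.sw_score,
                    "pct_div": b.pct_div})
    return pd.DataFrame(out).sort_values("begin").reset_index(drop=True) \
        if out else pd.DataFrame(columns=[
            "element_id", "length", "fragments", "begin", "end",
            "repeat_class", "repeat_family", "repeat_name", "sw_score",
            "pct_div"])


def _schema():
    fields = [
        ("total_hit_count", "hits", "count of resolved hits"),
        ("total_element_count", "elements", "count of aggregated elements"),
        ("total_coverage_fraction", "fraction", "resolved bp / length"),
        ("hits_per_kb", "1/kb", "hit count * 1000 / length"),
        ("elements_per_kb", "1/kb", "element count * 1000 / length"),
        ("mean_divergence", "%", "mean pct_div over resolved hits"),
        ("mean_fragments_per_element", "fragments", "fragmentation"),
        ("max_fragments_per_element", "fragments", "fragmentation"),
        ("max_gap", "nt", "largest gap between consecutive resolved spans"),
        ("mean_gap", "nt", "mean gap between consecutive resolved spans"),
        ("longest_repeat_free", "nt", "longest stretch with no repeat, "
                                      "flanks included"),
    ]
    for cls in REPEAT_CLASSES:
        fields.append((f"count_{cls}", "hits", f"resolved hits of class {cls}"))
        fields.append((f"coverage_{cls}", "fraction",
                       f"bp of class {cls} / length"))
        fields.append((f"presence_{cls}", "flag",
                       f"any resolved hit of class {cls}"))
    return fields


REPEAT_FEATURE_SCHEMA = {
    "version": SCHEMA_VERSION,
    "fields": [{"name": n, "units": u, "description": d}
               for n, u, d in _schema()],
}


def compute_repeat_features(resolved, transcript_length):
    """Fixed-schema repeat feature vector for one transcript.

    ``resolved`` are non-overlapping hits (see :func:`resolve_overlaps`);
    gaps are measured between consecutive resolved spans and the longest
    repeat-free stretch includes the flanks.  Returns (features dict,
    family_counts dict).
    """
    if transcript_length < 1:
        raise ValueError("transcript_length must be >= 1")
    for h in resolved:
        if h.begin < 1 or h.end > transcript_length:
            raise ValueError(
                f"hit [{h.begin},{h.end}] outside transcript of length "
                f"{transcript_length}")
    spans = sorted((h.begin, h.end) for h in resolved)
    elements = aggregate_elements(resolved)
    covered = sum(e - b + 1 for b, e in spans)
    gaps = [spans[i + 1][0] - spans[i][1] - 1 for i in range(len(spans) - 1)]
    free = [g for g in gaps]
    if spans:
        free.append(spans[0][0] - 1)                      # 5' flank
        free.append(transcript_length - spans[-1][1])     # 3' flank
        longest_free = max(free)
    else:
        longest_free = transcript_length
    f = {name: 0.0 for name, _, _ in _schema()}
    f["total_hit_count"] = len(resolved)
    f["total_element_count"] = len(elements)
    f["total_coverage_fraction"] = covered / transcript_length
    f["hits_per_kb"] = len(resolved) * 1000.0 / transcript_length
    f["elements_per_kb"] = len(elements) * 1000.0 / transcript_length
    f["mean_divergence"] = (float(np.mean([h.pct_div for h in resolved]))
                            if resolved else 0.0)
    if len(elements):
        f["mean_fragments_per_element"] = float(elements["fragments"].mean())
        f["max_fragments_per_element"] = float(elements["fragments"].max())
    f["max_gap"] = float(max(gaps)) if gaps else 0.0
    f["mean_gap"] = float(np.mean(gaps)) if gaps else 0.0
    f["longest_repeat_free"] = float(longest_free)
    family_counts = {}
    for h in resolved:
        cls = h.repeat_class if h.repeat_class in REPEAT_CLASSES else "Other"
        f[f"count_{cls}"] += 1
        f[f"coverage_{cls}"] += h.length / transcript_length
        f[f"presence_{cls}"] = 1.0
        if h.repeat_family:
            key = f"{cls}/{h.repeat_family}"
            family_counts[key] = family_counts.get(key, 0) + 1
    return f, family_counts


def repeat_feature_table(hits, lengths):
    """Per-transcript feature table from raw hits for many transcripts.

    ``hits`` is an iterable of RepeatHit over any number of transcripts;
    ``lengths`` maps transcript id -> length.  Transcripts with no hits get
    all-zero rows (with longest_repeat_free = length).  Family counts become
    ``family_count_<class/family>`` columns over the union of observed
    families.
    """
    by_tx = {}
    for h in hits:
        by_tx.setdefault(h.query_id, []).append(h)
    rows, fam_rows = {}, {}
    for tx, length in lengths.items():
        resolved = resolve_overlaps(by_tx.get(tx, []))
        feats, fams = compute_repeat_features(resolved, length)
        rows[tx] = feats
        fam_rows[tx] = fams
    table = pd.DataFrame.from_dict(rows, orient="index")
    all_fams = sorted({k for d in fam_rows.values() for k in d})
    for fam in all_fams:
        table[f"family_count_{fam}"] = [fam_rows[tx].get(fam, 0)
                                        for tx in table.index]
    table.index.name = "transcript_id"
    return table
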