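"""Promoter-context annotation of sgRNA binding sites.

Works entirely in promoter-local, 0-based half-open coordinates: the input
is a table of predicted transcription-factor binding sites (TFBS) for a
promoter window, as exported by a motif-scanning tool, plus the sgRNA
protospacer intervals and the TSS position within the window. Provides

* single-linkage TFBS clustering — a cluster is a chain of >= 10 sites
  each overlapping or within 10 bp of the next;
* per-guide annotation — distance to TSS, distance to the nearest
  cluster, and the number of TFBS overlapping the site or within 50 /
  100 bp of it;
* the downstream association analyses — Pearson correlation of
  activation against a genomic covariate, and Welch's t-test between an
  externally supplied low/high grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TFBSRecord",
    "TFBSCluster",
    "GuideSiteAnnotation",
    "CorrelationResult",
    "read_tfbs_table",
    "detect_tfbs_clusters",
    "annotate_guide_site",
    "correlate_activation",
    "welch_split_test",
]


@dataclass(frozen=True)
class TFBSRecord:
    """One predicted binding-site interval (promoter-local, 0-based half-open)."""

    factor: str
    start: int
    end: int
    strand: str = "unknown"
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}) for {self.factor!r}")
        if self.strand not in {"+", "-", "unknown"}:
            raise ValueError(f"strand must be '+', '-' or 'unknown', got {self.strand!r}")


@dataclass(frozen=True)
class TFBSCluster:
    start: int
    end: int
    members: int


@dataclass(frozen=True)
class GuideSiteAnnotation:
    guide: str
    start: int
    end: int
    strand: str
    distance_to_tss: float
    distance_to_nearest_cluster: float | None  # None when no clusters exist
    n_overlap: int
    n_within_50: int
    n_within_100: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float  # NaN when undefined (zero variance)
    p: float
    n: int
    undefined: bool = False


# ---------------------------------------------------------------------------
# Input

def read_tfbs_table(path: str | Path, min_score: float | None = None) -> list[TFBSRecord]:
    """Read a TFBS table: headered TSV (factor/start/end[/strand/score]) or
    headerless 6-column BED in promoter-local coordinates.

    ``min_score`` optionally drops sites below a score threshold (the
    upstream prediction tool's stringency filter is otherwise assumed to
    have been applied already).
    """
    head = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    first = [str(v).strip().lower() for v in head.iloc[0]]
    records: list[TFBSRecord] = []
    if "factor" in first and "start" in first and "end" in first:
        df = pd.read_csv(path, sep="\t")
        df.columns = [str(c).strip().lower() for c in df.columns]
        for _, r in df.iterrows():
            score = float(r["score"]) if "score" in df.columns and pd.notna(r["score"]) else None
            strand = str(r["strand"]).strip() if "strand" in df.columns else "unknown"
            records.append(
                TFBSRecord(str(r["factor"]), int(r["start"]), int(r["end"]),
                           strand if strand in {"+", "-"} else "unknown", score)
            )
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] < 3:
            raise ValueError("BED-style TFBS input needs at least 3 columns")
        for _, r in df.iterrows():
            name = str(r[3]) if df.shape[1] > 3 else "TFBS"
            score = float(r[4]) if df.shape[1] > 4 and pd.notna(r[4]) else None
            strand = str(r[5]).strip() if df.shape[1] > 5 else "unknown"
            records.append(
                TFBSRecord(name, int(r[1]), int(r[2]),
                           strand if strand in {"+", "-"} else "unknown", score)
            )
    if min_score is not None:
        records = [t for t in records if t.score is not None and t.score >= min_score]
    return records


# ---------------------------------------------------------------------------
# Clustering

def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap between two half-open intervals; 0 when overlapping."""
    return max(0, a_start - b_end, b_start - a_end)


def detect_tfbs_clusters(
    tfbs: Iterable[TFBSRecord], min_members: int = 10, max_gap: int = 10
) -> list[TFBSCluster]:
    """Single-linkage chaining of TFBS intervals into dense clusters.

    Intervals overlapping or within ``max_gap`` bp of each other are merged
    transitively (A near B and B near C chains all three even if A and C
    are far apart); merged groups with >= ``min_members`` sites are
    reported as clusters, sorted by start. Order-invariant in the input.
    """
    sites = sorted(tfbs, key=lambda t: (t.start, t.end))
    clusters: list[TFBSCluster] = []
    if not sites:
        return clusters
    group_start, group_end, count = sites[0].start, sites[0].end, 1
    for t in sites[1:]:
        # sorted by start, so the chain criterion reduces to the gap
        # between this site and the running group's right edge
        if t.start - group_end <= max_gap:
            group_end = max(group_end, t.end)
            count += 1
        else:
            if count >= min_members:
                clusters.append(TFBSCluster(group_start, group_end, count))
            group_start, group_end, count = t.start, t.end, 1
    if count >= min_members:
        clusters.append(TFBSCluster(group_start, group_end, count))
    return clusters


# ---------------------------------------------------------------------------
# Annotation

def annotate_guide_site(
    guide: str,
    start: int,
    end: int,
    tss_position: int,
    tfbs: Sequence[TFBSRecord],
    clusters: Sequence[TFBSCluster],
    strand: str = "+",
) -> GuideSiteAnnotation:
    """Annotate one protospacer interval against the promoter TFBS map.

    Distance to TSS is measured from the site midpoint; distance to the
    nearest cluster is the edge-to-edge gap (0 when overlapping, ``None``
    when the cluster list is empty). Window counts are inclusive at the
    boundary and nested: overlapping sites count toward every window.
    """
    if not (0 <= start < end):
        raise ValueError(f"invalid site interval [{start}, {end})")
    mid = (start + end) / 2.0
    d_tss = abs(mid - tss_position)
    d_cluster: float | None = None
    if clusters:
        d_cluster = float(min(_gap(start, end, c.start, c.end) for c in clusters))
    n_overlap = n50 = n100 = 0
    for t in tfbs:
        g = _gap(start, end, t.start, t.end)
        if g == 0 and t.start < end and t.end > start:
            n_overlap += 1
        if g <= 50:
            n50 += 1
        if g <= 100:
            n100 += 1
    return GuideSiteAnnotation(
        guide=guide,
        start=start,
        end=end,
        strand=strand,
        distance_to_tss=d_tss,
        distance_to_nearest_cluster=d_cluster,
        n_overlap=n_overlap,
        n_within_50=n50,
        n_within_100=n100,
    )


# ---------------------------------------------------------------------------
# Association analyses

def correlate_activation(
    values: Mapping[str, float], covariate: Mapping[str, float]
) -> CorrelationResult:
    """Pearson correlation between per-condition activation and a covariate.

    Pairs on the shared condition labels; needs >= 3 paired observations.
    Zero variance in either vector yields an undefined (NaN) result with
    the ``undefined`` flag set rather than an exception.
    """
    keys = sorted(set(values) & set(covariate))
    if len(keys) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(keys)}")
    x = np.array([values[c] for c in keys], dtype=float)
    y = np.array([covariate[c] for c in keys], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(keys), undefined=True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(keys))


def welch_split_test(
    values: Mapping[str, float], grouping: Mapping[str, str]
) -> tuple[float, float, float]:
    """Welch's t-test (Satterthwaite df) between a low/high condition split.

    ``grouping`` assigns each condition a group label; exactly two labels
    must appear among the conditions present in ``values`` and each group
    needs >= 2 values. Returns ``(t, df, p)`` for the two-sided test.
    """
    buckets: dict[str, list[float]] = {}
    for cond, v in values.items():
        if cond in grouping:
            buckets.setdefault(grouping[cond], []).append(float(v))
    if len(buckets) != 2:
        raise ValueError(f"grouping must yield exactly 2 groups, got {sorted(buckets)}")
    (la, a), (lb, b) = sorted(buckets.items())
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values for Welch's t-test")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
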