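"""Cluster formation, bin counting and per-base profiles.

Tags overlapping by at least one nucleotide (same chromosome and strand) are
chained into CLIP clusters; singletons are discarded.  Clusters are tiled
into fixed-width bins whose rounded mean per-base tag coverage feeds the
first HMM, and enriched regions are profiled base by base — total tags x and
marker-mutation tags m — for the second HMM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from clipcall.alignment_io import Tag

__all__ = [
    "Cluster",
    "BinSeries",
    "BaseProfile",
    "form_clusters",
    "bin_counts",
    "base_profiles",
    "coverage_track",
]


@dataclass
class Cluster:
    """A strand-specific maximal group of >= 2 tags chained by >= 1-nt overlaps."""

    id: int
    chrom: str
    strand: str
    start: int
    end: int
    tags: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tag_count(self) -> int:
        return len(self.tags)

    def coverage(self) -> np.ndarray:
        """Per-base count of distinct tags covering each position of the hull."""
        cov = np.zeros(self.length, dtype=np.int64)
        for tag in self.tags:
            cov[tag.start - self.start : tag.end - self.start] += 1
        return cov

    def mutation_coverage(self) -> np.ndarray:
        """Per-base count of tags contributing a marker event at each position."""
        mut = np.zeros(self.length, dtype=np.int64)
        for tag in self.tags:
            for pos, _kind in tag.mutations:
                if self.start <= pos < self.end:
                    mut[pos - self.start] += 1
        return mut


@dataclass
class BinSeries:
    """Observation sequence of the first HMM: one count per fixed-width bin."""

    cluster_id: int
    bin_width: int
    counts: np.ndarray  # integer, length ceil(cluster length / bin_width)


@dataclass
class BaseProfile:
    """Observation sequence of the second HMM: (x, m) per base of a region."""

    region_id: int
    cluster_id: int
    chrom: str
    strand: str
    start: int
    x: np.ndarray  # total tags covering each base
    m: np.ndarray  # tags with a marker event at each base

    def __post_init__(self):
        if np.any(self.m > self.x):
            raise ValueError("mutant tag count exceeds total tag count")

    @property
    def end(self) -> int:
        return self.start + len(self.x)


def form_clusters(tags: Iterable[Tag], min_tags: int = 2) -> list[Cluster]:
    """Single-linkage grouping of tags sharing >= 1-nt overlap.

    Tags on different chromosomes or strands never merge.  Groups with fewer
    than ``min_tags`` members are discarded.  Cluster ids are assigned in
    (chrom, start) order and are stable under input permutation.
    """
    by_group: dict[tuple, list[Tag]] = {}
    for tag in tags:
        by_group.setdefault((tag.chrom, tag.strand), []).append(tag)

    clusters: list[Cluster] = []
    for (chrom, strand), members in by_group.items():
        members.sort(key=lambda t: (t.start, t.end))
        run: list[Tag] = []
        run_end = -1
        for tag in members:
            if run and tag.start >= run_end:  # half-open: touching = no overlap
                if len(run) >= min_tags:
                    clusters.append(
                        Cluster(0, chrom, strand, run[0].start, run_end, run)
                    )
                run, run_end = [], -1
            run.append(tag)
            run_end = max(run_end, tag.end)
        if len(run) >= min_tags:
            clusters.append(Cluster(0, chrom, strand, run[0].start, run_end, run))

    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    for idx, cluster in enumerate(clusters):
        cluster.id = idx
    return clusters


def bin_counts(cluster: Cluster, bin_width: int = 5) -> BinSeries:
    """Rounded mean per-base tag coverage in each bin of the cluster.

    Bins tile [start, end) left to right; the last bin may be short.
    Rounding is half-up so a bin with mean coverage 2.5 counts as 3.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    cov = cluster.coverage()
    n_bins = -(-cluster.length // bin_width)
    counts = np.empty(n_bins, dtype=np.int64)
    for t in range(n_bins):
        chunk = cov[t * bin_width : (t + 1) * bin_width]
        counts[t] = int(np.floor(chunk.mean() + 0.5))  # round half-up
    return BinSeries(cluster_id=cluster.id, bin_width=bin_width, counts=counts)


def base_profiles(
    region, cluster: Cluster, region_id: int | None = None
) -> BaseProfile:
    """Per-base (total, mutant) tag counts over an enriched region.

    ``region`` is anything with chrom/strand/start/end attributes (or a
    (start, end) tuple interpreted on the cluster); the interval must lie
    inside the cluster hull.
    """
    if isinstance(region, tuple):
        start, end = region
        rid = region_id if region_id is not None else 0
    else:
        start, end = region.start, region.end
        rid = region_id if region_id is not None else getattr(region, "id", 0)
    if start < cluster.start or end > cluster.end:
        raise ValueError(
            f"region [{start}, {end}) lies outside cluster "
            f"[{cluster.start}, {cluster.end})"
        )
    cov = cluster.coverage()
    mut = cluster.mutation_coverage()
    sl = slice(start - cluster.start, end - cluster.start)
    return BaseProfile(
        region_id=rid,
        cluster_id=cluster.id,
        chrom=cluster.chrom,
        strand=cluster.strand,
        start=start,
        x=cov[sl].copy(),
        m=mut[sl].copy(),
    )


def coverage_track(
    tags: Sequence[Tag], per_strand: bool = False
) -> list[tuple]:
    """Maximal constant-depth intervals for BedGraph output.

    Sweep-line over tag boundaries; zero-depth gaps are omitted and adjacent
    equal-depth intervals are merged.  Returns (chrom, start, end, depth)
    tuples, or (chrom, start, end, depth, strand) with ``per_strand``.
    """
    groups: dict[tuple, list[Tag]] = {}
    for tag in tags:
        key = (tag.chrom, tag.strand) if per_strand else (tag.chrom,)
        groups.setdefault(key, []).append(tag)

    out: list[tuple] = []
    for key in sorted(groups):
        members = groups[key]
        starts = np.sort([t.start for t in members])
        ends = np.sort([t.end for t in members])
        boundaries = np.unique(np.concatenate([starts, ends]))
        for left, right in zip(boundaries[:-1], boundaries[1:]):
            depth = int(
                np.searchsorted(starts, left, "right")
                - np.searchsorted(ends, left, "right")
            )
            if depth > 0:
                if per_strand:
                    out.append((key[0], int(left), int(right), depth, key[1]))
                else:
                    out.append((key[0], int(left), int(right), depth))
    return _merge_adjacent(out)


def _merge_adjacent(intervals: list[tuple]) -> list[tuple]:
    merged: list[list] = []
    for iv in intervals:
        if merged:
            prev = merged[-1]
            same_meta = prev[0] == iv[0] and prev[3:] == list(iv)[3:]
            if same_meta and prev[2] == iv[1]:
                prev[2] = iv[2]
                continue
        merged.append(list(iv))
    return [tuple(iv) for iv in merged]
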