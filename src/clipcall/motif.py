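"""Seed-motif validation utilities.

AGO clusters that represent real miRNA-guided binding should contain the
7-mer seed match (complement of miRNA positions 2-8) of abundant miRNAs
near the cross-link site.  These helpers scan cluster sequences for exact
motif occurrences, measure signed site-to-match distances, and compute
signal/noise enrichment of match percentages against length-matched
background sequences sampled away from the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MotifMatch",
    "EnrichmentResult",
    "scan_matches",
    "site_relative_distances",
    "signal_noise",
    "enrichment_table",
    "background_sample",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class MotifMatch:
    """One exact motif occurrence within one cluster sequence."""

    cluster_id: int
    motif: str
    start: int  # 0-based offset within the scanned (transcript-strand) sequence
    distance: float | None = None  # signed site -> match-center distance


@dataclass
class EnrichmentResult:
    """One row of the per-motif enrichment table."""

    motif: str
    n_clusters_with_match: int
    percent_clusters: float  # unrounded, in percent
    percent_background: float
    signal_noise: float  # computed from unrounded percentages

    def rounded(self) -> tuple[float, float, float]:
        """2-decimal presentation values (percentages and ratio)."""
        return (
            round(self.percent_clusters, 2),
            round(self.percent_background, 2),
            round(self.signal_noise, 2),
        )


def scan_matches(
    sequences: Mapping[int, str] | Sequence[str], motifs: Iterable[str]
) -> list[MotifMatch]:
    """All exact, possibly overlapping motif occurrences per sequence.

    ``sequences`` maps cluster id -> transcript-strand DNA sequence (a plain
    list is keyed by index).  N never matches.
    """
    if not isinstance(sequences, Mapping):
        sequences = dict(enumerate(sequences))
    motifs = [m.upper() for m in motifs]
    if not motifs or any(not m for m in motifs):
        raise ValueError("motifs must be non-empty strings")
    matches = []
    for cid, seq in sequences.items():
        seq = seq.upper()
        for motif in motifs:
            if "N" in motif:  # N is a wildcard-free unknown: it never matches
                continue
            start = seq.find(motif)
            while start != -1:
                matches.append(MotifMatch(cluster_id=cid, motif=motif, start=start))
                start = seq.find(motif, start + 1)
    return matches


def site_relative_distances(
    matches: Sequence[MotifMatch],
    sites_by_cluster: Mapping[int, Sequence[int]],
    max_distance: int = 100,
) -> list[MotifMatch]:
    """Signed distance from the nearest binding site to each match center.

    Positions are transcript-strand offsets within the cluster sequence,
    the same space the matches were scanned in.  Positive means the match
    center lies downstream of the site.  With several sites in a cluster the
    smallest-|distance| value is kept.  Matches farther than
    ``max_distance`` keep their distance but are conventionally excluded
    from positional density plots; matches in clusters without sites get
    ``distance=None``.
    """
    out = []
    for match in matches:
        sites = sites_by_cluster.get(match.cluster_id)
        annotated = MotifMatch(match.cluster_id, match.motif, match.start)
        if sites:
            center = match.start + (len(match.motif) - 1) / 2.0
            deltas = [center - site for site in sites]
            annotated.distance = min(deltas, key=abs)
        out.append(annotated)
    return out


def signal_noise(cluster_percent: float, background_percent: float) -> float:
    """Ratio of match percentages, clusters over background."""
    if background_percent <= 0:
        raise ValueError("background percentage must be positive")
    return cluster_percent / background_percent


def enrichment_table(
    cluster_sequences: Mapping[int, str] | Sequence[str],
    background_sequences: Sequence[str],
    motifs: Iterable[str],
) -> list[EnrichmentResult]:
    """Per-motif enrichment of cluster sequences over background.

    A sequence counts once per motif however many occurrences it contains.
    Ratios are computed from unrounded percentages; presentation rounding is
    left to :meth:`EnrichmentResult.rounded`.
    """
    if not isinstance(cluster_sequences, Mapping):
        cluster_sequences = dict(enumerate(cluster_sequences))
    n_clusters = len(cluster_sequences)
    n_background = len(background_sequences)
    if n_clusters == 0 or n_background == 0:
        raise ValueError("need non-empty cluster and background sets")
    results = []
    for motif in (m.upper() for m in motifs):
        with_match = sum(1 for s in cluster_sequences.values() if motif in s.upper())
        bg_match = sum(1 for s in background_sequences if motif in s.upper())
        pct_sig = 100.0 * with_match / n_clusters
        pct_bg = 100.0 * bg_match / n_background
        ratio = signal_noise(pct_sig, pct_bg) if pct_bg > 0 else float("inf")
        results.append(
            EnrichmentResult(
                motif=motif,
                n_clusters_with_match=with_match,
                percent_clusters=pct_sig,
                percent_background=pct_bg,
                signal_noise=ratio,
            )
        )
    return results


def background_sample(
    genome: Mapping[str, str],
    n: int,
    length: int,
    exclusion_intervals: Sequence[tuple] = (),
    seed: int = 0,
    max_tries_factor: int = 200,
) -> list[str]:
    """Sample n length-matched background sequences avoiding excluded regions.

    Positions are uniform over all chromosomes (weighted by eligible span);
    a draw overlapping any (chrom, start, end) exclusion interval, or
    containing N, is rejected.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    spans = np.array([max(len(genome[c]) - length + 1, 0) for c in chroms], dtype=float)
    if spans.sum() <= 0:
        raise ValueError("no chromosome long enough for the requested length")
    excl: dict[str, list[tuple]] = {}
    for chrom, start, end in exclusion_intervals:
        excl.setdefault(chrom, []).append((start, end))

    out: list[str] = []
    tries = 0
    max_tries = max_tries_factor * n
    probs = spans / spans.sum()
    while len(out) < n:
        if tries >= max_tries:
            raise ValueError(
                "could not place background sequences: exclusion intervals "
                "leave too little eligible genome"
            )
        tries += 1
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        start = int(rng.integers(0, len(genome[chrom]) - length + 1))
        end = start + length
        if any(start < e and s < end for s, e in excl.get(chrom, ())):
            continue
        seq = genome[chrom][start:end].upper()
        if "N" in seq:
            continue
        out.append(seq)
    return out
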