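"""Seed-deterministic synthetic CLIP-Seq datasets.

The generator emulates the generative assumptions of both decoding rounds:
cluster bin counts follow a two-component Poisson mixture with persistent
background/enriched state runs, and per-base marker-mutation counts follow a zero-inflated
binomial (background, rate p0, inflation phi) or a plain binomial (planted
cross-link sites, rate p1).  Output is a valid, re-ingestible SAM file over
a toy genome plus ground-truth BED files of the planted sites and enriched
regions.

Coverage realization: each cluster's per-bin target counts are decomposed
skyline-fashion into stacked tag intervals (one tag per coverage level and
run); duplicate-coordinate tags are made distinct by splitting them into
adjacent pieces at varying offsets, which leaves per-base coverage exactly
equal to the drawn bin counts.  Bin counts are zero-truncated so clusters
stay contiguous.  Tag-level PCR duplicates are injected separately to
exercise duplicate collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pysam
import yaml

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "sample_bin_counts",
    "sample_zib",
    "simulate_dataset",
    "simulate_null",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimulationConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation settings."""


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Defaults give the reference scenario: 500 clusters, enriched-bin mean
    coverage 30 over background 4, background mutation rate 0.01 with
    zero-inflation 0.3, cross-link mutation rate 0.25.
    """

    seed: int
    n_clusters: int = 500
    n_chroms: int = 2
    chrom_length: int = 150_000
    bin_width: int = 5
    min_bins: int = 16  # cluster span in bins, drawn uniformly
    max_bins: int = 40
    lambda0: float = 4.0  # background bin-count mean
    lambda1: float = 30.0  # enriched bin-count mean
    omega: float = 0.25  # long-run fraction of enriched bins
    mean_enriched_run: float = 9.0  # mean enriched run length, bins
    min_enriched_run: int = 6  # shortest enriched run (peak width floor)
    min_background_run: int = 2
    p0: float = 0.01
    phi: float = 0.3
    p1: float = 0.25
    site_fraction: float = 0.04  # fraction of enriched bases planted as sites
    marker: str = "deletion"  # or "substitution"
    substitution_pair: tuple = ("T", "C")
    duplicate_rate: float = 0.1  # per-tag probability of one PCR duplicate
    min_gap: int = 60  # bp between consecutive clusters
    max_gap: int = 200

    def __post_init__(self):
        if self.seed is None:
            raise SimulationConfigError("a seed is mandatory")
        if not 0 <= self.lambda0 < self.lambda1:
            raise SimulationConfigError("require 0 <= lambda0 < lambda1")
        for name in ("omega", "p0", "p1", "phi", "site_fraction", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name}={v} is not a probability")
        if not self.p1 > self.p0:
            raise SimulationConfigError("require p1 > p0")
        if self.marker not in ("deletion", "substitution"):
            raise SimulationConfigError("marker must be 'deletion' or 'substitution'")
        if not 2 <= self.min_bins <= self.max_bins:
            raise SimulationConfigError("require 2 <= min_bins <= max_bins")
        if self.mean_enriched_run < self.min_enriched_run:
            raise SimulationConfigError(
                "mean_enriched_run must be >= min_enriched_run"
            )
        bg_mean = self.mean_enriched_run * (1 - self.omega) / self.omega
        if bg_mean < self.min_background_run:
            raise SimulationConfigError(
                "omega too large for the configured run lengths"
            )
        # worst-case footprint must fit the genome
        worst = self.n_clusters * (self.max_bins * self.bin_width + self.max_gap)
        if worst > self.n_chroms * self.chrom_length:
            raise SimulationConfigError(
                f"{self.n_clusters} clusters of up to "
                f"{self.max_bins * self.bin_width} bp do not fit "
                f"{self.n_chroms} x {self.chrom_length} bp"
            )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["substitution_pair"] = tuple(data.get("substitution_pair", ("T", "C")))
        return cls(**data)


@dataclass
class SimulatedDataset:
    """Paths and ground truth of one simulated dataset."""

    sam_path: str
    sites_bed: str
    regions_bed: str
    genome: dict
    sites: list  # (chrom, position, strand)
    regions: list  # (chrom, start, end, strand)
    config: SimulationConfig
    n_reads: int = 0
    bin_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    n_skipped_levels: int = 0  # coverage levels unplaceable by the skyline


# -- elementary samplers (also used directly by the test suite) -------------


def sample_bin_counts(
    n: int, lambda0: float, lambda1: float, omega: float, rng: np.random.Generator
) -> np.ndarray:
    """n i.i.d. draws from the two-component Poisson mixture."""
    enriched = rng.random(n) < omega
    lam = np.where(enriched, lambda1, lambda0)
    return rng.poisson(lam)


def sample_zib(
    x: np.ndarray, p0: float, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-base zero-inflated binomial mutation counts for sizes x."""
    x = np.asarray(x)
    suppressed = rng.random(x.shape) < phi
    m = rng.binomial(x, p0)
    m[suppressed] = 0
    return m


def _sample_state_runs(
    n_bins: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Alternating background/enriched run lengths (geometric tails above a
    minimum duration) whose long-run enriched fraction is omega."""
    mean1 = config.mean_enriched_run
    mean0 = mean1 * (1 - config.omega) / config.omega
    geo1 = 1.0 / max(mean1 - config.min_enriched_run + 1.0, 1.0)
    geo0 = 1.0 / max(mean0 - config.min_background_run + 1.0, 1.0)
    states = np.empty(n_bins, dtype=int)
    state = int(rng.random() < config.omega)
    pos = 0
    while pos < n_bins:
        if state == 1:
            length = config.min_enriched_run + int(rng.geometric(geo1)) - 1
        else:
            length = config.min_background_run + int(rng.geometric(geo0)) - 1
        states[pos : pos + length] = state
        pos += length
        state = 1 - state
    # an enriched run truncated by the cluster edge below its minimum
    # duration would be an undetectable stub: make it background
    for side in (slice(None), slice(None, None, -1)):
        s = states[side]
        if s[0] == 1:
            run_len = int(np.argmax(s != 1)) or len(s)
            if run_len < config.min_enriched_run:
                s[:run_len] = 0
    return states


def _pyramid(values: np.ndarray) -> np.ndarray:
    """Rearrange counts into a unimodal profile (smallest at the edges).

    Preserves the multiset — the pooled marginal distribution is untouched —
    while keeping adjacent-bin differences small so the skyline
    decomposition can realize the profile with distinct tags, and giving
    runs the peaked shape of real tag pileups."""
    s = np.sort(values)
    left = s[0::2]
    right = s[1::2][::-1]
    return np.concatenate([left, right])


def _zero_truncated_poisson(
    lam: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Poisson conditioned on > 0 (keeps cluster coverage contiguous)."""
    out = rng.poisson(lam)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam[zero] if np.ndim(lam) else lam)
        zero = out == 0
    return out


# -- coverage realization ----------------------------------------------------


_GOLDEN = 0.6180339887498949


def _split_patterns(width: int):
    """Yield split-offset tuples in a deterministic order: no split, then
    single splits, then offset pairs.  Offsets follow a golden-ratio
    sequence so that successive levels cut at well-spread positions —
    clustering cuts at one base would starve that base of tags able to
    host an interior deletion."""
    yield ()
    order = sorted(range(1, width), key=lambda o: ((o * _GOLDEN) % 1.0, o))
    for off in order:
        yield (off,)
    for i, o1 in enumerate(order):
        for o2 in order[i + 1 :]:
            yield tuple(sorted((o1, o2)))


def _pieces(start: int, end: int, offsets: tuple) -> list[tuple]:
    cuts = [start] + [start + o for o in offsets] + [end]
    return list(zip(cuts[:-1], cuts[1:]))


def _skyline_tags(
    bin_counts: np.ndarray, start: int, bin_width: int
) -> tuple[list[tuple], int]:
    """Decompose a per-bin coverage profile into distinct tag intervals.

    One tag per coverage level and maximal run of bins at or above that
    level; coordinate collisions between levels are resolved by splitting a
    tag into adjacent pieces (coverage-preserving) at level-dependent
    offsets.  Returns (start, end) intervals whose per-base pileup equals
    the profile exactly, plus the count of levels that could not be placed
    (a narrow run supports at most one tag per distinct left endpoint, so a
    tall spike can exhaust its patterns; the resulting per-bin deficit of
    one count per skipped level is rare and tracked).
    """
    used: set[tuple] = set()
    tags: list[tuple] = []
    skipped = 0
    max_level = int(bin_counts.max(initial=0))
    for level in range(1, max_level + 1):
        above = bin_counts >= level
        padded = np.concatenate([[False], above, [False]])
        run_starts = np.flatnonzero(~padded[:-1] & padded[1:])
        run_ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for a, b in zip(run_starts, run_ends):
            s = start + int(a) * bin_width
            e = start + int(b) * bin_width
            placed = False
            for offsets in _split_patterns(e - s):
                pieces = _pieces(s, e, offsets)
                if all(p not in used for p in pieces):
                    used.update(pieces)
                    tags.extend(pieces)
                    placed = True
                    break
            if not placed:
                skipped += 1
    return tags, skipped


# -- SAM record assembly -----------------------------------------------------


def _build_alignment(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    tid: int,
    strand: str,
    start: int,
    end: int,
    deletions: list[int],
    substitutions: list[int],
    genome_seq: str,
) -> pysam.AlignedSegment:
    """One aligned read with the given marker events encoded in CIGAR/MD/SEQ."""
    deletions = sorted(set(deletions))
    substitutions = sorted(set(substitutions))

    cigar: list[tuple] = []
    seq_parts: list[str] = []
    md_parts: list[str] = []
    match_run = 0
    pos = start
    del_set = set(deletions)
    sub_set = set(substitutions)
    while pos < end:
        if pos in del_set:
            md_parts.append(f"{match_run}^")
            match_run = 0
            run = []
            while pos < end and pos in del_set:
                run.append(genome_seq[pos])
                pos += 1
            md_parts.append("".join(run))
            cigar.append((2, len(run)))
        else:
            base = genome_seq[pos]
            if pos in sub_set:
                read_base = _substituted_base(base, strand)
                md_parts.append(f"{match_run}{base}")
                match_run = 0
                seq_parts.append(read_base)
                # mismatches are M in CIGAR
                if cigar and cigar[-1][0] == 0:
                    cigar[-1] = (0, cigar[-1][1] + 1)
                else:
                    cigar.append((0, 1))
            else:
                seq_parts.append(base)
                match_run += 1
                if cigar and cigar[-1][0] == 0:
                    cigar[-1] = (0, cigar[-1][1] + 1)
                else:
                    cigar.append((0, 1))
            pos += 1
    md_parts.append(str(match_run))

    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.flag = 16 if strand == "-" else 0
    read.reference_id = tid
    read.reference_start = start
    read.mapping_quality = 60
    read.cigartuples = cigar
    read.query_sequence = "".join(seq_parts)
    read.query_qualities = pysam.qualitystring_to_array("I" * len(read.query_sequence))
    read.set_tag("MD", "".join(md_parts))
    read.set_tag("NM", len(deletions) + len(substitutions))
    return read


def _substituted_base(ref_base: str, strand: str) -> str:
    # transcript-strand T->C marker: genomic T->C on +, A->G on -
    if strand == "+":
        return "C" if ref_base == "T" else ref_base
    return "G" if ref_base == "A" else ref_base


# -- main entry points -------------------------------------------------------


def simulate_dataset(config: SimulationConfig, out_dir: str) -> SimulatedDataset:
    """Generate one dataset: SAM reads plus ground-truth BED files.

    Deterministic for a fixed config (same seed, byte-identical output).
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = {
        name: "".join(rng.choice(_BASES, size=config.chrom_length))
        for name in chrom_names
    }
    genome_arrays = {name: np.array(list(seq)) for name, seq in genome.items()}

    bw = config.bin_width
    sites: list[tuple] = []
    regions: list[tuple] = []
    reads: list[dict] = []
    all_bin_counts: list[np.ndarray] = []

    chrom_idx = 0
    cursor = 0
    n_skipped_levels = 0
    for _k in range(config.n_clusters):
        n_bins = int(rng.integers(config.min_bins, config.max_bins + 1))
        span = n_bins * bw
        gap = int(rng.integers(config.min_gap, config.max_gap + 1))
        if cursor + gap + span > config.chrom_length:
            chrom_idx += 1
            cursor = 0
            if chrom_idx >= config.n_chroms:
                raise SimulationConfigError("clusters overflow the genome")
        chrom = chrom_names[chrom_idx]
        start = cursor + gap
        cursor = start + span
        strand = "+" if rng.random() < 0.5 else "-"

        states = _sample_state_runs(n_bins, config, rng)
        lam = np.where(states == 1, config.lambda1, config.lambda0)
        counts = _zero_truncated_poisson(lam, rng)
        # unimodal arrangement within each state run (multiset-preserving)
        boundaries = np.concatenate(
            [[0], np.flatnonzero(np.diff(states) != 0) + 1, [n_bins]]
        )
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            counts[a:b] = _pyramid(counts[a:b])
        all_bin_counts.append(counts)

        # ground-truth enriched regions: maximal state-1 runs
        padded = np.concatenate([[0], states, [0]])
        for a, b in zip(
            np.flatnonzero(np.diff(padded) == 1), np.flatnonzero(np.diff(padded) == -1)
        ):
            regions.append((chrom, start + int(a) * bw, start + int(b) * bw, strand))

        tag_intervals, skipped = _skyline_tags(counts, start, bw)
        n_skipped_levels += skipped

        # per-base coverage and mutation planning; sites stay >= 2 bp inside
        # their run (the cross-link sits within the protein footprint, and
        # run-boundary bases are tag edges that cannot carry a deletion)
        coverage = np.repeat(counts, bw)
        enriched_base = np.repeat(states == 1, bw)
        plantable = enriched_base.copy()
        edges = np.flatnonzero(np.diff(enriched_base.astype(int)))
        for e in edges:
            plantable[max(e - 1, 0) : e + 3] = False
        if enriched_base[0]:
            plantable[:2] = False
        if enriched_base[-1]:
            plantable[-2:] = False
        is_site = plantable & (rng.random(span) < config.site_fraction)
        m = sample_zib(coverage, config.p0, config.phi, rng)
        m[is_site] = rng.binomial(coverage[is_site], config.p1)

        if config.marker == "substitution":
            ref_marker = config.substitution_pair[0]
            if strand == "-":
                ref_marker = _COMPLEMENT[ref_marker]
            arr = genome_arrays[chrom]
            for b in np.flatnonzero(m > 0):
                arr[start + b] = ref_marker
            genome[chrom] = "".join(arr)

        for b in np.flatnonzero(is_site & (coverage > 0)):
            sites.append((chrom, start + int(b), strand))

        tag_records = [
            {"start": s, "end": e, "dels": [], "subs": []} for s, e in tag_intervals
        ]
        for b in np.flatnonzero(m > 0):
            pos = start + int(b)
            if config.marker == "deletion":
                eligible = [
                    t for t in tag_records if t["start"] < pos < t["end"] - 1
                ]
                key = "dels"
            else:
                eligible = [t for t in tag_records if t["start"] <= pos < t["end"]]
                key = "subs"
            take = min(int(m[b]), len(eligible))
            for idx in rng.choice(len(eligible), size=take, replace=False):
                eligible[int(idx)][key].append(pos)

        for t in tag_records:
            t["chrom"] = chrom
            t["strand"] = strand
            copies = 1 + int(rng.random() < config.duplicate_rate)
            t["copies"] = copies
            reads.append(t)

    # -- write SAM (coordinate sorted) --------------------------------------
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": config.chrom_length} for name in chrom_names
            ],
        }
    )
    sam_path = out / "reads.sam"
    n_reads = 0
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as fh:
        order = sorted(
            range(len(reads)),
            key=lambda i: (reads[i]["chrom"], reads[i]["start"], reads[i]["end"]),
        )
        for i in order:
            rec = reads[i]
            tid = chrom_names.index(rec["chrom"])
            for copy in range(rec["copies"]):
                read = _build_alignment(
                    header,
                    f"sim{i:07d}.{copy}",
                    rec["chrom"],
                    tid,
                    rec["strand"],
                    rec["start"],
                    rec["end"],
                    rec["dels"],
                    rec["subs"],
                    genome[rec["chrom"]],
                )
                fh.write(read)
                n_reads += 1

    sites_bed = out / "truth_sites.bed"
    with open(sites_bed, "w") as fh:
        for chrom, pos, strand in sorted(sites):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tsite\t0\t{strand}\n")
    regions_bed = out / "truth_regions.bed"
    with open(regions_bed, "w") as fh:
        for chrom, rstart, rend, strand in sorted(regions):
            fh.write(f"{chrom}\t{rstart}\t{rend}\tenriched\t0\t{strand}\n")

    return SimulatedDataset(
        sam_path=str(sam_path),
        sites_bed=str(sites_bed),
        regions_bed=str(regions_bed),
        genome=genome,
        sites=sorted(sites),
        regions=sorted(regions),
        config=config,
        n_reads=n_reads,
        bin_counts=np.concatenate(all_bin_counts),
        n_skipped_levels=n_skipped_levels,
    )


def simulate_null(config: SimulationConfig, out_dir: str) -> SimulatedDataset:
    """Same generative process with zero planted sites (background only)."""
    null_config = SimulationConfig(
        **{**asdict(config), "site_fraction": 0.0}
    )
    null_config.substitution_pair = tuple(null_config.substitution_pair)
    return simulate_dataset(null_config, out_dir)
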