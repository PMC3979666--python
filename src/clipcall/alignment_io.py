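"""Alignment input: SAM/BAM reading, duplicate collapsing, marker-mutation extraction.

CLIP-Seq reads carry diagnostic "marker" mutations at cross-link positions:
deletions for AGO/Nova-type HITS-CLIP, T->C substitutions for 4SU PAR-CLIP,
or user-defined combinations.  This module turns aligned records into
deduplicated :class:`Tag` objects annotated with the genomic positions of
their marker events.  Coordinates are 0-based half-open throughout (SAM's
1-based starts are converted on input).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

logger = logging.getLogger(__name__)

MUTATION_KINDS = frozenset({"deletion", "insertion", "substitution"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ConfigurationError(ValueError):
    """Raised when the mutation specification cannot be applied to the input."""


class FastqParseError(ValueError):
    """Raised for a malformed FASTQ record, naming its index."""


@dataclass(frozen=True)
class MutationSpec:
    """Which mutation types count as cross-link markers.

    Parameters
    ----------
    kinds
        Non-empty subset of {"deletion", "insertion", "substitution"}.
    substitution_pairs
        For restricted substitution markers, the (ref, alt) base pairs in
        transcript-strand space, e.g. {("T", "C")} for 4SU PAR-CLIP.  ``None``
        with substitution in ``kinds`` counts every mismatch.
    strand_aware
        If true, substitutions on minus-strand reads are evaluated after
        reverse-complementing both bases, so a genomic A->G on a minus-strand
        read counts as T->C.
    """

    kinds: frozenset = frozenset({"deletion"})
    substitution_pairs: frozenset | None = None
    strand_aware: bool = True

    def __post_init__(self):
        kinds = frozenset(self.kinds)
        object.__setattr__(self, "kinds", kinds)
        if not kinds:
            raise ConfigurationError("at least one mutation kind is required")
        unknown = kinds - MUTATION_KINDS
        if unknown:
            raise ConfigurationError(f"unknown mutation kinds: {sorted(unknown)}")
        if self.substitution_pairs is not None:
            pairs = frozenset(
                (r.upper(), a.upper()) for r, a in self.substitution_pairs
            )
            object.__setattr__(self, "substitution_pairs", pairs)
            if "substitution" not in kinds:
                raise ConfigurationError(
                    "substitution_pairs given but substitution not in kinds"
                )


@dataclass(frozen=True)
class ReadRecord:
    """A mapped read reduced to what tag building needs."""

    chrom: str
    strand: str  # "+" or "-"
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    mutations: tuple = ()  # ((genomic position, kind), ...)


@dataclass
class Tag:
    """A deduplicated mapped fragment.

    ``multiplicity`` counts how many identical-coordinate reads were
    collapsed; ``mutations`` is the union of marker events across the
    duplicates, each genomic position at most once, so a tag contributes at
    most one mutant count per base.
    """

    chrom: str
    strand: str
    start: int
    end: int
    multiplicity: int = 1
    mutations: list = field(default_factory=list)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty tag interval [{self.start}, {self.end})")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_marker_mutations(
    read: pysam.AlignedSegment, spec: MutationSpec
) -> list[tuple[int, str]]:
    """Genomic positions of each marker event on one aligned read.

    Deletions report every deleted reference base; insertions report the
    reference base immediately 5' (on the + strand) of the inserted sequence;
    substitutions report the mismatched reference base.  Substitution
    detection needs mismatch information: an MD tag or a reader opened with a
    reference.
    """
    events: list[tuple[int, str]] = []
    want_del = "deletion" in spec.kinds
    want_ins = "insertion" in spec.kinds
    want_sub = "substitution" in spec.kinds

    if want_del or want_ins:
        ref_pos = read.reference_start
        for op, length in read.cigartuples or ():
            if op in (0, 7, 8):  # M, =, X consume both
                ref_pos += length
            elif op == 2:  # D: deleted reference bases
                if want_del:
                    events.extend((ref_pos + i, "deletion") for i in range(length))
                ref_pos += length
            elif op == 3:  # N skips reference
                ref_pos += length
            elif op == 1:  # I: anchored to base left of the insertion
                if want_ins and ref_pos > read.reference_start:
                    events.append((ref_pos - 1, "insertion"))
            # S, H, P consume no reference

    if want_sub:
        if not read.has_tag("MD"):
            raise ConfigurationError(
                "substitution markers requested but read has no MD tag and no "
                "reference sequence was supplied"
            )
        is_reverse = read.is_reverse
        seq = read.query_sequence
        for qpos, rpos, ref_base in read.get_aligned_pairs(matches_only=True, with_seq=True):
            ref_base = ref_base.upper()
            read_base = seq[qpos].upper()
            if read_base == ref_base or "N" in (read_base, ref_base):
                continue
            pair = (ref_base, read_base)
            if spec.strand_aware and is_reverse:
                pair = (
                    ref_base.translate(_COMPLEMENT),
                    read_base.translate(_COMPLEMENT),
                )
            if spec.substitution_pairs is None or pair in spec.substitution_pairs:
                events.append((rpos, "substitution"))

    events.sort()
    return events


def _to_record(read: pysam.AlignedSegment, spec: MutationSpec) -> ReadRecord:
    strand = "-" if read.is_reverse else "+"
    return ReadRecord(
        chrom=read.reference_name,
        strand=strand,
        start=read.reference_start,
        end=read.reference_end,
        mutations=tuple(extract_marker_mutations(read, spec)),
    )


def iter_read_records(
    path: str, spec: MutationSpec, mode: str | None = None
) -> Iterator[ReadRecord]:
    """Stream mapped primary records from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped (multi-hit
    reads are expected to be absent already, but secondary flags are dropped
    defensively).  Paired-end data is resolved to one record per fragment:
    the leftmost mate of a proper pair defines the fragment interval via the
    template length, takes its strand from read 1, and carries its own
    marker events.
    """
    skipped = 0
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                skipped += 1
                continue
            if read.is_paired:
                if not read.is_proper_pair:
                    skipped += 1
                    continue
                # fragment = leftmost mate start .. start + |TLEN|
                if read.template_length <= 0:
                    continue  # mate handles the fragment
                rec = _to_record(read, spec)
                frag_strand = rec.strand if read.is_read1 else ("-" if rec.strand == "+" else "+")
                yield ReadRecord(
                    chrom=rec.chrom,
                    strand=frag_strand,
                    start=rec.start,
                    end=rec.start + read.template_length,
                    mutations=rec.mutations,
                )
            else:
                yield _to_record(read, spec)
    if skipped:
        logger.info("skipped %d unmapped/secondary/supplementary records", skipped)


def collapse_duplicates(records: Iterable[ReadRecord]) -> list[Tag]:
    """Collapse reads with identical (chrom, strand, start, end) into tags.

    Marker events are unioned across duplicates, each genomic position kept
    at most once per tag (PCR duplicates must not multiply-count a base).
    Tags are returned sorted by (chrom, strand, start, end).
    """
    buckets: dict[tuple, dict] = {}
    for rec in records:
        key = (rec.chrom, rec.strand, rec.start, rec.end)
        entry = buckets.setdefault(key, {"n": 0, "muts": set()})
        entry["n"] += 1
        entry["muts"].update(rec.mutations)
    tags = []
    for (chrom, strand, start, end), entry in sorted(buckets.items()):
        # one event per genomic position per tag
        seen: dict[int, str] = {}
        for pos, kind in sorted(entry["muts"]):
            seen.setdefault(pos, kind)
        tags.append(
            Tag(
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                multiplicity=entry["n"],
                mutations=sorted(seen.items()),
            )
        )
    return tags


def read_tags(path: str, spec: MutationSpec) -> list[Tag]:
    """Read a SAM/BAM file and return collapsed, mutation-annotated tags."""
    return collapse_duplicates(iter_read_records(path, spec))


# -- BED round trip ----------------------------------------------------------


def write_tags_bed(tags: Sequence[Tag], path: str) -> None:
    with open(path, "w") as fh:
        for tag in tags:
            fh.write(
                f"{tag.chrom}\t{tag.start}\t{tag.end}\t"
                f"tag\t{min(tag.multiplicity, 1000)}\t{tag.strand}\n"
            )


def read_tags_bed(path: str) -> list[Tag]:
    tags = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, _name, score, strand = line.rstrip("\n").split("\t")[:6]
            tags.append(
                Tag(chrom=chrom, strand=strand, start=int(start), end=int(end),
                    multiplicity=max(int(score), 1))
            )
    return tags


# -- 3' adapter trimming -----------------------------------------------------


def trim_read(seq: str, adapter: str, min_overlap: int) -> int:
    """Return the trim point: index where the adapter begins, or len(seq).

    The longest read suffix exactly matching a prefix of the adapter
    (overlap >= min_overlap) wins; failing that, a full internal adapter
    occurrence trims there together with everything 3' of it.
    """
    la = len(adapter)
    n = len(seq)
    for i in range(max(n - la, 0), n - min_overlap + 1):
        if adapter.startswith(seq[i:]):
            return i
    hit = seq.find(adapter)
    if hit != -1:
        return hit
    return n


def trim_adapter(
    fastq_records: Iterable[tuple],
    adapter: str,
    min_overlap: int = 5,
    min_length: int = 15,
) -> Iterator[tuple]:
    """Trim a 3' adapter from (id, sequence, quality) FASTQ tuples.

    Reads whose trimmed length falls below ``min_length`` are dropped.
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    adapter = adapter.upper()
    for idx, rec in enumerate(fastq_records):
        try:
            name, seq, qual = rec
        except (TypeError, ValueError) as exc:
            raise FastqParseError(f"malformed FASTQ record at index {idx}") from exc
        if len(seq) != len(qual):
            raise FastqParseError(
                f"sequence/quality length mismatch in FASTQ record {idx}"
            )
        cut = trim_read(seq.upper(), adapter, min_overlap)
        if cut >= min_length:
            yield (name, seq[:cut], qual[:cut])


def parse_fastq(path: str) -> Iterator[tuple]:
    """Yield (id, sequence, quality) tuples from a FASTQ file."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 and lines[-1] == "":
        lines = lines[:-1]
    for idx in range(0, len(lines) - 3, 4):
        header, seq, plus, qual = lines[idx : idx + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise FastqParseError(f"malformed FASTQ record at index {idx // 4}")
        yield (header[1:].split()[0], seq, qual)


def trim_fastq_file(
    path_in: str,
    path_out: str,
    adapter: str,
    min_overlap: int = 5,
    min_length: int = 15,
) -> int:
    """Trim a FASTQ file on disk; returns the number of reads written."""
    n = 0
    with open(path_out, "w") as out:
        for name, seq, qual in trim_adapter(
            parse_fastq(path_in), adapter, min_overlap, min_length
        ):
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n
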