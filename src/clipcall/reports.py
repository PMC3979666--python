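"""Report writers: BED6, BedGraph, site TSV and a JSON run summary.

Every file begins with comment lines carrying the run's configuration
fingerprint and seed so outputs can be traced back to their settings.
BED scores are posterior probabilities scaled to the conventional 0-1000
integer range.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence


def _header_lines(fingerprint: str, seed) -> str:
    return f"# clipcall run fingerprint={fingerprint} seed={seed}\n"


def bed_score(posterior: float) -> int:
    return int(min(max(round(1000 * posterior), 0), 1000))


def write_clusters_bed(clusters, path, fingerprint="-", seed="-", flags=None):
    """Clusters as BED6; the name field carries enrichment/site flags
    ("cluster<id>|enriched=0/1|sites=0/1") when ``flags`` maps cluster id to
    (has_enriched, has_sites)."""
    with open(path, "w") as fh:
        fh.write(_header_lines(fingerprint, seed))
        for c in clusters:
            name = f"cluster{c.id}"
            if flags is not None:
                enr, sit = flags.get(c.id, (False, False))
                name += f"|enriched={int(enr)}|sites={int(sit)}"
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t"
                f"{min(c.tag_count, 1000)}\t{c.strand}\n"
            )


def write_regions_bed(regions, path, fingerprint="-", seed="-"):
    """Enriched regions as BED6 with the parent cluster id in the name."""
    with open(path, "w") as fh:
        fh.write(_header_lines(fingerprint, seed))
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t"
                f"region{r.id}|cluster{r.cluster_id}\t0\t{r.strand}\n"
            )


def write_sites(sites, bed_path, tsv_path, fingerprint="-", seed="-"):
    """Sites as BED6 (score = 1000 * posterior) plus a full TSV table."""
    with open(bed_path, "w") as fh:
        fh.write(_header_lines(fingerprint, seed))
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t"
                f"site|cluster{s.cluster_id}\t{bed_score(s.score)}\t{s.strand}\n"
            )
    with open(tsv_path, "w") as fh:
        fh.write(_header_lines(fingerprint, seed))
        fh.write(
            "chrom\tposition\tstrand\ttotal_tags\tmutant_tags\t"
            "posterior\tregion_id\tcluster_id\n"
        )
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.strand}\t{s.x}\t{s.m}\t"
                f"{s.score:.6f}\t{s.region_id}\t{s.cluster_id}\n"
            )


def write_bedgraph(intervals: Sequence[tuple], path, fingerprint="-", seed="-"):
    """(chrom, start, end, depth[, strand]) tuples as BedGraph."""
    with open(path, "w") as fh:
        fh.write(_header_lines(fingerprint, seed))
        fh.write('track type=bedGraph name="clipcall coverage"\n')
        for iv in intervals:
            chrom, start, end, depth = iv[:4]
            fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


def read_bedgraph(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            chrom, start, end, depth = line.split()[:4]
            out.append((chrom, int(start), int(end), int(depth)))
    return out


def write_summary_json(summary: dict, path):
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
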