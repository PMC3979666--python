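"""End-to-end pipeline: alignment -> clusters -> enrichment -> sites -> reports.

Stage order and products:

1. read and collapse the alignment into tags (marker events attached),
2. chain overlapping tags into strand-specific clusters,
3. decode enriched bins per cluster with the Poisson-mixture HMM and merge
   them into enriched regions,
4. profile the regions base by base and decode cross-link sites with the
   ZIB/binomial HMM,
5. optionally estimate a permutation FDR and apply the control-sample SNP
   filter,
6. write BED/BedGraph/TSV/JSON reports.

Per-stage counts (tags, clusters, bins, enriched regions, sites) are logged
at INFO and returned in the run summary, mirroring how real datasets are
usually reported.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from clipcall import binding, clustering, enrichment, error_control, reports
from clipcall.alignment_io import MutationSpec, read_tags

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exit_code: int, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; round-trips through YAML."""

    input_path: str
    output_dir: str = "clipcall_out"
    mutation_kinds: tuple = ("deletion",)
    substitution_pair: tuple | None = None  # e.g. ("T", "C") for PAR-CLIP
    strand_aware: bool = True
    bin_width: int = 5
    truncation_cutoff: float | None = None  # None: 99.5th percentile of counts
    c: float = 0.5  # split parameter of the second round
    persistence: float = 0.5  # HMM state stickiness rho
    decoding: str = "viterbi"  # or "posterior"
    min_score: float | None = None  # optional posterior floor for reporting
    fdr_permutations: int = 10
    seed: int = 0
    control_path: str | None = None
    min_control_rate: float = 0.25
    min_control_coverage: int = 5

    def mutation_spec(self) -> MutationSpec:
        pairs = (
            frozenset({tuple(self.substitution_pair)})
            if self.substitution_pair
            else None
        )
        return MutationSpec(
            kinds=frozenset(self.mutation_kinds),
            substitution_pairs=pairs,
            strand_aware=self.strand_aware,
        )

    def fingerprint(self) -> str:
        blob = yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha1(blob.encode()).hexdigest()[:10]

    def to_yaml(self, path: str) -> None:
        data = {
            k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("mutation_kinds", "substitution_pair"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineResult:
    tags: list
    clusters: list
    bin_series: list
    poisson_params: enrichment.PoissonMixtureParams
    enriched_labels: list
    regions: list
    profiles: list
    mutation_params: binding.MutationMixtureParams
    sites: list
    removed_sites: list = field(default_factory=list)
    fdr: error_control.FdrEstimate | None = None
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(
    config: RunConfig, write_outputs: bool = True, run_fdr: bool = True
) -> PipelineResult:
    """Execute all stages on one alignment file.

    Raises :class:`PipelineError` carrying the failing stage name and a
    machine-readable exit code (2 config, 3 input parse, 4 estimation,
    5 internal consistency).
    """
    try:
        spec = config.mutation_spec()
    except Exception as exc:
        raise PipelineError("config", 2, str(exc)) from exc

    try:
        tags = read_tags(config.input_path, spec)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("alignment_io", 3, str(exc)) from exc
    logger.info("tags: %d", len(tags))

    clusters = clustering.form_clusters(tags)
    logger.info("clusters (>=2 tags): %d", len(clusters))
    if not clusters:
        raise PipelineError("clustering", 5, "no clusters formed from input tags")

    series = [clustering.bin_counts(c, config.bin_width) for c in clusters]
    pooled = np.concatenate([s.counts for s in series])
    logger.info("bins: %d", pooled.size)

    try:
        poisson_params = enrichment.estimate_poisson_mixture(
            pooled, cutoff=config.truncation_cutoff
        )
    except enrichment.EstimationError as exc:
        raise PipelineError("enrichment", 4, str(exc)) from exc
    logger.info(
        "Poisson mixture: lambda0=%.3f lambda1=%.3f omega=%.4f cutoff=%.1f",
        poisson_params.lambda0,
        poisson_params.lambda1,
        poisson_params.omega,
        poisson_params.cutoff,
    )

    labels = enrichment.infer_enriched(
        series, poisson_params, persistence=config.persistence
    )
    regions = enrichment.merge_enriched_regions(labels, clusters, config.bin_width)
    logger.info(
        "enriched regions: %d in %d clusters",
        len(regions),
        len({r.cluster_id for r in regions}),
    )

    cluster_by_id = {c.id: c for c in clusters}
    profiles = [
        clustering.base_profiles(r, cluster_by_id[r.cluster_id], region_id=r.id)
        for r in regions
    ]
    n_bases = sum(len(p.x) for p in profiles)
    logger.info("profiled bases: %d", n_bases)

    try:
        mutation_params = binding.fit_mutation_mixture(profiles, c=config.c)
    except (binding.ModeEstimationError, binding.ModelOrderError) as exc:
        raise PipelineError("binding", 4, str(exc)) from exc
    logger.info(
        "mutation mixture: p0=%.4g phi=%.3f p1=%.4g theta=%.4g",
        mutation_params.p0,
        mutation_params.phi,
        mutation_params.p1,
        mutation_params.theta,
    )

    sites = binding.infer_binding_sites(
        profiles,
        mutation_params,
        persistence=config.persistence,
        decoding=config.decoding,
        min_score=config.min_score,
    )
    logger.info(
        "binding sites: %d in %d clusters",
        len(sites),
        error_control.count_significant_clusters(sites),
    )

    fdr = None
    if run_fdr and config.fdr_permutations > 0:
        fdr = error_control.permutation_fdr(
            profiles,
            sites,
            n_perm=config.fdr_permutations,
            seed=config.seed,
            c=config.c,
            persistence=config.persistence,
            decoding=config.decoding,
        )
        logger.info(
            "permutation FDR: %s (observed=%d, permuted mean=%.1f)",
            "NA" if fdr.fdr is None else f"{fdr.fdr:.3f}",
            fdr.observed,
            fdr.permuted_mean,
        )

    removed: list = []
    if config.control_path:
        sites, removed = error_control.snp_filter(
            sites,
            config.control_path,
            spec,
            min_control_rate=config.min_control_rate,
            min_control_coverage=config.min_control_coverage,
        )
        logger.info("SNP filter removed %d sites", len(removed))

    # referential integrity: site -> region -> cluster
    region_by_id = {r.id: r for r in regions}
    for s in sites:
        r = region_by_id.get(s.region_id)
        if r is None or not (r.start <= s.position < r.end) or r.cluster_id != s.cluster_id:
            raise PipelineError(
                "reports", 5, f"site at {s.chrom}:{s.position} lost its parent region"
            )

    stage_counts = {
        "tags": len(tags),
        "mapped_read_records": sum(t.multiplicity for t in tags),
        "clusters": len(clusters),
        "bins": int(pooled.size),
        "enriched_regions": len(regions),
        "enriched_clusters": len({r.cluster_id for r in regions}),
        "profiled_bases": n_bases,
        "binding_sites": len(sites),
        "significant_clusters": error_control.count_significant_clusters(sites),
        "snp_removed_sites": len(removed),
    }

    result = PipelineResult(
        tags=tags,
        clusters=clusters,
        bin_series=series,
        poisson_params=poisson_params,
        enriched_labels=labels,
        regions=regions,
        profiles=profiles,
        mutation_params=mutation_params,
        sites=sites,
        removed_sites=removed,
        fdr=fdr,
        stage_counts=stage_counts,
    )
    if write_outputs:
        write_reports(result, config)
    return result


def write_reports(result: PipelineResult, config: RunConfig) -> dict:
    """Write every report file; returns a name -> path mapping."""
    out = Path(config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise PipelineError("reports", 3, f"output directory not writable: {exc}")

    fp = config.fingerprint()
    seed = config.seed
    enriched_clusters = {r.cluster_id for r in result.regions}
    site_clusters = {s.cluster_id for s in result.sites}
    flags = {
        c.id: (c.id in enriched_clusters, c.id in site_clusters)
        for c in result.clusters
    }

    paths = {
        "clusters_bed": out / "clusters.bed",
        "regions_bed": out / "enriched_regions.bed",
        "sites_bed": out / "sites.bed",
        "sites_tsv": out / "sites.tsv",
        "bedgraph": out / "coverage.bedgraph",
        "removed_bed": out / "snp_removed_sites.bed",
        "summary_json": out / "summary.json",
        "config_yaml": out / "run_config.yaml",
    }
    reports.write_clusters_bed(result.clusters, paths["clusters_bed"], fp, seed, flags)
    reports.write_regions_bed(result.regions, paths["regions_bed"], fp, seed)
    reports.write_sites(result.sites, paths["sites_bed"], paths["sites_tsv"], fp, seed)
    track = clustering.coverage_track(
        [t for c in result.clusters for t in c.tags]
    )
    reports.write_bedgraph(track, paths["bedgraph"], fp, seed)
    with open(paths["removed_bed"], "w") as fh:
        fh.write(f"# clipcall run fingerprint={fp} seed={seed}\n")
        for s in result.removed_sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\tsnp_removed\t"
                f"{reports.bed_score(s.score)}\t{s.strand}\n"
            )

    summary = {
        "fingerprint": fp,
        "seed": seed,
        "stage_counts": result.stage_counts,
        "poisson_mixture": {
            "lambda0": result.poisson_params.lambda0,
            "lambda1": result.poisson_params.lambda1,
            "omega": result.poisson_params.omega,
            "cutoff": result.poisson_params.cutoff,
        },
        "mutation_mixture": {
            "p0": result.mutation_params.p0,
            "phi": result.mutation_params.phi,
            "p1": result.mutation_params.p1,
            "theta": result.mutation_params.theta,
            "c": result.mutation_params.c,
        },
        "fdr": None
        if result.fdr is None
        else {
            "observed": result.fdr.observed,
            "permuted_mean": result.fdr.permuted_mean,
            "fdr": result.fdr.fdr,
            "n_permutations": result.fdr.n_permutations,
        },
    }
    reports.write_summary_json(summary, paths["summary_json"])
    config.to_yaml(paths["config_yaml"])
    return {k: str(v) for k, v in paths.items()}
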