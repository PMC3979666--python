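"""Dataset-level error control: permutation FDR and SNP-artifact filtering.

The FDR procedure jointly shuffles the per-base (m, x) observation pairs
across all enriched regions — pairs stay intact so m <= x always holds —
re-fits and re-decodes the second-round model on each permutation, and
reports the mean permuted count of significant clusters over the observed
count.  The enrichment stage is not re-run: permutation operates on the
second stage's inputs.

SNP filtering removes sites whose marker mutation recurs in a non-cross-
linked control alignment at sufficient rate and coverage; genuine genomic
variants mutate control reads too, cross-link artifacts do not.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from clipcall import binding
from clipcall.alignment_io import MutationSpec, iter_read_records

logger = logging.getLogger(__name__)

__all__ = ["FdrEstimate", "permutation_fdr", "snp_filter", "count_significant_clusters"]


@dataclass
class FdrEstimate:
    """Permutation false-discovery-rate summary."""

    observed: int  # clusters with >= 1 reliable site in the observed data
    permuted_mean: float  # mean such count over permutations
    fdr: float | None  # min(permuted_mean / observed, 1); None if observed == 0
    n_permutations: int
    seed: int
    permuted_counts: tuple = ()


def count_significant_clusters(sites: Sequence[binding.BindingSite]) -> int:
    return len({s.cluster_id for s in sites})


def _fit_and_count(profiles, c: float, persistence: float, decoding: str) -> int:
    try:
        params = binding.fit_mutation_mixture(profiles, c=c)
    except (binding.ModeEstimationError, binding.ModelOrderError):
        return 0  # no separable cross-link component: nothing significant
    sites = binding.infer_binding_sites(
        profiles, params, persistence=persistence, decoding=decoding
    )
    return count_significant_clusters(sites)


def permutation_fdr(
    profiles: Sequence,
    observed_sites: Sequence[binding.BindingSite],
    n_perm: int = 10,
    seed: int = 0,
    c: float = 0.5,
    persistence: float = 0.5,
    decoding: str = "viterbi",
) -> FdrEstimate:
    """Estimate the FDR of the binding stage by joint (m, x) permutation.

    Parameters
    ----------
    profiles
        The base profiles of the enriched regions the observed sites came
        from.
    observed_sites
        Sites called on the unpermuted data (the binding stage must already
        have been run).
    n_perm
        Number of permutations; each re-fits and re-decodes the model.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = count_significant_clusters(observed_sites)

    all_m = np.concatenate([p.m for p in profiles])
    all_x = np.concatenate([p.x for p in profiles])
    lengths = [len(p.m) for p in profiles]
    pair_multiset = sorted(zip(all_m.tolist(), all_x.tolist()))

    counts = []
    for _ in range(n_perm):
        order = rng.permutation(len(all_m))
        perm_m, perm_x = all_m[order], all_x[order]
        assert sorted(zip(perm_m.tolist(), perm_x.tolist())) == pair_multiset
        perm_profiles = []
        offset = 0
        for p, ln in zip(profiles, lengths):
            q = copy.copy(p)
            q.m = perm_m[offset : offset + ln]
            q.x = perm_x[offset : offset + ln]
            offset += ln
            perm_profiles.append(q)
        counts.append(_fit_and_count(perm_profiles, c, persistence, decoding))

    permuted_mean = float(np.mean(counts))
    if observed == 0:
        logger.warning("no significant clusters observed: FDR is undefined")
        fdr = None
    else:
        fdr = min(permuted_mean / observed, 1.0)
    return FdrEstimate(
        observed=observed,
        permuted_mean=permuted_mean,
        fdr=fdr,
        n_permutations=n_perm,
        seed=seed,
        permuted_counts=tuple(counts),
    )


def snp_filter(
    sites: Sequence[binding.BindingSite],
    control_path: str,
    spec: MutationSpec,
    min_control_rate: float = 0.25,
    min_control_coverage: int = 5,
) -> tuple[list, list]:
    """Split sites into (kept, removed) using a control alignment.

    A site is removed when the control sample shows the same marker mutation
    at the same position with mutation rate >= ``min_control_rate`` and
    coverage >= ``min_control_coverage``; such positions behave like genomic
    variants rather than cross-link artifacts.  Removed sites are returned,
    not discarded silently.
    """
    wanted = {(s.chrom, s.position) for s in sites}
    coverage: dict[tuple, int] = {}
    mutated: dict[tuple, int] = {}
    n_control = 0
    for rec in iter_read_records(control_path, spec):
        n_control += 1
        mut_positions = {pos for pos, _ in rec.mutations}
        for chrom, pos in wanted:
            if chrom == rec.chrom and rec.start <= pos < rec.end:
                key = (chrom, pos)
                coverage[key] = coverage.get(key, 0) + 1
                if pos in mut_positions:
                    mutated[key] = mutated.get(key, 0) + 1

    if n_control == 0:
        logger.warning("control alignment is empty: all sites retained")
        return list(sites), []

    kept, removed = [], []
    for site in sites:
        key = (site.chrom, site.position)
        cov = coverage.get(key, 0)
        mut = mutated.get(key, 0)
        if cov >= min_control_coverage and cov > 0 and mut / cov >= min_control_rate:
            removed.append(site)
        else:
            kept.append(site)
    return kept, removed
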