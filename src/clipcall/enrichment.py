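"""First-round model: enriched vs. non-enriched bins.

Bin-level tag counts pooled over all clusters are fitted with a
two-component Poisson mixture — lambda0 for background bins, lambda1 for
enriched bins, mixing weight omega — by the method of moments on the first
three factorial moments.  Each cluster's bin series is then decoded
independently by the two-state HMM and maximal runs of enriched bins are
concatenated into enriched regions.

Extreme bin counts are winsorized at a user cutoff (default: the 99.5th
percentile of the pooled counts) before both estimation and decoding; this
is the model's first and only tuning parameter besides the second round's
split point c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from clipcall import hmm
from clipcall.clustering import BinSeries, Cluster

__all__ = [
    "PoissonMixtureParams",
    "EnrichedRegion",
    "EstimationError",
    "winsorize_counts",
    "estimate_poisson_mixture",
    "poisson_mixture_emission",
    "infer_enriched",
    "merge_enriched_regions",
]


class EstimationError(RuntimeError):
    """Moment system has no admissible solution for these counts."""


@dataclass
class PoissonMixtureParams:
    """Fitted two-component Poisson mixture for bin counts."""

    lambda0: float  # background bin-count mean
    lambda1: float  # enriched bin-count mean
    omega: float  # proportion of enriched bins
    cutoff: float  # winsorization threshold applied to counts

    def __post_init__(self):
        if not 0.0 <= self.lambda0 < self.lambda1:
            raise ValueError("parameters must satisfy 0 <= lambda0 < lambda1")
        if not 0.0 < self.omega < 1.0:
            raise ValueError("omega must lie in (0, 1)")


@dataclass
class EnrichedRegion:
    """A maximal run of enriched bins, mapped back to genome coordinates."""

    id: int
    cluster_id: int
    chrom: str
    strand: str
    start: int
    end: int


def winsorize_counts(counts: np.ndarray, cutoff: float) -> np.ndarray:
    return np.minimum(np.asarray(counts), cutoff)


def default_cutoff(counts: np.ndarray, quantile: float = 0.995) -> float:
    """Winsorization threshold: the given quantile of the pooled counts,
    never below 3 so that small datasets keep usable dynamic range."""
    return float(max(3.0, np.quantile(np.asarray(counts), quantile)))


def estimate_poisson_mixture(
    bin_counts: np.ndarray, cutoff: float | None = None
) -> PoissonMixtureParams:
    """Method-of-moments fit of the two-component Poisson mixture.

    With factorial moments M_r = E[Y(Y-1)...(Y-r+1)] the mixture satisfies
    M_r = omega * lambda1**r + (1 - omega) * lambda0**r for r = 1, 2, 3, a
    classical two-support-point moment problem: the lambdas are the roots of
    z**2 - A z + B with A = (M3 - M1 M2) / (M2 - M1**2) and
    B = (M1 M3 - M2**2) / (M2 - M1**2), and omega follows from M1.
    """
    y = np.asarray(bin_counts, dtype=float)
    if y.size < 100:
        raise EstimationError(f"need >= 100 bins to fit the mixture, got {y.size}")
    if np.any(y < 0):
        raise ValueError("bin counts must be nonnegative")
    if cutoff is None:
        cutoff = default_cutoff(y)
    y = winsorize_counts(y, cutoff)

    if np.ptp(y) == 0:
        raise EstimationError("all bin counts identical: mixture is degenerate")

    m1 = y.mean()
    m2 = (y * (y - 1)).mean()
    m3 = (y * (y - 1) * (y - 2)).mean()

    denom = m2 - m1 * m1
    if abs(denom) < 1e-12:
        raise EstimationError(
            "second factorial moment matches a single Poisson; "
            "no two-component solution (try raising the cutoff)"
        )
    a = (m3 - m1 * m2) / denom
    b = (m1 * m3 - m2 * m2) / denom
    disc = a * a - 4.0 * b
    if disc < 0:
        raise EstimationError(
            "negative discriminant in the moment system; the count "
            "distribution is incompatible with a two-component Poisson "
            "mixture (try raising the cutoff)"
        )
    root = np.sqrt(disc)
    lam0 = (a - root) / 2.0
    lam1 = (a + root) / 2.0
    if lam1 - lam0 < 1e-6:
        raise EstimationError("mixture components are indistinguishable")
    if lam0 < 0:
        if lam0 > -1e-8:
            lam0 = 0.0
        else:
            raise EstimationError(
                "negative rate estimate; raise the truncation cutoff"
            )
    if lam1 <= 0:
        raise EstimationError("non-positive enriched-rate estimate")
    omega = (m1 - lam0) / (lam1 - lam0)
    omega = float(np.clip(omega, 1e-4, 1.0 - 1e-4))
    return PoissonMixtureParams(
        lambda0=float(lam0), lambda1=float(lam1), omega=omega, cutoff=float(cutoff)
    )


def poisson_mixture_emission(
    y: np.ndarray, params: PoissonMixtureParams
) -> np.ndarray:
    """(T, 2) emission log-likelihood table: Poisson(lambda0) vs Poisson(lambda1).

    Counts are winsorized at the fitted cutoff for consistency with
    estimation.
    """
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("bin counts must be nonnegative")
    y = winsorize_counts(y, params.cutoff)
    return np.column_stack(
        [
            stats.poisson.logpmf(np.floor(y), params.lambda0),
            stats.poisson.logpmf(np.floor(y), params.lambda1),
        ]
    )


def infer_enriched(
    series: Sequence[BinSeries],
    params: PoissonMixtureParams,
    transition: np.ndarray | None = None,
    persistence: float = 0.5,
) -> list[np.ndarray]:
    """Viterbi-decode each cluster's bin series independently.

    Returns one 0/1 label array per input series (1 = enriched).  The
    transition matrix defaults to the one whose stationary enriched mass is
    the fitted omega.
    """
    if transition is None:
        transition = hmm.build_transition(params.omega, persistence)
    labels = []
    for s in series:
        loglik = poisson_mixture_emission(s.counts, params)
        labels.append(hmm.viterbi(loglik, transition))
    return labels


def merge_enriched_regions(
    labels: Sequence[np.ndarray],
    clusters: Sequence[Cluster],
    bin_width: int = 5,
) -> list[EnrichedRegion]:
    """Concatenate maximal runs of enriched bins into genomic regions.

    Runs in different clusters never merge, even if genomically adjacent;
    one cluster may yield several regions (multi-modal peaks).  Region ends
    are clipped to the cluster hull (the last bin may be short).
    """
    regions: list[EnrichedRegion] = []
    for lab, cluster in zip(labels, clusters):
        lab = np.asarray(lab)
        if lab.size == 0 or not lab.any():
            continue
        padded = np.concatenate([[0], lab, [0]])
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1)
        for s_bin, e_bin in zip(starts, ends):
            regions.append(
                EnrichedRegion(
                    id=len(regions),
                    cluster_id=cluster.id,
                    chrom=cluster.chrom,
                    strand=cluster.strand,
                    start=cluster.start + int(s_bin) * bin_width,
                    end=min(cluster.start + int(e_bin) * bin_width, cluster.end),
                )
            )
    return regions
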