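"""Second-round model: single-base cross-link sites within enriched regions.

Per base b of an enriched region we observe the total tag count x_b and the
marker-mutation tag count m_b.  Background bases emit m ~ ZIB(x, p0, phi) — a
binomial with success probability p0 whose zero class is inflated by mass
phi, absorbing bases where reverse transcription never errs — while true
cross-link sites emit m ~ Binomial(x, p1) with p1 > p0.  Keeping x in the
emission is the point of the model: 30 mutations in 100 tags is far stronger
evidence than 3 in 10 even though both rates are 0.3.

Parameter estimation follows a mode-split scheme: the two modes of the
mutation-rate (m/x) density locate the background and cross-link rate scales,
a user parameter c in (0, 1) places a split threshold tau between them
(tau = mode0 + c * (mode1 - mode0), midpoint by default), bases at or below
tau estimate (p0, phi) by method of moments and the rest estimate p1 by the
pooled ratio.  Decoding is the shared two-state HMM; every reported site
carries its forward-backward posterior probability of the cross-link state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from clipcall import hmm

logger = logging.getLogger(__name__)

__all__ = [
    "MutationMixtureParams",
    "BindingSite",
    "ModeEstimationError",
    "ModelOrderError",
    "binomial_pmf",
    "binomial_logpmf",
    "zib_pmf",
    "zib_logpmf",
    "estimate_mutation_modes",
    "partition_by_threshold",
    "estimate_zib",
    "estimate_binomial",
    "fit_mutation_mixture",
    "infer_binding_sites",
]


class ModeEstimationError(RuntimeError):
    """The mutation-rate density does not show two usable modes."""


class ModelOrderError(RuntimeError):
    """Estimated cross-link rate does not exceed the background rate."""


@dataclass
class MutationMixtureParams:
    """Fitted emission parameters of the second-round HMM."""

    p0: float  # background per-tag mutation probability
    phi: float  # zero-inflation mass of the background component
    p1: float  # cross-link per-tag mutation probability
    theta: float  # proportion of cross-link bases among enriched-region bases
    c: float = 0.5  # user split parameter placing tau between the modes
    mode0: float = float("nan")  # background mode of the m/x density
    mode1: float = float("nan")  # cross-link mode of the m/x density

    def __post_init__(self):
        if not 0.0 <= self.p0 < self.p1 <= 1.0:
            raise ValueError("parameters must satisfy 0 <= p0 < p1 <= 1")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must lie in [0, 1)")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if not 0.0 < self.c < 1.0:
            raise ValueError("c must lie in (0, 1)")


@dataclass
class BindingSite:
    """A single-base cross-link site with its posterior probability score."""

    chrom: str
    strand: str
    position: int  # 0-based
    x: int
    m: int
    score: float  # P(cross-link state | region observations)
    region_id: int
    cluster_id: int


# -- probability mass functions ---------------------------------------------


def binomial_logpmf(m, x, p) -> np.ndarray | float:
    """log C(x, m) + m log p + (x - m) log(1 - p), vectorized."""
    m = np.asarray(m)
    x = np.asarray(x)
    if np.any(m > x) or np.any(m < 0):
        raise ValueError("require 0 <= m <= x")
    out = stats.binom.logpmf(m, x, p)
    return float(out) if out.ndim == 0 else out


def binomial_pmf(m, x, p) -> float:
    """Probability of m marker mutations among x covering tags at rate p."""
    return float(np.exp(binomial_logpmf(m, x, p)))


def zib_logpmf(m, x, p, phi) -> np.ndarray | float:
    """Zero-inflated binomial log-pmf.

    P(0) = phi + (1 - phi) (1 - p)^x and P(m) = (1 - phi) Binom(m; x, p)
    for m > 0.
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError("phi must lie in [0, 1)")
    m = np.asarray(m)
    x = np.asarray(x)
    base = binomial_logpmf(m, x, p) + math.log1p(-phi)
    with np.errstate(divide="ignore"):
        zero_mass = np.logaddexp(
            math.log(phi) if phi > 0 else -np.inf,
            math.log1p(-phi) + x * math.log1p(-p) if p < 1 else -np.inf,
        )
    out = np.where(m == 0, zero_mass, base)
    return float(out) if out.ndim == 0 else out


def zib_pmf(m, x, p, phi) -> float:
    return float(np.exp(zib_logpmf(m, x, p, phi)))


# -- parameter estimation ----------------------------------------------------


def estimate_mutation_modes(
    rates: np.ndarray,
    grid_size: int = 512,
    fallback_quantile: float = 0.9,
) -> tuple[float, float]:
    """The two modes of the mutation-rate density, ordered.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a grid over [0, 1];
    local maxima are ranked by density and the top two returned.  Rates of
    exactly zero are excluded — they would swamp the background mode — but
    the zero bases still enter ZIB estimation later.  If only one mode is
    found, the fallback takes the detected mode as the background mode and
    the ``fallback_quantile`` of the nonzero rates as the cross-link mode.
    """
    rates = np.asarray(rates, dtype=float)
    nonzero = rates[rates > 0]
    if nonzero.size < 2 or np.ptp(nonzero) == 0:
        raise ModeEstimationError(
            "mutation-rate density has a single point mass; supply mode "
            "estimates manually via configuration"
        )
    kde = stats.gaussian_kde(nonzero, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, grid_size)
    density = kde(grid)
    interior = np.flatnonzero(
        (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    ) + 1
    # grid endpoints can hold a mode too (mass piled against 0 or 1)
    candidates = list(interior)
    if density[0] > density[1]:
        candidates.insert(0, 0)
    if density[-1] > density[-2]:
        candidates.append(grid_size - 1)
    candidates.sort(key=lambda i: -density[i])

    if len(candidates) >= 2:
        m0, m1 = sorted(float(grid[i]) for i in candidates[:2])
        if m1 - m0 > 1e-6:
            return m0, m1
    # single-mode fallback
    m0 = float(grid[candidates[0]]) if candidates else float(np.median(nonzero))
    m1 = float(np.quantile(nonzero, fallback_quantile))
    if m1 <= m0 + 1e-6:
        raise ModeEstimationError(
            "could not locate two distinct modes in the mutation-rate "
            "density; supply mode estimates manually via configuration"
        )
    return m0, m1


def split_threshold(mode0: float, mode1: float, c: float = 0.5) -> float:
    """tau = mode0 + c * (mode1 - mode0); c -> 0 recovers the background
    mode, c -> 1 the cross-link mode."""
    if not 0.0 < c < 1.0:
        raise ValueError("c must lie in (0, 1)")
    if not mode0 < mode1:
        raise ValueError("require mode0 < mode1")
    return mode0 + c * (mode1 - mode0)


def partition_by_threshold(
    m: np.ndarray, x: np.ndarray, modes: tuple[float, float], c: float = 0.5
) -> tuple[np.ndarray, float]:
    """Boolean cross-link-candidate mask over covered bases and the threshold.

    Bases with rate m/x <= tau (which includes every m = 0 base) form the
    background set; bases above tau are cross-link candidates.  Bases with
    x = 0 are never candidates.
    """
    m = np.asarray(m)
    x = np.asarray(x)
    tau = split_threshold(modes[0], modes[1], c)
    covered = x > 0
    rate = np.zeros_like(m, dtype=float)
    rate[covered] = m[covered] / x[covered]
    candidate = covered & (rate > tau)
    if not candidate.any():
        raise ModeEstimationError(
            f"no bases above the split threshold tau={tau:.4f}; "
            "try a smaller c"
        )
    return candidate, tau


def estimate_zib(
    m: np.ndarray, x: np.ndarray, upper: float = 0.5
) -> tuple[float, float]:
    """Method-of-moments fit of (p0, phi) from background (m, x) pairs.

    Two moment conditions with heterogeneous sizes x_b:
    the pooled mean, sum(m) = (1 - phi) p0 sum(x), and the zero fraction,
    mean 1{m=0} = mean_b[phi + (1 - phi)(1 - p0)^x_b].  phi is profiled out
    of the first condition and p0 found by 1-D root finding on the second.
    """
    m = np.asarray(m, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = x > 0
    m, x = m[keep], x[keep]
    if m.size == 0:
        raise ValueError("background set is empty")
    total_x = x.sum()
    pooled = m.sum() / total_x
    zero_frac = float(np.mean(m == 0))

    if pooled == 0.0:  # no mutations at all: floor the rate, zeros give phi
        p0 = 1e-6
        pbar = float(np.mean((1.0 - p0) ** x))
        phi = 0.0 if pbar >= 1.0 else (zero_frac - pbar) / (1.0 - pbar)
        return p0, float(np.clip(phi, 0.0, 1.0 - 1e-9))

    def phi_of(p0: float) -> float:
        return 1.0 - pooled / p0

    def gap(p0: float) -> float:
        phi = phi_of(p0)
        predicted = phi + (1.0 - phi) * np.mean((1.0 - p0) ** x)
        return float(predicted - zero_frac)

    lo = pooled  # phi = 0 boundary
    hi = max(upper, lo * (1 + 1e-9))
    if gap(lo) >= 0.0:
        # pure binomial already over-predicts zeros: no inflation detectable
        return float(pooled), 0.0
    if gap(hi) <= 0.0:
        logger.warning(
            "ZIB moment system has no interior root below p0=%.3f; "
            "returning the boundary estimate", hi,
        )
        return float(hi), float(np.clip(phi_of(hi), 0.0, 1.0 - 1e-9))
    p0 = optimize.brentq(gap, lo, hi, xtol=1e-12)
    return float(p0), float(np.clip(phi_of(p0), 0.0, 1.0 - 1e-9))


def estimate_binomial(m: np.ndarray, x: np.ndarray, p0: float | None = None) -> float:
    """Pooled cross-link rate p1 = sum(m) / sum(x) over candidate bases."""
    m = np.asarray(m, dtype=float)
    x = np.asarray(x, dtype=float)
    if m.size == 0 or x.sum() == 0:
        raise ValueError("candidate set is empty")
    p1 = float(m.sum() / x.sum())
    if p0 is not None and p1 <= p0:
        raise ModelOrderError(
            f"estimated p1={p1:.4g} does not exceed p0={p0:.4g}; "
            "try a different split parameter c"
        )
    return p1


def fit_mutation_mixture(
    profiles: Sequence, c: float = 0.5, modes: tuple[float, float] | None = None
) -> MutationMixtureParams:
    """Full estimation pass over the pooled bases of all enriched regions."""
    m = np.concatenate([p.m for p in profiles])
    x = np.concatenate([p.x for p in profiles])
    covered = x > 0
    if modes is None:
        rates = m[covered] / x[covered]
        modes = estimate_mutation_modes(rates)
    candidate, _tau = partition_by_threshold(m, x, modes, c)
    background = covered & ~candidate
    p0, phi = estimate_zib(m[background], x[background], upper=max(modes[1], 0.5))
    p1 = estimate_binomial(m[candidate], x[candidate], p0=p0)
    theta = float(np.clip(candidate.sum() / covered.sum(), 1e-4, 1 - 1e-4))
    return MutationMixtureParams(
        p0=p0, phi=phi, p1=min(p1, 1.0), theta=theta, c=c,
        mode0=modes[0], mode1=modes[1],
    )


# -- decoding ----------------------------------------------------------------


def emission_table(
    m: np.ndarray, x: np.ndarray, params: MutationMixtureParams
) -> np.ndarray:
    """(B, 2) log-likelihoods: ZIB background vs binomial cross-link.

    Bases with x = 0 (possible at region edges after binning) are pinned to
    the background state without evaluating either pmf.
    """
    m = np.asarray(m)
    x = np.asarray(x)
    covered = x > 0
    table = np.zeros((len(m), 2))
    table[:, 1] = -np.inf
    if covered.any():
        mc, xc = m[covered], x[covered]
        table[covered, 0] = zib_logpmf(mc, xc, params.p0, params.phi)
        table[covered, 1] = binomial_logpmf(mc, xc, params.p1)
    return table


def infer_binding_sites(
    profiles: Sequence,
    params: MutationMixtureParams,
    persistence: float = 0.5,
    decoding: str = "viterbi",
    min_score: float | None = None,
) -> list[BindingSite]:
    """Decode every enriched region and return its cross-link sites.

    A reliable site is a base labeled cross-link by the chosen decoder
    (``viterbi`` path state, or ``posterior`` > 0.5) with at least one
    mutant tag; every site carries its forward-backward posterior score.
    """
    if decoding not in ("viterbi", "posterior"):
        raise ValueError("decoding must be 'viterbi' or 'posterior'")
    transition = hmm.build_transition(params.theta, persistence)
    sites: list[BindingSite] = []
    for profile in profiles:
        table = emission_table(profile.m, profile.x, params)
        scores = hmm.posterior(table, transition)
        if decoding == "viterbi":
            labels = hmm.viterbi(table, transition)
        else:
            labels = (scores > 0.5).astype(int)
        for b in np.flatnonzero((labels == 1) & (profile.m >= 1)):
            site = BindingSite(
                chrom=profile.chrom,
                strand=profile.strand,
                position=profile.start + int(b),
                x=int(profile.x[b]),
                m=int(profile.m[b]),
                score=float(scores[b]),
                region_id=profile.region_id,
                cluster_id=profile.cluster_id,
            )
            if min_score is None or site.score > min_score:
                sites.append(site)
    return sites
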