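# Methods

This note records the statistical model implemented by `clipcall`, the
estimation and decoding choices where the design was genuinely open, what
the synthetic-data generator does and does not emulate, and the known
limitations. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The pipeline assumes aligned CLIP-Seq reads in which (i) protein binding
causes local tag pile-up and (ii) the cross-link position imprints a marker
mutation — deletion, insertion, substitution, or a combination, configured
per experiment (T→C, evaluated strand-aware, for 4SU PAR-CLIP) — into a
fraction of the reads that traverse it. Reads with identical (chromosome,
strand, start, end) are treated as PCR duplicates and collapsed to a single
tag; marker events are unioned across duplicates with at most one event per
genomic base per tag, which guarantees m ≤ x everywhere downstream.
Multi-mapped, secondary and supplementary records are dropped. Paired-end
fragments are collapsed on the fragment interval (leftmost mate start plus
template length), with strand taken from read 1.

**Round 1.** Cluster bin counts (5-bp bins; the statistic is the rounded
mean per-base tag coverage, half-up) are modeled as a two-component Poisson
mixture. Counts above a truncation cutoff are winsorized before both
estimation and decoding; the default cutoff is the 99.5th percentile of the
pooled counts, floored at 3. The factorial-moment system
M_r = ω λ₁^r + (1−ω) λ₀^r (r = 1, 2, 3) reduces to a quadratic whose roots
are the two rates; ω follows from the first moment and is clamped to
[10⁻⁴, 1−10⁻⁴]. Inadmissible systems (negative discriminant, negative or
indistinguishable rates) raise an estimation error advising a higher
cutoff rather than returning a silently bad fit.

**Round 2.** Within enriched regions, per-base mutation counts are modeled
as ZIB(x, p₀, φ) in the background state and Binomial(x, p₁) in the
cross-link state. The zero inflation φ absorbs bases where reverse
transcription simply never errs, beyond what the binomial zero class
predicts. Estimation is a mode-split scheme: a Gaussian KDE (Silverman
bandwidth) of the nonzero mutation rates m/x yields the two
highest-density modes; rates of exactly zero are excluded from mode
finding (they would swamp the background mode) but re-enter ZIB
estimation. The split threshold is the convex combination
τ = p̂₀\* + c (p̂₁\* − p̂₀\*) with user parameter c ∈ (0, 1), default 0.5
(midpoint). If only one mode is found, the background mode is kept and the
90th percentile of nonzero rates stands in for the cross-link mode.
(p₀, φ) are fitted by matching the pooled mean Σm = (1−φ) p₀ Σx and the
zero fraction mean 1{m=0} = mean_b[φ + (1−φ)(1−p₀)^{x_b}], profiling φ out
and root-finding in p₀ (Brent); p₁ is the pooled ratio over the candidate
set, required to exceed p₀.

**Decoding.** Both rounds share a hand-written two-state HMM engine
(log-space Viterbi and forward–backward; ties in Viterbi resolve toward
the background state; an all-impossible position raises a decoding error
naming it). State labels come from Viterbi; reported per-site scores are
forward–backward posteriors; posterior-threshold decoding can be selected
by configuration instead. The transition matrix is built from the fitted
state-1 mass w (ω in round 1, the candidate fraction θ in round 2) and a
persistence hyperparameter ρ (default 0.5):
π₀₁ = w(1−ρ), π₁₀ = (1−w)(1−ρ), so the chain's stationary distribution is
(1−w, w) for any ρ, and the initial distribution is that stationary
distribution. A reported ("reliable") site is a base labeled cross-link
with m ≥ 1; a reliable cluster contains at least one such site.

Bases with x = 0 inside a region (possible at region edges after binning)
are pinned to the background state without evaluating either pmf.

## Tunable parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| bin width | round-1 resolution (bp) | 5 | |
| truncation cutoff | winsorization of bin counts | 99.5th pct, ≥ 3 | the first of the two user parameters |
| c | split point between rate modes | 0.5 | the second user parameter; estimates are insensitive over a broad middle range |
| ρ | HMM state persistence | 0.5 | shapes run lengths only; stationary masses are fixed by the fits |
| decoding | viterbi / posterior | viterbi | scores are posteriors either way |
| FDR permutations | joint (m,x) pair shuffles | 10 | seeded |
| SNP filter | control rate / coverage | 0.25 / 5 | sites exceeding both in a control alignment are removed (and listed, not silently dropped) |

## Permutation FDR: what it can and cannot detect

The FDR procedure shuffles the (m, x) pairs jointly across all bases of all
enriched regions — pairs stay intact, so validity (m ≤ x) and the pair
multiset are preserved — then re-fits and re-decodes round 2 and reports
mean permuted significant-cluster count over the observed count (capped at
1; undefined when nothing was observed). Two structural facts matter.
First, every round-2 estimate (modes, τ, p₀, φ, p₁, θ) is a function of the
pair multiset and is therefore *identical* under permutation; only the
spatial arrangement changes. Second, whenever a base's emission
log-likelihood ratio exceeds the chain's state-flip penalty on its own, it
is called wherever it lands — permuted or not. The FDR therefore measures
how much the calls depend on spatial context. On data with strong per-base
evidence (such as the default synthetic scenario, p₁ = 0.25 at coverage
30, where single-base ratios are an order of magnitude above the flip
penalty) the permuted data yields as many significant clusters as the
observed data and the FDR is ≈ 1 *by construction*, for signal and null
alike. The statistic is informative in the regime real datasets occupy —
weak, spatially structured per-base evidence — and the enrichment stage is
deliberately not re-run under permutation.

## Known estimation bias of the mode-split partition

The background set {b : m_b/x_b ≤ τ} excludes every low-coverage base that
carries even one mutant tag (at x = 4, a single mutation is rate 0.25,
above any reasonable τ). The surviving background set therefore
over-represents zeros, which inflates φ̂ and, through
p̂₀ = pooled/(1−φ̂), p̂₀ as well — on the default synthetic scenario by
roughly a third relative, while λ₀, λ₁, ω and p₁ pass through the full
pipeline within 10%. This is a property of the published estimation
scheme, not of the data generator: the same moment estimators applied to
the truth-partitioned bases recover p₀ within 10% and φ within estimator
noise (the zero-fraction moment carries limited information; ~10–15%
relative error at ~2·10⁴ background bases). Decoding is barely affected —
the fitted background component still describes the background bases it
was fitted on — but users reading p̂₀, φ̂ as physical mutation rates
should be aware of the direction of the bias.

## Synthetic data generator

The generator emulates exactly the generative assumptions of the two
model rounds, on a toy genome, and writes spec-valid SAM plus ground-truth
BED files; everything is driven by one integer seed and reruns are
byte-identical.

* Clusters (default 500, spans 16–40 bins) are placed non-overlapping with
  random gaps on two 150-kb chromosomes, with random strand.
* Bin states alternate background/enriched runs with geometric lengths
  above minimum durations (enriched: mean 9 bins, minimum 6 — a 30-bp
  peak-width floor; background minimum 2), tuned so the long-run enriched
  fraction equals ω. Enriched stubs truncated below the minimum by a
  cluster edge are flipped to background.
* Bin counts are zero-truncated Poisson draws (λ₀ or λ₁ by state;
  truncation keeps clusters contiguous and biases the realized background
  mean by < 2% at λ₀ = 4, the default). Within each run the drawn counts
  are rearranged into a unimodal "pyramid" — a multiset-preserving
  reordering, so the pooled count distribution is exactly the mixture —
  giving runs the peaked shape of real pileups.
* The per-bin profile is realized *exactly* as a read pileup by a skyline
  decomposition: one tag per coverage level and run, with
  coordinate-identical tags made distinct by splitting them into adjacent
  pieces (splitting preserves per-base coverage); split offsets follow a
  golden-ratio sequence so cut points spread out. A narrow run supports
  only as many stacked tags as it has distinct endpoints; the rare
  unplaceable level is skipped and counted (≈ 0.1% of coverage mass at
  the defaults, tracked on the dataset object).
* Mutations: each planted site draws m ~ Binomial(x, p₁) and assigns the
  events to distinct covering tags; background bases draw from
  ZIB(x, p₀, φ) via a per-base suppression flag. Deletion markers are
  encoded in CIGAR (with MD/NM tags), substitution markers in SEQ + MD
  with the genome forced to the appropriate reference base (T on +, A on −
  for the T→C marker). Sites are planted ≥ 2 bp inside enriched runs: the
  cross-link sits within the protein footprint, and run-boundary bases are
  tag edges that cannot carry an interior deletion. Optional PCR
  duplicates (rate 0.1) exercise collapsing.

What the generator does **not** emulate: base-quality structure, generic
(non-marker) sequencing errors, mappability and transcript-abundance
variation, fragment-length biology (tag lengths are a construction of the
exact-coverage realization, down to short fragments), overlapping or
nested clusters, and iCLIP truncation chemistry. Passing the recovery
suite therefore shows the estimators and decoders are correct under the
model's own assumptions at realistic signal levels — not that the model is
robust to the ways real libraries violate those assumptions.

## Numerical choices

* All HMM arithmetic in log space; −inf emissions are legal and propagate
  correctly through `logsumexp`.
* Binomial/Poisson pmfs evaluated via their scipy log-pmf forms; the ZIB
  zero mass uses `logaddexp` of the two branches.
* Transition-matrix rows are validated to sum to 1 within 1e-12; posterior
  marginals are normalized per position (forward ⊙ backward, renormalized).
* The Poisson-mixture moment quadratic tolerates λ₀ down to −1e-8
  (clamped to 0) before declaring failure; component separation below
  1e-6 is a degeneracy error.
* ω and θ are clamped to [1e-4, 1−1e-4] before building transitions.
* ZIB root-finding brackets p₀ in [pooled rate, max(mode₁, 0.5)]; a
  boundary solution is returned with a warning instead of failing.
* BED scores are round(1000·posterior), clamped to [0, 1000]; coordinates
  are 0-based half-open everywhere internally and in BED/BedGraph output.

## Limitations

* Emission families are fixed (Poisson / ZIB–binomial); over-dispersed
  coverage (a negative-binomial regime) will push λ̂₁ upward and fragment
  enriched regions.
* The mutation-rate modes need enough covered bases (≥ ~200) and a visible
  cross-link mode; sparse libraries fall back to a quantile heuristic or
  require manual modes via configuration.
* The permutation FDR is uninformative precisely when per-base evidence is
  overwhelming (see above) — a conservative failure mode.
* SNP filtering needs a control alignment; no catalog-based (dbSNP)
  lookup is provided.
* iCLIP is out of scope: its truncation-based signal requires a different
  observation model.
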