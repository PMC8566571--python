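# Methods

## The model

DNA methylation along a genomic region with N CpG sites is modeled as a
binary random vector **x** = (x_1, …, x_N), x_n ∈ {0, 1}, distributed
according to a correlated potential energy landscape (CPEL): a
nearest-neighbor Ising chain

    p(x; α, β, γ) = exp(−V(x)) / Z(α, β, γ),
    V(x) = −[ α Σ_n x̃_n + β Σ_n ρ_n x̃_n + γ Σ_{n<N} x̃_n x̃_{n+1} ],

with spins x̃_n = 2x_n − 1. The three parameters are

| parameter | meaning | default box |
|---|---|---|
| α | global methylation propensity of the region | [−10, 10] |
| β | modulation of the propensity by local CpG density ρ_n | [−10, 10] |
| γ | nearest-neighbor cooperativity between adjacent CpG sites | [−10, 10] |

ρ_n ∈ [0, 1] is the CpG count inside a 1000-bp window centered on site n
divided by the maximum count such a window can hold (half its length,
clipped and renormalized at chromosome ends). The ±10 box keeps all
exponentials finite and already covers effectively deterministic
landscapes (tanh 10 ≈ 1). The interaction is a single region-wide γ; no
distance weighting or long-range coupling is used.

One parameter triple is fitted per **estimation region**, a fixed
3000-bp tile of the chromosome (configurable). Each estimation region is
split into the minimum number of equally-sized **analysis regions** of at
most s_max = 350 bp (larger sizes leftmost when the division is not
exact); analysis regions are the resolution of all summary statistics and
tests. CpG sites whose C positions are closer than 10 bp form a
**CG-group**; nanopore callers emit one likelihood pair per CG-group, and
the hidden state is assumed constant within a group.

All chain quantities — log-partition, site marginals, adjacent-pair
joints, pattern marginals over analysis regions — are computed exactly by
2×2 transfer-matrix recursions in log space; nothing is sampled or
truncated. Because V is linear in θ = (α, β, γ), the gradient of log Z is
the expected sufficient-statistic vector E[T] and its Hessian is Cov[T];
both are obtained by propagating first and second derivatives through the
forward recursion, which is exact (verified against full 2^N enumeration
to ~1e−14) and stable to at least N = 500 at the parameter bounds.

## Estimation from nanopore evidence

A read is one molecule whose hidden state follows the CPEL model
restricted to group-consistent states. The caller's evidence enters as
per-CG-group log-likelihood pairs q(y | x_g); uncovered groups contribute
a factor of one (they are marginalized, never imputed). The observed-data
likelihood of a read,

    p(y; θ) = Σ_x q(y | x) p(x; θ),

is one transfer-matrix pass with the emission log-likelihoods added to the
group potentials. Fitting maximizes Σ_reads log p(y_r; θ) by EM from
θ⁰ = (0, 0, 0): the E-step computes each read's posterior expected
sufficient statistics exactly (gradient of the emission-weighted
log-partition), and the M-step solves the concave subproblem
max_θ [θ·S − R log Z(θ)] over the box with L-BFGS-B using the exact
gradient. Convergence is declared when the relative change of the
observed log-likelihood drops below 1e−6 (likelihood-based because
parameter tolerances are scale-dependent); at most 100 iterations.

**Ridge default.** At realistic CpG geometries ρ_n spans only ~0.01-0.12,
so the statistic Σ ρ_n x̃_n is nearly collinear with Σ x̃_n: only the
combination α + β·ρ̄ is well identified within a single region, and exact
ML lets β̂ drift along the flat likelihood ridge to the box bounds. The
default fit therefore adds a mild ridge penalty 0.5·|θ|² to the M-step —
a weak zero-mean Gaussian prior (sd = 1) matching the plausible landscape
range — which pins directions the data leave flat while perturbing well-
identified directions negligibly (the error benchmark below is unchanged
with or without it). `m_step` itself defaults to ridge = 0 and keeps the
exact arg-max contract; `em_fit(..., ridge=0.0)` gives the pure ML path.

Two comparator estimators mirror the benchmark baselines:
`direct_ml_fit` fits the model to hard, thresholded methylation calls
(delta emissions; no noise model), and `empirical_estimates` tallies raw
per-site and per-pair call frequencies.

## Summaries and testing

For an analysis region with K CpG sites the exact pattern distribution
g(x) is the marginal of the fitted chain over the contiguous block of
sites (flanking sites absorbed into boundary messages). From it:

* **MML** μ = (1/K) Σ_k Pr[X_k = 1];
* **NME** h = −(1/K) Σ_x g(x) log₂ g(x) ∈ [0, 1], evaluated in O(K)
  through the chain rule (initial entropy plus expected conditional
  entropies), never by enumeration;
* **CMD** d₁₂ = [D(g₁‖ḡ) + D(g₂‖ḡ)] / [H(g₁,ḡ) + H(g₂,ḡ)] ∈ [0, 1],
  where ḡ is the distribution of the model whose potential is the average
  of the two potentials (exactly the componentwise parameter average,
  since V is linear in θ). KL divergences and cross-entropies are
  evaluated in O(K) from pairwise marginals of g₁ against the log
  transition tables of g₂, in bits throughout (CMD itself is base
  invariant; bits are fixed for determinism). Support violations yield
  +∞ (KL) and NaN (CMD); analysis regions with K = 0 yield missing
  values and are excluded downstream.

**Differential testing.** For two groups of M samples each, the per-region
statistics are T_MML and T_NME (differences of group-averaged MML/NME)
and T_CMD (mean of the M² between-group pairwise CMDs). Null
distributions come from exact enumeration: all C(2M, M) label splits for
the unmatched design (252 at M = 5), all 2^M within-pair swaps for the
matched design. Two-tailed p-values count the observed assignment in both
numerator and denominator, so the attainable values are {1/P, …, 1} and
Pr[p ≤ α] = ⌊αP⌋/P exactly under exchangeability (12/252 = 4.76% at
α = 0.05, P = 252). Since the mirrored split always attains the same
|T|, the attainable two-tailed minimum is 2/P. Fits do not depend on
labels, so permutations only re-average precomputed per-sample summaries
and CMD matrix entries. Benjamini-Hochberg correction (statsmodels) is
applied per statistic across all tested analysis regions; significance at
q ≤ 0.05.

Known limitation: in the matched design the pairwise CMD is symmetric
under within-pair label swaps, so the T_CMD permutation distribution is
degenerate and p_cmd = 1 by construction; matched comparisons are
informative for T_MML/T_NME only. A two-sample (one sample per group)
design, which would require read-label permutation with re-fitting, is
not implemented.

## The simulator and what it does (not) emulate

The generator produces study conditions entirely in code:

* **Sequences.** 3000-bp regions with a controlled number of CpGs (20-60
  by default), arranged as one dense CpG-island-like cluster holding
  50-80% of the sites at per-gap spacings of 7-15 bp plus uniformly
  scattered background sites (minimum separation 4 bp). Sub-10-bp island
  gaps produce multi-CpG CG-groups, as in real caller output, and the
  island/background contrast produces genuine within-region density
  variation — without it β is unidentifiable by construction. Accidental
  background CGs are removed, so the planted positions are the complete
  CpG set.
* **Ground truth.** θ* drawn uniformly from α ∈ [−2, 2], β ∈ [−1, 1],
  γ ∈ [0, 1] per region.
* **Reads.** Lengths lognormal (median 8 kb, log-sd 0.5, minimum 500 bp);
  uniform placement including partial end overlaps; a pool is generated
  at 1.6× the target coverage and thinned by the iterative
  random-transfer procedure (move one random read at a time until the
  mean per-CpG coverage reaches the target). Noise grid sd ∈ {2, 2.5, 3,
  3.5}; coverage grid 5×-25×.
* **Signals.** Per read, one hidden group-consistent state drawn exactly
  from p(x; θ*); per covered CG-group a current summary
  s ~ N(± delta/2, sd²), emitted as the Gaussian log-likelihood pair.
  The separation delta = 7.0 is the one calibrated constant (see
  `scripts/calibrate_delta.py`): the zero-threshold call error
  Φ(−delta/2sd) is 12.2% at sd = 3 and 15.9% at sd = 3.5, and the
  measured co-occurrence error is 20-26% over that range.

Not emulated: squiggle-level signals and k-mer pore models (the Gaussian
two-mean model is a deliberate summary-level simplification), basecalling
and alignment artifacts, strand asymmetries, mapping errors, biological
replicate variability beyond the hidden-state sampling, and
WGBS-derived landscape shapes. Passing tests therefore demonstrate the
correctness and noise behavior of the inference machinery under the
stated generative model, not performance on real flow-cell data.

## Problem sizes used in the shipped checks

The error benchmark runs 50 simulated qualified regions (3 kb, 20-60
CpGs) at sd = 3 and 10× coverage — large enough for stable medians over
~4000 site/pair errors while keeping the full suite and the acceptance
script each well inside a coffee break on one CPU. The permutation
calibration uses 2000 exchangeable-null analysis regions; the caller
calibration pools ≥ 10,000 call entries per noise level. Region
qualification (≥ 10 CpGs, at least half the target coverage per CG-group
on average, calls on ≥ 2/3 of CG-groups) is applied before fitting, and
non-qualified regions are re-simulated.

## Numerical choices

* All chain recursions in log space with per-step log-sum-exp; tolerance
  constants centralized in `cpelmeth.config`.
* M-step: L-BFGS-B, ftol 1e−14, gtol 1e−9, warm-started from the previous
  EM iterate.
* 0·log 0 := 0 in all entropies; KL clipped at 0 from below against
  rounding.
* Ties at the binarization threshold abstain (calls are made only for
  |LLR| strictly above the threshold).
* Duplicate (read, CG-group) rows keep the entry with the larger |LLR|.
* Reverse-strand rows are mapped to the forward-strand C (pos − 1);
  CpGs are treated as strand-symmetric throughout.
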