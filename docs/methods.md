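# Methods

This note documents the statistical procedures implemented in `sftest`, the
choices made where the methodology is genuinely open, and what the test
suite's synthetic validations do and do not establish about real data.

## 1. The tail model and its estimation

The model is the discrete power law Pr(K = k) = k^(−α) / ζ(α, k_min) on
integers k ≥ k_min ≥ 1, α > 1.  It is a model of the distribution's *upper
tail* only; the body (k < k_min) is left unmodeled.  Estimation follows the
standard two-stage recipe:

* **k̂_min** — every distinct observed degree whose tail retains at least
  two distinct values is a candidate; for each candidate the tail MLE α̂ is
  computed and the Kolmogorov–Smirnov distance between the conditional
  ECDF and model CDF (both restricted to k ≥ k_min, evaluated on the
  observed tail support) is recorded; the candidate with minimal KS wins.
  Ties break toward smaller k̂_min (larger n_tail, more data used;
  deterministic).
* **α̂** — bounded scalar maximization of the exact discrete
  log-likelihood −n_tail·log ζ(α, k_min) − α·Σ log k_i on the box
  [1 + 10⁻⁶, 12], converged to 10⁻⁶ in α (tighter than the 10⁻⁴
  contract).  ζ is evaluated with `scipy.special.zeta`, with a stable
  log-space series fallback where k_min^(−α) underflows.

**The α ceiling is deliberate and fixed.**  If α may grow without bound,
the discrete power law degenerates into a one-parameter family of
near-geometric decays that can locally mimic *any* log-concave tail slice:
on Erdős–Rényi/Poisson degree data the KS scan then retreats to a narrow
upper-tail window, fits α̂ ≈ 13–47, and the goodness-of-fit test loses all
power (we measured p ≥ 0.1 in roughly 90% of seeds for n from 5·10³ to
5·10⁵).  A ceiling of 12 — far above every exponent reported for real
networks — preserves all empirically relevant fits while restoring the
test's ability to reject thin-tailed data: fits that hit the ceiling are
reported at the boundary and are then typically rejected by the bootstrap.
A tail with fewer than two distinct values has an unbounded likelihood and
raises a degenerate-tail error instead of returning a fit.

Degree-0 nodes and body degrees are excluded from the tail but retained in
the sequence; the bootstrap and the density filter need them.

## 2. Goodness of fit (semi-parametric bootstrap)

Each of n_boot replicates draws a synthetic sequence of the original size
n: with probability n_tail/n from the fitted discrete power law (exact
inverse-CDF sampling: cumulative table to a cap, bisection on the zeta
survival function beyond it), otherwise uniformly with replacement from
the observed body.  The *entire* fitting procedure (k_min scan + MLE) is
re-run on each replicate, and

p = (# replicate KS ≥ observed KS) / n_boot

with no +1 smoothing, so p lives on the grid {0, 1/n_boot, …, 1}.  p ≥ 0.1
reads "plausibly scale free"; under a true power-law generating process
the test rejects a fraction ≈ 0.1 of the time (its designed false-negative
rate; the suite verifies this within 3 binomial standard errors).
Replicates on which no k_min candidate is fittable are regenerated from a
reserve substream and counted on the result.  Default n_boot = 1000
(p-resolution ≈ 0.015 around the 0.1 threshold); the calibration runs in
the suite use 200 for speed.

One practical caveat the suite documents explicitly: because k̂_min is
re-selected on every replicate, the test judges only the *selected* tail.
Thin-tailed data whose upper slice happens to sit below the α ceiling can
survive (a Poisson tail occasionally does); the taxonomy's n_tail ≥ 50 and
2 < α̂ < 3 requirements are what keep such fits out of the stronger
categories.

## 3. Alternative distributions

Four alternatives are fitted by maximum likelihood **on exactly the tail
the power law selected** (same k_min, same observations); this makes the
likelihoods directly comparable and slightly favors the power law, the
conservative direction.  All four are defined directly on the integers
k ≥ k_min by normalizing the continuous kernel through summation:

| family            | kernel f(k)                     | parameters |
|-------------------|---------------------------------|------------|
| exponential       | e^(−λk)                         | λ > 0      |
| log-normal        | (1/k)·e^(−(log k − μ)²/(2σ²))   | μ, σ > 0   |
| Weibull           | e^(−(k/b)^a)                    | a, b > 0   |
| power-law cutoff  | k^(−α)·e^(−λk)                  | α, λ ≥ 0   |

Normalizers: the exponential is a shifted geometric in closed form; the
log-normal and Weibull use an exact sum over a window plus a closed-form
integral tail (Gaussian tail and upper incomplete gamma respectively, a
midpoint Euler–Maclaurin correction, relative error ≲ 10⁻⁸); the cutoff
uses an exact 2048-term window plus adaptive quadrature split at the
kernel mode.  Discretization by summation (rather than CDF differencing)
is isolated in one function so the convention can be swapped.

Fitting: the exponential MLE is closed-form (p̂ = 1/(1 + mean(k − k_min))
for the equivalent geometric).  Two-parameter families use Nelder–Mead
from five deterministic starts (moment-matched plus dispersed) inside
identifiable boxes (σ ≥ 10⁻³; a ∈ [0.05, 20], b ∈ [10⁻³, 10⁶]; cutoff
α ∈ [−5, 12], λ ∈ [10⁻⁶, 60]).  The cutoff fit additionally evaluates the
pure-power-law boundary (λ = 0, α = the tail MLE) and keeps whichever
likelihood is higher, so the nesting guarantee L_cutoff ≥ L_PL holds *by
construction*, not merely by optimizer luck.  λ values below 10⁻⁶ are
indistinguishable from the boundary for any realistic degree range, which
is why the interior search stops there.

## 4. Model comparison

**Non-nested families** (exponential, log-normal, Weibull): Vuong's
normalized LRT.  With pointwise log-ratios ℓ_i = log p_PL(k_i) −
log p_Alt(k_i), R = Σℓ_i, and σ the n−1 sample standard deviation of the
ℓ_i, the statistic R/(σ√n_tail) is asymptotically standard normal when
the models are equally close to the truth; the p-value is two-tailed.
p ≥ 0.1 ⇒ inconclusive, otherwise the sign of R picks the winner.  This
threshold sets the per-test false-positive rate for an alternative at
0.05 (verified by simulation in the suite).  If all ℓ_i are identical
(σ = 0) the comparison is flagged degenerate and reported inconclusive.

**The nested cutoff family**: R ≤ 0 always, so the power law can never be
favored; −2R is referred to χ² with one degree of freedom and p < 0.1
reads "cutoff favored", otherwise inconclusive.  The true boundary null
(λ = 0 on the edge of the parameter space) makes χ²₁ conservative — the
correct boundary distribution is a ½δ₀ + ½χ²₁ mixture — but the χ²₁ form
is the convention of the framework this package follows; the suite's
boundary-null calibration (pure power-law data mostly inconclusive)
documents the realized behavior.

**Information-criterion variant**: each model scored 2p − 2L (p = number
of estimated parameters: 2 for the power law's (k_min, α), 1 + family
parameters for alternatives), with the small-sample correction
2p(p+1)/(n−p−1) applied when n_tail/p < 40; |Δ| < 2 is a tie
(inconclusive).  Which criterion variant to use is exposed as an argument
because the choice is not canonical.

No multiple-testing correction is applied across the four comparisons —
deliberately, so each comparison keeps its stated marginal error rate.

## 5. Simplification and the density filter

A network data set is decomposed into simple-graph *views* whose degree
sequences are unambiguous:

* weights dropped; parallel edges collapsed; self-loops removed;
* directed → three views (in-degree, out-degree, undirected collapse);
* bipartite → two views, one degree sequence per node class, on the
  bipartite graph itself (no one-mode projection — projections inflate
  density and manufacture hubs);
* multiplex → one view per layer plus the layer union;
* temporal → one view per time slice plus the time-aggregated union;
* transformations compose: slices/layers split first, then direction and
  class views.

The exact decomposition used by the original corpus study is not fully
published; the table above is this package's committed reconstruction and
the output count is a deterministic function of the flag set.  Isolated
nodes recorded in the input stay in the sequence (they are part of n and
⟨k⟩).  Slice and layer views take their node set from the edges present
in that slice/layer; union and base views use the declared node set.

A sequence is analyzed only if 2 < ⟨k⟩ < √n (strict on both sides):
sparser graphs cannot carry a meaningful tail, denser ones cannot be
power-law.  Filtered and unfittable sequences are reported as untestable
and never count for or against a category.

## 6. The evidence taxonomy

Per-sequence predicates: *superweak-ok* = no alternative favored over the
power law among the four comparisons; *weakest-ok* = GoF p ≥ 0.1;
*weak-ok* = weakest-ok and n_tail ≥ 50; *strong-ok* = weak-ok and
superweak-ok and 2 < α̂ < 3.  Data-set categories from the fractions of
testable sequences: Super-Weak and Weakest at ≥ 50%, Weak at ≥ 50% of the
joint weak-ok predicate, Strong requires Weak and Super-Weak plus ≥ 50%
strong-ok, Strongest requires ≥ 90% strong-ok and ≥ 95% superweak-ok.
Not Scale Free ⇔ neither Super-Weak nor Weakest.  A data set whose every
sequence is untestable is reported *unclassifiable*, never silently Not
Scale Free.

Where the published phrasing leaves the quantifier placement open (does
"n_tail ≥ 50 for at least 50% of graphs" share one 50% set with the GoF
requirement?), the per-sequence *joint* reading is committed: each
sequence must satisfy both conditions itself.  All thresholds live in a
`Thresholds` object; the *permissive* variant grants a category if a
single sequence qualifies, making Strong and Strongest coincide.

## 7. Synthetic generators and what the validations show

* **i.i.d. samplers** for the power law and all alternatives (inverse-CDF;
  the non-power-law tables are extended until the residual tail mass is
  below 10⁻¹², so "exact" holds to that residual).
* **Erdős–Rényi** G(n, p): no scale-free structure by construction.
* **Directed preferential attachment**: each arriving node emits m
  directed edges; targets chosen ∝ (in-degree + a).  Asymptotic in-degree
  exponent 2 + a/m; defaults m = 3, a = 1.5 give α = 2.5 inside the
  canonical (2, 3) band while keeping mean in-degree 3 above the sparsity
  filter.
* **Vertex copying**: each arriving node copies a uniform prototype's
  out-links with probability q (default 0.6), rewiring the rest uniformly;
  heavy-tailed in-degrees.
* **Temporal power-law graph**: each snapshot is an independent Chung–Lu
  graph whose expected degrees are i.i.d. discrete power-law draws (capped
  at √(Σw) so edge probabilities stay ≤ 1), timestamped by snapshot.

End-to-end validations in the suite: ER (n = 5000, ⟨k⟩ ≈ 10) lands in Not
Scale Free; directed preferential attachment (n = 20000) reaches Strongest
under the permissive scheme through its in-degree view; an i.i.d.
power-law sequence (α = 2.5, k_min = 2, n = 5000) reaches Strong.  The
i.i.d. check generates at k_min = 2 because a k_min = 1 sequence at
α = 2.5 has mean degree ζ(1.5)/ζ(2.5) ≈ 1.95 and would (correctly) be
excluded by the sparsity filter.  Problem sizes throughout (n = 500–1000
calibration sequences, 200 bootstrap replicates, 100–500 replicate
batches) were chosen as the smallest runs at which the binomial error
bands are informative.

These generators emulate clean mechanisms with i.i.d. or exchangeable
randomness.  They do not emulate degree correlations, community structure,
measurement error, or size-dependent sampling of real networks — so a
green synthetic suite certifies the statistical machinery, not any claim
about what fraction of real networks is scale-free.

## 8. Numerical and engineering notes

* All randomness flows from `numpy` SeedSequence spawning: one master seed
  per run, one independent substream per replicate; results are
  bit-reproducible given (input, seed, configuration).
* KS ties across k_min (within 10⁻¹²) resolve to the smaller candidate.
* Hurwitz-zeta evaluations are exact to ≈ 10⁻¹⁰ (checked against direct
  series summation with integral tail bounds in the suite).
* Degenerate inputs fail loudly: empty graphs, all-equal degree
  sequences, bipartite data without a partition, layer/timestamp columns
  inconsistent with declared flags.

## 9. Known limitations

* The χ²₁ nested test is conservative at the λ = 0 boundary (above).
* The α ceiling of 12 means genuinely steeper-than-α=12 power laws are
  reported at the boundary; no real degree sequence in the literature
  approaches this regime.
* The Weibull likelihood is nearly flat along an (a, b) ridge at moderate
  n; parameters are recovered loosely even though the likelihood is
  maximized correctly (the suite asserts likelihood dominance over the
  generating parameters rather than tight parameter recovery).
* Bipartite one-mode projections, weight-thresholded simplifications and
  sliding temporal windows are out of scope.
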