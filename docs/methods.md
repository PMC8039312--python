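# Methods

## Model and assumptions

The simulator implements a single-layer feed-forward network of binary
threshold (McCulloch–Pitts) neurons: internal state *sᵢ = Σⱼ wᵢⱼxⱼ*, output
*yᵢ = 1* iff *sᵢ − η ≥ 0* (threshold equality fires). Dynamics are
synchronous within a step: all internal states are computed from the
pre-update weights, then all weight updates are applied. The layer is square
by default (120 inputs, 120 outputs); rectangular layers are supported.

Two plasticity rules act on the same substrate:

- **Hebbian (HEBLR)**: potentiation only, gated by postsynaptic firing.
  Each presentation adds δw to every active synapse of every neuron with
  *sᵢ ≥ η*. Weight trajectories are element-wise non-decreasing, and the
  per-neuron step magnitude obeys *ΔŴᵢ = yᵢ (Σⱼ xⱼ) δw* exactly.
- **Spatiotemporal (STLR)**: LTP/LTD of active synapses controlled by a
  coincidence coefficient against two thresholds (θ₁ > θ₂), independent of
  output firing; weights are not clipped and may become negative. The
  temporal-history factor of the full rule is deliberately omitted; only
  the within-frame coincidence term is modelled. The coefficient has an
  exact product form *Iᵢⱼ = wᵢⱼxⱼ·Σ_{m≠j} wᵢₘxₘ* and a large-network
  approximation *Iᵢⱼ = wᵢⱼxⱼ/sᵢ* (row-sums equal 1 for every driven
  neuron). By default classification happens in the unit-sphere projection
  *Ĩᵢⱼ = w̃ᵢⱼ·s̃ᵢ*, where thresholds are scale-free and the relationship
  between Ĩ and w̃ is a line through the origin with slope s̃ᵢ. Neurons
  partition into regions by s̃ᵢ: R1 (s̃ ≥ θ̃₁, all three branches
  reachable), R2 (between, no enhancement), R3 (s̃ ≤ θ̃₂, attenuation
  only); boundaries are inclusive on the R1/R3 sides.

Weight **normalization is an analysis-time projection only**: training
updates raw weights, and no per-step renormalization is applied.

## Inputs

Spatial patterns are constant-weight binary vectors (n = 120, 60 ones) with
exact pairwise Hamming distance 10, generated by a shared-core design: a
common random core of `ones − hd/2 = 55` active positions plus one disjoint
random block of `hd/2 = 5` unique positions per pattern. This is the
simplest construction that makes "random elements, constant ones, exact
pairwise distance" simultaneously true; infeasible parameter combinations
raise instead of being silently relaxed. Two pattern-geometry consequences
worth noting: the inter-pattern cosine is forced to 55/60 ≈ 0.9167 (a
narrative value of ≈0.93 sometimes quoted for this geometry is inconsistent
with the stated combinatorics and is not reproduced), and at most
55 + 5·5 = 80 of the 120 input lines are ever active across a five-frame
different-context sequence.

Sequences are five frames: *same context* repeats one pattern; *different
context* presents the five patterns (in order by default; a randomized mode
draws the first four frames without replacement — four distinct of the
five — and keeps the last pattern as the final frame, both configurable).

## Parameters, defaults, rationale

| parameter | default | meaning / rationale |
|---|---|---|
| n, k, hd, ones | 120, 5, 10, 60 | input geometry of the study conditions |
| t_len | 5 | one update per frame, five frames, no epochs |
| initial weights | U[0, 1) | nonnegative start for excitatory synapses; only the ratios δw/spread and low/spread matter (the model is scale-invariant in weights and δw jointly) |
| η | median of s at the first frame, then frozen | makes the winner set nondegenerate (≈ half the neurons) at any weight scale; configurable as an absolute value |
| δw (weight-distribution protocol) | 0.25 | 5 steps move trained weights by 1.25 > the initial spread, so the trained block separates from the untouched block by several histogram bins — the requirement for resolving the distribution's mode structure |
| δw (completion/discrimination readout) | 0.05 | see "Two increment regimes" below |
| θ̃₁, θ̃₂ | 60th/40th quantiles of Ĩ over active synapses at the first frame, then frozen | the narrow (20%) invariance band keeps the untouched middle peak small relative to the enhancement/attenuation peaks, matching the reported dominance structure; configurable as absolute values or other quantiles |
| coincidence form | approximate, thresholded in normalized space | the approximation is the operative quantity in the mechanism analysis; the exact form and raw-space thresholding remain available |
| histogram | raw weights, pooled over ever-active columns, 50 bins | raw rather than normalized: under HEBLR a winner row's norm grows proportionally to its enhancement, so row normalization cancels exactly the trained/untrained separation. Ever-active pooling: the ≥ 40 never-stimulated columns retain the initial uniform distribution forever and would otherwise dominate the histogram middle |
| mode counting | moving average over 5 bins, peaks with prominence ≥ 10% of the smoothed maximum | fixed, documented procedure that makes "bimodal"/"multimodal" machine-checkable; invariant to count rescaling; zero-padding makes edge peaks detectable |

Degenerate inputs are total: an all-zero frame changes nothing; a zero-drive
row in the approximate coefficient is defined as zero with a warning; an
empty training sequence resolves η to 0 and STLR thresholds to (+∞, −∞)
(no branch ever taken) and leaves the initial weights untouched.

## Two increment regimes (a finding, not a bug)

The two headline phenomena live in different δw regimes, and no single
increment exhibits both:

- **Weight-space structure** (bimodal HEBLR, multimodal STLR histograms)
  requires 5δw to exceed the initial weight spread, otherwise the trained
  and untouched blocks overlap into a single hump.
- **Output-space discrimination** (STLR separating the five similar
  same-context sequences more than HEBLR, measured across replicate
  networks with shared initial weights) exists only for small increments
  (δw ≲ 0.1 of the spread). With large steps the branch classification
  freezes after the first frame and, under normalized-space thresholding,
  the R1/R2/R3 geometry amplifies the *shared* s̃-ranking of neurons —
  all replicates converge toward the same winner set and the outputs
  *collapse* (with more steps, pairwise output distance → 0, i.e. the STLR
  turns into a pattern completer at the output level even while its weight
  distribution is multimodal). With small steps, threshold-crossing jitter
  keeps accumulating pattern-specific weight differences over all five
  frames and the STLR outputs end measurably further apart than the frozen
  Hebbian winner masks.

Accordingly, the weight-distribution protocol uses δw = 0.25 and the
completion/discrimination readout documents its own δw = 0.05
(`stlrnet.experiments.DISCRIMINATION_DW`); both are parameters of the
respective experiment, and sweeping δw reproduces the transition.

## What the synthetic generator does and does not emulate

The generator reproduces the *idealized* input statistics of the study
conditions: exact constant weight, exact pairwise distance, binary frames,
noiseless presentation. Real sensory or hippocampal input streams have none
of these exactnesses — variable sparseness, graded rates, jitter, and
distances that are distributed rather than fixed. Passing tests therefore
demonstrate the self-organization mechanisms under the stated idealized
geometry, not robustness to realistic input noise, rate coding, or
temporal-history effects (the omitted history factor is exactly the
component that would make frame order matter within the STLR).

## Numerical choices

Branch fractions are computed as counts over active synapses with
*p = 1 − (q + r)* so that *q + r + p == 1.0* holds bit-exactly per neuron.
Threshold comparisons use the inclusive conventions stated above
(*I ≥ θ₁*, *I ≤ θ₂*, *s ≥ η*). Auto-thresholds are resolved once from the
first frame and frozen, making every run a pure function of its seed;
experiment seeds derive deterministically (patterns: seed, randomized
sequences: seed+1, weights: seed+2), so conditions sharing a seed share
patterns and initial weights. Vectorized updates are tested bit-exactly
against per-synapse reference loops.

## Known limitations

- Modality of flat-topped (uniform-block) histograms is robust, but the
  *positions* of such modes are only stable to the plateau width; tests
  compare mode counts and block membership, not exact peak positions.
- The mode count of the STLR same-context condition is typically 3 (the
  small invariant residue forms a minor middle peak, as described
  qualitatively in the source experiments); "two dominant modes" is
  operationalized as the two most prominent peaks lying at a negative and
  a positive location.
- Frozen global thresholds are a deliberate simplification of BCM-style
  sliding thresholds; per-step threshold adaptation is not implemented.
- No spike timing, no temporal-history factor, no feedback connections;
  the integrated feedforward–feedback one-shot architecture built on these
  rules is out of scope.
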