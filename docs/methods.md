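# Methods

## Model

The network is a feedforward hierarchy of four competitive sheets of rate
neurons over a Gabor-filtered retina. Its assumptions, in order of
importance:

- **Locality.** Every synaptic update uses only the presynaptic rate, the
  postsynaptic rate (or its short-term trace), and the current weight.
  There is no error signal, no supervision, and no weight sharing.
- **Temporal continuity as the teacher.** All views of one object are
  presented consecutively (object-blocked schedule, views shuffled within
  the block each epoch). The postsynaptic trace
  `ȳ_τ = (1−η) y_τ + η ȳ_{τ−1}` outlives a single presentation, so weights
  learned during one view are steered by the firing caused by the previous
  views of the same object — this is the entire invariance mechanism.
- **Competition via a sparseness target.** After the activation pass, a
  sigmoid threshold is set so the population sparseness
  `a = (Σy/n)²/(Σy²/n)` matches a per-Layer target. Competition is
  winner-share-all: a small population with graded rates, not a single
  winner.
- **Bounded, retinotopic connectivity.** Each neuron samples its afferents
  without replacement from an isotropic Gaussian centred on its retinotopic
  projection; `σ = radius/1.5` so ≈67% of connections fall inside the
  stated radius. Sheets are toroidal: samples beyond an edge wrap. (With
  bounded sheets a corner neuron of the 32-grid preset cannot supply 200
  distinct in-radius sources; wrapping keeps the afferent statistics
  identical for every neuron. Resampling at edges remains available as an
  option for strongly diluted configurations.)

## Layer-1 input sampling

The retina has 32 channels: 4 wavelengths halving from `base_wavelength`
(default 16 px) × 4 orientations × a positive/negative rectified pair per
kernel. Kernels are even-symmetric, zero-mean (envelope-subtracted), with
envelope σ = 0.5·wavelength and aspect ratio 1.5 — standard V1-model
constants, configurable. Each channel is normalised once, at bank
construction, by the kernel's peak response to a full-contrast matched
grating, keeping filtering image-independent; responses are clipped into
[0, 1]. Images are edge-padded before convolution so that a uniform image
produces exactly zero response (zero padding would create spurious border
energy). Layer-1 connection counts per frequency band follow a halving
geometric series (8:4:2:1) favouring low frequencies; the channel within a
band is drawn uniformly per connection.

## Competition modes

Whether the sigmoid output of sub-threshold neurons is carried (small
graded rates) or zeroed outright is genuinely ambiguous in descriptions of
this model family, and the two readings have different physics, so both are
implemented as `LayerSpec.competition`:

- `"hard"` (default): the threshold is placed at the k-th most activated
  neuron, k chosen by bisection so the measured sparseness of the
  thresholded, sigmoid-transformed vector hits the target; everything below
  is exactly 0 and the k-th neuron fires at 0.5.
- `"graded"`: the sigmoid is applied to the whole sheet about the
  (1−a)-percentile threshold. Low-activation neurons keep small rates that
  shrink as β grows; at β ≥ ~1000 the code is effectively binary with an
  active fraction of exactly a.

The sigmoid-slope experiment uses `"graded"`, because the effect under
study *is* the participation of low-rate neurons in learning: at β = 10
their weak traces drag every neuron's weights toward the global mean input
(strongly hurting the self-scaling competitive rule), and raising β to 100
silences them. In hard mode that mechanism is absent by construction and β
has almost no effect. All other experiments use the default hard mode.

## Learning

Three rules share the trace machinery (Layer 1 always uses the
instantaneous rate instead of the trace, so spatial feature binding is
learned before any invariance):

- `hebb_normalized`: `w ← (w + α ȳ x)/‖w + α ȳ x‖₂`.
- `competitive_standard` (default): `δw_j = α ȳ (x_j − w_j)`. For
  `α·ȳ ≤ 1` and inputs in [0, 1] the update is a convex combination, so
  weights stay in [0, 1] without any normalisation.
- `oja`: `δw_j = α ȳ (x_j − ȳ w_j)`; identical to the competitive rule
  when ȳ = 1. For small steps Oja's rule is the differential form of
  Hebbian growth plus renormalisation, which is why those two rules score
  close together on many stimulus sets.

By default the postsynaptic term is the trace from the previous
presentation only (`ȳ_{τ−1}`), with no contribution from the current,
possibly never-seen view; a flag restores the blended trace. The trace is
reset at object boundaries so the last views of one object are not
associated into the next; carrying it across is available as a flag. When a
weight ceiling is set, clipping follows every update.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| sparseness `a` | 0.01 | fraction | ≈10 winners per 32×32 sheet; sparse distributed code |
| sigmoid slope β | 10 | 1/activation | graded rates; 100–1000 → near-binary |
| trace proportion η | 0.8 | — | trace memory ≈ 5 presentations, matches 9-view blocks |
| learning rate α | 0.5 | — | reaches convergence within 25 epochs/Layer at desk scale |
| epochs per Layer | 50 (25 in shipped experiments) | — | Layers train sequentially, lower Layers frozen |
| radius (32-grid) | 15 (L1, retina px), 7 (L2–4, grid units) | — | transitive Layer-4 field covers the whole retina (verified by graph reachability) |
| max_weight | off; 0.1 in clipping experiment, 0.06 in large preset | weight | spreads learning over many synapses under load |

## Synthetic stimuli

The generator emulates a turntable image library: each object is a filled
star-domain shape (four families: near-regular polygons, mild stars, Fourier
blobs, elongated ellipses with a bump) with object-specific extent and a
rotation-invariant interior shading (radial fade plus concentric rings whose
frequency is stratified across objects). Views rotate the shape in 40°
steps with mild shear/scale jitter. Consequences:

- Views of one object stay strongly pixel-correlated (the shading and
  silhouette are rotation-tolerant) while different objects decorrelate:
  within-object mean pixel correlation exceeds between-object mean on every
  generated set, and per-object block-mean dominance holds for typical
  seeds.
- All stimuli share a large centred bright-on-dark component, so absolute
  between-object correlations remain far higher than for photographs of
  distinct objects; top-Layer selectivities at desk scale (≈0.3–0.5 for the
  competitive rule at 9 objects) are accordingly lower than what distinct
  photographic objects support, and the shipped experiments read out
  orderings and directions, not absolute levels.
- What passing tests show: the trace mechanism binds rotated views onto
  shared neurons far above the untrained baseline (≈0.03), the competitive
  rule beats both normalisation rules on most stimulus draws, clipping helps
  under load, and β gates low-rate participation. What they do not show:
  performance on natural images, or the absolute selectivity levels
  reachable with a 256-px retina and full connection counts.

## Shipped experiment conditions (desk scale)

All experiments in `visnet.experiments` (used by `scripts/acceptance.py`
and the end-to-end tests) run a 64-px retina (wavelengths 16/8/4/2 px),
four 32×32 sheets with 100 afferents per neuron (Layer-1 radius 4 px,
higher radii 7), a = 0.01, β = 10, η = 0.8, α = 0.5, 25 epochs per Layer —
chosen once as the largest configuration that keeps a full
train-and-evaluate run at a few seconds on one core. Specifics:

- **Rule comparison** (10 paired runs): each run draws a fresh stimulus set
  (9 objects × 9 views) and network; the three rules train on identical
  inputs within a run.
- **Clipping** (10 paired runs, 20 objects × 9 views): ceiling 0.1 on
  Layers 1–3 vs none; also reports the fraction of Layer-3 weights within
  10% of the ceiling (clipped) or of the observed maximum (unclipped).
- **β effect** (6 paired runs, 20 objects, graded mode): β = 10 vs 100.
- **Capacity** (3 replicates per point): objects 2→6, synapses
  {50, 100, 200} with the Layer-2–4 radius scaled {5, 7, 10} to hold
  dilution roughly constant; capacity is the last object count above
  S = 0.6 before the first failure. At this sheet size only ~10
  presynaptic neurons fire per stimulus, so the number of *informative*
  afferents saturates between 100 and 200 synapses and the capacity curve
  flattens there; the 50→100 increase is robust, the 100→200 leg is
  flat-to-noisy depending on the seed.

## Numerical choices and degenerate inputs

- Threshold search: bisection over the kept-count k (hard mode), exploiting
  that measured sparseness is nondecreasing in k; ties broken by neuron
  index. All-equal activation sheets fall back to index-ordered top-k at
  rate 0.5 with a warning. Sheets with fewer strictly positive activations
  than k keep only the positive ones.
- Pearson rows with zero variance correlate 0 with everything (1 with
  themselves); negative correlations are clipped at 0 in the selectivity
  sum (switchable), pinning S's minimum at exactly 0.
- Weight updates run in a low-allocation in-place path verified
  element-for-element against the documented pure rule functions.
- The Gabor cache stores float32 responses; per-Layer afferent gathers are
  precomputed when they fit in ~0.5 GB.
- Lognormal weight fits fix the location at 0 and use only strictly
  positive weights; Kolmogorov–Smirnov statistics accompany the fitted
  (μ, σ).

## Known limitations

- No recurrent collaterals, no backprojections, no explicit inhibitory
  dynamics (competition is algorithmic), no colour, no clutter/saliency.
- The difference-of-Gaussians lateral-inhibition stage is implemented and
  tested but off in every preset; competition rests on the sparseness
  threshold.
- Selectivity levels on the synthetic sets are not comparable to
  photographic libraries (see above); the oja-vs-hebb ranking in
  particular is stimulus-statistics dependent and can invert on easy sets.
- The large-256 preset is provided for completeness and scales the verified
  mechanisms, but the shipped experiments do not run it.
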