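# Methods

## Problem and model

Wearable bioimpedance sensors placed over a peripheral artery record a
quasi-periodic pulsatile signal ΔZ: each heartbeat expands the artery,
and because blood conducts better than the surrounding tissue, −ΔZ rises
with the arriving pressure pulse. The package translates beat-segmented
ΔZ waveforms into continuous blood pressure (systolic, diastolic, or
pulse pressure — one model per target) using only a handful of reference
BP labels.

The regressor `y_NN = f_NN(x, u, Θ)` takes two inputs per beat:

* `x` — the beat waveform, down-sampled to 30 Hz and zero-padded to a
  fixed length N (default 60 samples, i.e. 2 s, covering heart rates
  ≥ 30 bpm; the length is configurable and no value of N is canonical);
* `u = (u¹, u², u³)` — three physiological features:
  `u¹ = (ΔZ)_A − (ΔZ)_C` (pulsatile amplitude swing, a proxy for arterial
  volume expansion), `u² = 1/(t_F − t_B)` (inverse systolic-to-reflection
  crest delay, a proxy for pulse wave velocity), and
  `u³ = 60/(t_J − t_A)` (beat-to-beat heart rate in bpm).

Architecture: conv1d(32 filters, width 5, ReLU) → conv1d(64, width 3,
ReLU) → max-pool(width 3, stride 1) → flatten → concatenate with `u` →
dense(60, ReLU) → dense(1). All inputs and outputs are standardized over
the complete dataset before training and predictions are mapped back to
mmHg for every reported statistic.

## The physics-informed loss

The supervised objective alone needs many labels. The additional,
fully unsupervised term exploits two facts: (i) the feature→BP map is
smooth and locally linearizable, and (ii) consecutive beats are close in
feature space. Anchored at beat *i*, the first-order Taylor polynomial
in the features is

    P_i(u) = f_NN(x_i, u_i, Θ) + Σ_k ∂f_NN/∂u^k |_i (u^k − u_i^k),

with the gradients taken by exact differentiation of the network (the
features enter at the concatenation, so ∂f/∂u is carried by the fully
connected head alone). Evaluating P_i at the next beat defines the
residual

    h_i = f_NN(x_{i+1}, u_{i+1}, Θ) − P_i(u_{i+1}),

which tends to 0 as consecutive segments coincide. The training
objective is

    L_total = L_conv + λ · L_phys,
    L_conv  = (1/S) Σ_labeled (y_NN − y_true)²,
    L_phys  = (1/P) Σ_pairs h_i²,

with λ = 1 by default (λ = 0 is exactly the conventional CNN baseline;
both settings run through the same implementation). Residual pairs never
span session boundaries — the locality premise fails across recording
gaps — and the physics loss divides by the number of pairs actually
evaluated, not by R−1, when sessions exclude some pairs. The expansion
is first order and in `u` only; the x-dependence at beat i+1 is absorbed
by the residual.

## Implementation of the derivatives

The network and all of its derivatives are implemented directly in
NumPy. Optimizing L_phys requires the mixed second-order terms
∂²f/∂u∂Θ. With ReLU activations these are written out analytically
under the standard almost-everywhere convention — activation masks are
treated as locally constant (ReLU″ = 0) — which is the same quantity
reverse-over-reverse automatic differentiation computes. Because `u`
enters only at the concatenation, the Taylor term touches only the
output weights and the feature columns of the first dense layer; every
implemented derivative is verified against central finite differences
in the test suite (relative error ≤ 1e-4 for input gradients, absolute
error ≤ 2e-7 for parameter gradients of the full composite loss).

Finite-difference checks near ReLU kinks use perturbations small enough
to stay inside a linear region; the derandomized test seeds keep those
comparisons stable.

## Fiducial landmarks

Nine landmarks A..J (letter I unused) are placed on the inverted
waveform −ΔZ per beat: A beat foot, B systolic crest, C global −ΔZ
maximum (the amplitude reference; usually coincides with B), D
inter-wave valley, E steepest reflection upstroke, F reflection crest,
G steepest decay, H decay inflection, J beat end. Only A, B, C, F, J
feed the three features, so downstream results are insensitive to the
exact placement of D, E, G, H. Crests are detected on a lightly
Savitzky-Golay-smoothed copy with a prominence threshold of 10% of the
beat's swing; the systolic crest is the most prominent crest and the
reflection crest the most prominent one after it. A beat without two
prominent crests raises a detection error carrying the beat index
(callers may drop such beats instead).

Two readings of the landmark letters are possible (crest-based as above,
or slope-based with B at the maximum upstroke slope); the crest-based
reading is used because `u²` is defined as the inverse delay between the
two impedance-drop arrivals, which are the two crests of −ΔZ.

## Preprocessing chain and its order

normalize by Z0 when available (samples and Z0 must share units; without
Z0 the raw-ΔZ mode is flagged) → segment at supplied beat boundaries
(or detect onsets as prominent ΔZ peaks) → extract fiducials and
features per beat at the native rate → resample to 30 Hz and zero-pad →
three-beat moving average with one-beat overlap (stride 2) applied to
waveforms, features, and labels, windows never spanning sessions →
standardize. Features are computed before smoothing; "one-beat overlap"
is read as consecutive windows sharing one beat (stride 2), so each
session of R beats yields floor((R−3)/2)+1 smoothed beats. Whole-dataset
(transductive) standardization matches the physics loss, which also
sees every beat; a strictly train-only variant is available by applying
one dataset's recorded statistics to another
(`apply_norm_stats`).

## Label budgets

* Minimal criterion: 1-mmHg bins tile [min, max] of the labels
  (K = ceil(range) bins, anchored at the minimum, final bin closed on
  the right); one uniformly drawn beat per non-empty bin is labeled.
  1000 beats spanning 120–160 mmHg give exactly 40 training and 960
  test beats.
* Growing sets: one draw per non-empty 0.5-mmHg bin forms a pool of k
  points; a fixed random ordering of the pool is consumed in nested
  prefixes of sizes 1, 3, 5, …, giving ceil(k/2) models (125 → 63;
  pools of 125/77/69 → 137 models over three targets).

## Training

Full-batch Adam (the datasets are ~10³ beats), learning rate 1e-3,
β = (0.9, 0.999). Training stops as soon as the supervised loss reaches
0.01 on the standardized scale — checked before each update, so both
the physics-informed model and the λ = 0 baseline stop by the identical
rule; 0.01 in mmHg² would be practically unreachable, so the threshold
is read on the normalized scale on which the network is trained.
Hitting the epoch cap (default 20 000) flags the report as
non-converged rather than raising; a non-finite loss raises a
divergence error with the epoch index. Identical seeds reproduce
identical trajectories.

## Synthetic data generator

The generator is first-class: it produces recordings whose structure is
exactly the set of assumptions the method rests on, with known ground
truth. Each beat's −ΔZ is a two-Gaussian pulse (systolic crest at
0.15 s, σ = 40 ms; reflection crest at 45% amplitude, σ = 60 ms) —
deliberately not a hemodynamic simulation: Gaussians make the fiducial
and gradient ground truth exact, which is what parameter-recovery tests
need. Blood pressure follows a piecewise-linear cold-pressor-style
schedule (two elevations of ~44 mmHg with recoveries, four sessions,
~750 s) plus AR(1) beat-to-beat noise (ρ = 0.9, σ = 1 mmHg), keeping
consecutive beats close as the sequential residual assumes.

Three couplings tie the beat morphology to BP:

| coupling | form | default | emulates |
|---|---|---|---|
| amplitude | a(BP) = α₀ − α₁·ΔBP | α₀ = 1, α₁ = 0.01/mmHg | peripheral vasoconstriction |
| reflection delay | d(BP) = d₀ − d₁·ΔBP | d₀ = 0.28 s, d₁ = 1.5 ms/mmHg | pressure-dependent pulse wave velocity |
| heart rate | HR(BP) = h₀ + h₁·ΔBP − h₂·ΔBP² | 70 bpm, 0.8, 0.02 | biphasic cold-pressor HR response |

The quadratic HR coupling makes ∂BP/∂u³ change sign across the response
vertex, so the sign-flip seen in gradient-interpretation analyses is
reproducible in simulation. On top of the couplings, each beat receives
physiological scatter — amplitude jitter (SD 0.08), delay jitter
(SD 12 ms), heart-rate variability (SD 2.5 bpm) — plus additive
waveform noise (SD 0.03). The jitter magnitudes are set so that the
latent feature–BP correlation is about |r| ≈ 0.9 before smoothing,
the high-correlation regime in which the gradient interpretation is
meaningful; without this scatter the features would determine BP almost
exactly and the label-efficiency question would be trivial. The
analytic gradient truth is the implicit-function inverse per component:
∂BP/∂u¹ = −1/α₁, ∂BP/∂u² = d(BP)²/d₁, ∂BP/∂u³ = 1/(h₁ − 2h₂·ΔBP).

What the generator does not emulate: motion artifacts, respiration
coupling, baseline wander, sensor drift, morphology change beyond the
two-Gaussian family, and any cross-feature dependence not mediated by
BP. Passing tests on this generator therefore demonstrate correct
mechanics and the claimed label-efficiency behaviour under the method's
own assumptions — not performance on real wearable recordings.

## Numerical choices and degenerate inputs

* Standardization uses one scalar mean/SD for the whole waveform matrix
  (per-position statistics would distort morphology), per-component
  statistics for `u`, scalar for labels; zero-variance channels raise.
* Resampling is linear interpolation onto the grid k/30 Hz (constants
  are preserved exactly); a beat longer than pad_len/rate raises rather
  than truncating silently.
* Bin tiling is anchored at min(labels); the final bin is closed on the
  right; empty bins contribute no training point.
* Max-pool argmax ties resolve to the earliest window position.
* Bland-Altman limits are bias ± 1.96·SDE with SDE on the n−1
  denominator, so RMSE² = ME² + SDE²·(n−1)/n holds as an identity.
* The AAMI flag is the simplified classical criterion (|ME| ≤ 5 mmHg
  and SDE ≤ 8 mmHg), not the standard's full grading procedure, and is
  labelled as simplified in reports.
* Constant inputs make Pearson's r undefined: a warning is emitted and
  the correlation reported as missing while the other metrics are
  returned.
* Gradient trend lines bin predictions by rounding to the nearest
  integer mmHg; SD_avg averages the across-model trend SD over the
  integer BP values where at least two models contribute; group trends
  use means.

## Problem sizes used in the shipped experiments

The packaged simulation study uses the default generator (1000 raw
beats → 497 after smoothing, ~50 labeled under the minimal criterion)
with ten paired seeds for the physics-informed vs conventional
comparison, and three models per size group (1/5/9 vs 41/45/49 labels)
for the growing-set consistency analysis. These sizes match the scale
of one participant's recording session in a typical cold-pressor
protocol.

## Known limitations

* The physics loss presumes beat-to-beat locality; long gaps, arrhythmia
  or abrupt posture changes violate it (session boundaries are the only
  mitigation provided).
* Transductive standardization and the unsupervised loss both see the
  test inputs; deployment on truly unseen streams requires the
  train-statistics mode and should expect some degradation.
* Fiducial detection assumes a visible reflection crest; heavily damped
  or very noisy morphologies raise detection errors rather than
  guessing.
* First-order expansion only; strongly curved feature→BP relationships
  between neighbouring beats are absorbed into the residual rather than
  modelled.
* The waveform path sees strictly more information than the features
  extracted from it, so the network initially attributes its output to
  `x`; the physics loss transfers that attribution onto `u` only
  gradually. Because training halts when the *supervised* loss reaches
  its threshold, the magnitude of the learned feature gradients depends
  on how many epochs that takes — models that converge quickly report
  smaller (though correctly signed) gradients than the fully
  physics-converged map would. Across-model comparisons of gradient
  trends should account for this epoch dependence; the shipped
  growing-set experiment measures and exposes it rather than hiding it.
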