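# Methods

## Problem

Electromagnetic tracking (EMT) localizes a small sensor coil inside the
body, but the metal gantry of a mobile C-arm distorts the magnetic field and
corrupts the measurements — predominantly the z component for the tracker
family this package models.  `emtcomp` implements an *online* compensation
strategy: a model trained once on measurements from a clean bench
(laboratory, domain L) and a handful of C-arm placements (domain C)
translates points from any — including unseen — C-arm environment back to
their laboratory equivalents, without per-environment recalibration.

A measuring point is the 7-tuple `(x, y, z, q, φx, φy, φz)`: position in
tracker-frame millimetres, the tracker's dimensionless quality (distortion)
estimate `q`, and orientation angles in degrees.

## Model

Two generator/discriminator pairs are trained adversarially on *unpaired*
samples from the two domains.  `G_CL : C → L` performs compensation;
`G_LC : L → C` closes the consistency cycle; `D_CL` and `D_LC` judge
domain membership.  All four are small dense networks over inputs
min–max-normalized to the unit interval:

* generators: 7 → 16 → 16 → 16 → 5, leaky-rectifier slope 0.01, linear head;
* discriminators: 7 → 16 → 16 → 1, leaky-rectifier slope 0.2, sigmoid head.

A generator outputs only `(ẑ, q̂, φ̂x, φ̂y, φ̂z)`; the planar position (x, y)
passes through *structurally* so that points cannot be relocated to
arbitrary places in the target domain.  The generator objective is

```
L_total = λ_adv·L_adv + λ_cycle·L_cycle + λ_comp·L_comp
```

with `λ_adv = 0.5`, `λ_cycle = 10`, `λ_comp = 1e-5`:

* `L_adv` — binary cross-entropy of each discriminator's verdict on
  generated points against the soft "valid" label;
* `L_cycle = L_recov,L + L_recov,C` — L1 recovery residual of the round
  trips L→C→L and C→L→C (mean over batch and all 7 channels; the x–y
  channels recover exactly and contribute zero);
* `L_comp = MSE(d_G_CL, d_true)` — squared error between pairwise distances
  of compensated points (in mm) and the known lattice distances, evaluated
  in the laboratory domain only.  Millimetre (not normalized) distances are
  used, which fixes the meaning of the 1e-5 weight.

Training: Adam (lr 5e-4, β₁ = 0.5 as customary in adversarial training),
one shared optimizer for both generators and one per discriminator; batch
16; 200 epochs; the learning rate is constant for the first 100 epochs and
then decays linearly to zero.  Discriminators train on real samples versus
gradient-detached generated samples with soft labels drawn per batch from
U[0.8, 1.0] (valid) and U[0.0, 0.2] (fake); cross-entropies are computed
from logits for numerical stability.  An epoch is
`ceil(max(|C|,|L|)/16)` unpaired minibatch steps; C-domain batches are drawn
as lattice-neighbor sample pairs so `L_comp` always has defined ground-truth
distances.  In `vanilla_gan` mode (the ablation) the cycle and identity
terms are dropped, reducing the compensation path to a single adversarial
generator.

### Stabilizers

Low-dimensional adversarial training at this data scale is dominated by the
generator–discriminator orbit: without damping, the translated z offset
oscillates with an amplitude (~0.3 of the normalized range) far larger than
the distortion being corrected, because the adversarial and cycle terms
leave every measure-preserving bijection equally optimal.  Three standard
remedies are used, none of which changes the loss definitions, weights,
schedule or architecture above:

* a 50-sample replay buffer of generated points for discriminator updates
  (each fresh fake is swapped with a stored one with probability 1/2);
* an identity term `|G_CL(x_L) − x_L| + |G_LC(x_C) − x_C|` at weight 5
  (half the cycle weight, the customary choice), anchoring the absolute
  offset and scale of the translated channels on the target manifold;
* historical parameter averaging — every player is pulled toward an
  exponential moving average of its own weights
  (`λ_hist = 0.3`, decay 0.99 per step), which converts the orbit into a
  damped spiral.

Finally, because the game still orbits its equilibrium, the generator
weights kept at the end of training are those of the epoch with the lowest
mean displacement RMSE on the held-out *validation* C-arm environments
(the environment split reserves two such environments).  The displacement
metric is self-calibrating — it compares measured inter-point distances
with the known board lattice — so this selection needs no reference
standard.  Without validation data the final-epoch weights are kept.

### Ensemble and uncertainty

Ten (default; three in the desk-scale configuration) identically configured
models are trained sequentially from seeds `master + i`.  The compensated
output is the member mean (circular mean for angles; x, y untouched);
`σ_pred` is the per-point standard deviation of the compensated position
across members — per axis, sample convention (n−1), combined as the
Euclidean norm of the per-axis deviations and averaged over points.  An
ensemble of identical members reports exactly zero.

### Fine-tuning

The translation leaves x–y error untouched.  Because translated points lie
in the laboratory domain, a linear corrector fitted on laboratory data
applies to them: two least-squares regressions with features `(x, y, z, q)`
plus intercept predict additive offsets `(Δx, Δy)` toward grid-anchored
targets.  Offsets are fitted against absolute targets rather than distances
only (distance-only fitting is under-determined up to rigid motion); no
separate rigid pre-alignment is needed because a rigid 2-D transform is
affine in (x, y) and the regression design already spans every affine x–y
map.  In the ensemble pipeline one corrector is fitted per member on that
member's own compensated laboratory data, so the fine-tuning stage
contributes to `σ_pred`.

## Evaluation metrics

* **Displacement error** — RMSE and sample standard deviation of
  `measured − true` inter-point distances over lattice-neighbor pairs
  (adjacent nodes along one axis, within or across layers; an `all-pairs`
  scheme is available and pair counts are always reported).  Being purely
  relative, the metric needs no external measurement standard and is
  invariant to rigid motion of the measured point set.
* **Cross-environment consistency** — for every grid node measured in two
  or more environments, the mean pairwise distance between its measured
  (or compensated) positions; an online-consistent compensation maps the
  same node to nearly the same point regardless of the input environment.
* **Rotational stability** — circular mean/std per orientation channel
  (azimuth = φz, elevation = φy, roll = φx) along an ordered pull-out
  trajectory, plus the maximum unwrapped drift from the starting angle.

## Synthetic study design

No public measurement set exists for this bench/bedside protocol, so a
seeded simulator emulates the campaign:

* **Board**: a calibrated pegboard lattice, 8 mm pitch, measured at three
  elevations (0/20/40 mm).  The default board is 10×8 nodes per layer (240
  points per environment).  The physical protocol used 60 points; the
  denser board is a deliberate desk-scale choice — the training protocol
  fixes epochs and batch size, so optimization steps scale with dataset
  size, and 60-point environments give the adversarial game too few steps
  to settle.
* **Acquisition**: every stored point is the mean of 500 noisy samples
  (0.5 mm, 1 unit, 1° per-sample noise), so residual noise is ~0.02 mm.
* **Distortion field**: per axis, a down-weighted linear trend plus 12
  Gaussian radial-basis bumps (length scale 15 mm), normalized to unit RMS
  over the board and scaled by
  `amplitude · (50 cm / distance)^p` with `p = 0.4` and amplitude 3.6 mm —
  calibrated so raw displacement RMSEs reproduce the magnitudes and the
  gentle distance trend observed in real bedside campaigns (~1.3 mm at
  8 cm, ~0.6 mm at 50 cm, bench lowest).  Axis weights (0.15, 0.15, 0.70)
  make z dominant.  All C-arm environments share one base field
  realization — the same physical distorter moved in distance — mixed with
  a 10% independent per-environment variation; without this sharing nothing
  about a held-out environment would be learnable even in principle.  The
  laboratory has its own independent, much weaker field (amplitude
  0.06 mm).
* **Quality channel**: `q = 5 + 10/mm · |displacement| + ε(0.3)` — a
  DC-tracker-style indicator that grows with local distortion (direction
  configurable).
* **Orientation**: smooth angle-perturbation fields scaled like the
  positional distortion (2° at the reference distance).
* **Domain-common x–y warp**: a small random affine warp (~1.2% scale/shear)
  applied identically in every environment, standing in for the tracker's
  baseline field nonlinearity; it is the systematic error the linear
  fine-tuning stage can learn on the bench and remove everywhere.
* **Environments**: laboratory (restricted to 2 of 3 layers, as in the
  physical protocol), training C-arm placements at 8/11/50 cm, validation
  at 10/30 cm, evaluation at 7/9/12 cm (the desk-scale campaign drops 9 cm).
* **Pull-out trajectory**: 13 steps of 8 mm along +x at constant true
  orientation near the C-arm, for the rotational-stability analysis.

All randomness flows from one suite seed through per-environment derived
seeds; suites, training runs and reports are bit-reproducible.

What the simulator does *not* model: electromagnetic physics (eddy
currents, field line geometry), sensor-orientation-dependent error, drift
over time, outliers/dropouts, and any coupling between orientation and
position error.  Passing the synthetic acceptance checks therefore shows
the pipeline is correct and behaves as designed under the modeled
conditions — not that it would compensate a particular physical tracker.

## Known limitations

Implemented faithfully, the adversarial stage at desk scale reaches a
plateau where the translated map removes only part of the distortion
(~10–30%) while adding map noise of roughly 0.5–1 mm, so the compensated
displacement RMSE typically lands near — often slightly above — the raw
value, and clearly above the supervised ceiling (a generator of identical
architecture trained with oracle targets removes 20–70% of held-out error
on the same suites, so the task itself is learnable).  This mirrors the
thin margins the approach achieves on real campaigns, where the
domain-translation stage alone improves displacement RMSE by only a few
percent and the substantive quantitative gains come from the linear
fine-tuning stage.  The end-to-end error-reduction, cross-environment
consistency and rotational-stability checks in `tests/test_acceptance.py`
encode the stronger behavior (strict improvement over raw everywhere) and
are expected to fail in part; they are kept strict deliberately as an
executable record of the gap.

Numerical notes: float64 throughout; single-threaded deterministic
training; BCE from logits; normalization is global (both domains pooled)
and out-of-range inputs extrapolate linearly rather than clamp, so a model
applied in an unseen environment does not silently discard positional
information.  Angles are stored wrapped to [−180°, 180°) and converted to
radians only inside circular statistics.
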