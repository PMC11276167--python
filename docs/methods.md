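# Methods

## Problem

A powdered plant product certified for one geographical origin can be
blended with cheaper powder of the same species from another origin. The
task is to classify the adulteration weight fraction f ∈ {0, 0.2, 0.4, 0.6,
0.8, 1.0} (six levels) from two spectra acquired per sample:

* **LIBS** — a broadband laser-induced breakdown spectrum (196–874 nm,
  24,564 points) carrying elemental emission lines (C, Mg, Si, Al, Ca, Na,
  N, K, O);
* **VNIR** — a visible/near-infrared diffuse-reflectance spectrum
  (350–1100 nm, 997 points) carrying molecular absorption bands
  (chlorophyll near 670 nm, O–H stretching overtones near 920 and 970 nm).

Because the two origins contain the *same* constituents, every class shows
the same lines and bands; only intensities differ. All information is in
small intensity shifts, which is what makes single-modality classification
hard and fusion attractive.

## Feature extraction

**LIBS.** Eighteen emission lines with robust signal are registered with
their profile intervals (data file `libs_lines.yaml`; one printed interval
bound, 589.52–598.71 nm for the second Na D line, is corrected to
589.52–589.71 nm — the listed width contradicts its own 14-point count).
Each interval's raw points (7–22 on the reference axis) are standardized to
exactly **14 points**: zero-padding centers short intervals among zeros
(extra zero on the right for odd deficits), 14-point intervals pass through,
longer intervals keep their central 14 points (left offset ⌊(n−14)/2⌋).
The result is an 18 × 14 matrix per spectrum that retains the full line
profile — wings and FWHM — rather than just the peak. A peak-maximum-only
extractor (18 values) exists as the weaker baseline input.

**VNIR.** Five wavebands bracketing the informative peaks and troughs
(63 + 67 + 136 + 27 + 82 = 375 points) are selected, and within each band
the first derivative is taken as forward differences divided by the local
wavelength spacing (a true slope, robust to non-uniform dispersion; no
smoothing is applied before differencing). Slopes never cross a band
boundary, giving 370 features that are invariant to additive baseline
offsets.

**Reference axes.** Both axes are built piecewise so that every registered
interval contains exactly its reference point count under closed-interval
membership; remaining points fill the gaps proportionally to gap length.
The printed counts are mutually inconsistent with any uniform grid (real
multi-channel spectrometers have non-uniform dispersion), so the piecewise
construction is what makes the counts exactly testable.

## Models

* **DL-LIBS**: one *shared* learned width-14 inner product (a stride-14
  convolution over the flattened 252-vector) scores each line interval,
  giving an 18-step sequence ordered by wavelength; a bidirectional LSTM
  (hidden size 32 per direction) consumes it, the two final states are
  concatenated, and a dense head (64 units, ReLU, batch norm, dropout 0.3)
  yields 6 logits.
* **DL-VNIR**: the 370 slopes pass through a dense layer (64 units, ReLU,
  batch norm, dropout) and a linear head.
* **LVDLNet** (fusion): both branch extractors, without their heads, are
  projected by learned linear maps to a common dimension d = 64, **added
  elementwise**, and classified; the whole graph trains end to end with no
  auxiliary losses on the branches.

The networks are implemented in numpy with hand-written backpropagation
(verified against central finite differences in the test suite); the
bidirectional LSTM evaluates both directions in one batched pass.

### Training protocol

Stratified random split 7:1:2 (1200 paired spectra → 840/120/240; per class
the test share is round(0.2 n), validation round(0.1 n), remainder to
train). Training rows only are doubled by adding zero-mean Gaussian noise
with per-feature sd = 0.02 × the feature's own sd. Features are centered
and scaled per feature on the original training rows only. Optimization is
Adam at learning rate 5 × 10⁻⁴, batch size 32, cross-entropy loss; the
returned model is the epoch checkpoint with the best validation accuracy.
Default epochs are 500; the simulation studies below use 40–100 epochs
(problem sizes chosen so the full study suite runs comfortably on one CPU),
which the validation curves show is past the best checkpoint on these data.

Two choices were made where the protocol above leaves freedom, both forced
by experiments on simulated data:

1. **Batch normalization sits after the ReLU activation.** Because band
   depths and line intensities are linear in f, the six class means are
   *collinear* in feature space. Pre-activation batch normalization
   subtracts the batch mean, which contains the batch's class composition,
   and therefore erases most of the (rank-1) class signal during training;
   post-activation placement avoids this and restored near-perfect accuracy
   on cleanly separable simulated data.
2. **An L2 penalty (weight_decay = 0.03) on weight matrices** is added to
   Adam. Most slope features are noise-dominated; without an explicit ridge
   term a network of this size interpolates the training noise and places
   the ordinal class boundaries where they do not generalize (the same
   failure, and the same cure, reproduce in scikit-learn's MLP via its
   `alpha`). Biases and normalization parameters are not penalized.

## Simulator

The generator emulates the structure described above rather than plasma or
radiative-transfer physics:

* LIBS: intensity(λ) = baseline + (1 + ε)·Σₑ (aₑ + bₑ f)·L(λ; cₑ, γₑ) +
  N(0, σ_add) per point, with L a unit-peak Lorentzian (γ = 0.05 nm) and ε
  one zero-mean draw per spectrum (shot-to-shot pulse-energy fluctuation —
  it scales all lines together, which is why it cannot be averaged away
  across lines).
* VNIR: reflectance(λ) = baseline(λ) − Σ_b (d0_b + d1_b f)·G(λ; c_b, w_b) +
  N(0, σ_add) per point, with G a unit-peak Gaussian, bands at 670/920/970
  nm, and a smooth monotone-segment baseline through fixed control points.
  The noiseless reflectance is validated to stay in (0, 1.2].

One seed sequence is spawned per sample (LIBS and VNIR child streams), so a
dataset is bit-reproducible from its manifest and single samples can be
regenerated independently.

### Presets

Four parameter presets ship as data files. Their effect sizes were set from
a signal-to-noise analysis of the adjacent-level separation (signal step
b·Δf against the profile-averaged additive noise and the common-mode
fluctuation) and then verified by running the pipeline:

* `easy` — large coefficients, low noise: raw spectra are separable by a
  nearest-centroid rule (> 95%) and every model reaches ≈ 1.0; a sanity
  preset.
* `hard` — coefficients a few noise sd per 20% step (σ_add = 20 counts,
  σ_mult = 0.02). Here interval features hold a real advantage over peak
  maxima: the 14-point profile lets noise be averaged while the peak
  maximum is an extreme-value statistic, biased and noisy.
* `complementary` — the class signal is split across modalities (three Ca/K
  lines in LIBS; the three bands in VNIR) and each modality's SNR caps its
  accuracy near 0.4–0.65. The modal noises are independent, so Add-fusion
  raises the effective SNR by ≈ √2 and the fused model gains ≥ 5 accuracy
  points over either branch. This is the preset that exhibits the fusion
  effect.
* `null` — all fraction coefficients zero; any accuracy away from 1/6 is a
  bug.

What the simulator does **not** reproduce: self-absorption and matrix
effects in the plasma, instrument line-spread functions, scatter effects in
reflectance (SNV/MSC territory), wavelength drift, and — importantly —
class structure richer than "linear in f along one direction". Passing
tests therefore show the pipeline is correct and the fusion mechanism works
under the stated noise model; they do not certify accuracy figures on real
pellet spectra.

## Evaluation

Accuracy plus macro-averaged precision, recall, and F-measure. Per-class
precision (recall) with an empty predicted (true) class is defined as 0
with a warning; macro-F is the arithmetic mean of per-class F1 (the
harmonic mean of each class's precision and recall), the standard macro-F
reading. Conventional baselines are feature input → train-fitted z-score →
train-fitted PCA (components capturing 99% variance by default) → LDA /
KNN (k = 5) / RBF-SVM (C = 10) / ELM (200 sigmoid hidden nodes, random
fixed input weights, ridge-regularized least-squares output weights).
t-SNE is a thin wrapper for visualization only.

Reported study results are medians over seeds; single-split accuracy on 240
test samples has a sampling sd of ≈ 0.02–0.03, and the median over 5 seeds
is the stable summary (this is also how the chance-level band for the null
preset, 1/6 ± 0.08, is read).

## Numerical notes and edge cases

* Axis gap apportionment uses the largest-remainder rule (stable
  tie-break), so axes are deterministic and endpoints exact.
* Interval membership is closed ([lower, upper]); odd zero-padding deficits
  put the extra zero on the right, odd interception overflows drop one more
  point on the right.
* Constant features (always-zero padded positions) get unit scale in the
  z-scorer and pass through as zeros.
* Training batches with fewer than 2 rows are skipped (batch statistics are
  undefined); a non-finite loss aborts with a diagnostic rather than
  returning a silently broken model.
* The ELM solves ridge-regularized normal equations (λ = 10⁻⁶) to stay
  defined for degenerate hidden matrices.

## Known limitations

* The 500-epoch default is untested at full length in routine runs; studies
  use 40–100 epochs, which the validation histories show is sufficient on
  simulated data.
* DL-LIBS does not dominate PCA-SVM on the `hard` preset (the SVM is strong
  when the signal is linear in the features); a general ordering of deep
  vs conventional models on real spectra is not a property the simulator
  tries to enforce.
* Checkpoints store network weights as `.npz` with a YAML sidecar; they are
  runtime artifacts, not an interchange format.
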