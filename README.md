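# lvdlnet

Classification of adulteration levels in powdered plant material by fusing
two spectral modalities: laser-induced breakdown spectroscopy (LIBS,
elemental emission lines) and visible/near-infrared reflectance (VNIR,
molecular absorption bands). The package is for chemometricians and
spectroscopists who want a runnable, testable implementation of
feature-level Add-fusion between a line-interval LIBS branch and a
derivative-spectroscopy VNIR branch, together with the conventional
PCA + LDA/KNN/SVM/ELM baselines and a paired-spectrum simulator so the
whole method works without instrument data.

## Method

Each sample i carries a LIBS spectrum (24,564 points, 196–874 nm) and a
VNIR spectrum (997 points, 350–1100 nm) plus a label for the adulteration
weight fraction f ∈ {0, 0.2, …, 1.0} (six classes).

* **LIBS branch (DL-LIBS).** 18 registered emission-line intervals are each
  standardized to exactly K = 14 points (zero-padding / retention /
  interception of the central block). A single shared width-14 convolution
  kernel w produces one value per line, uₑ = tanh(w·xₑ + b); the sequence
  (u₁, …, u₁₈), ordered by wavelength, feeds a bidirectional LSTM whose
  concatenated final states go through a dense head to 6 logits.
* **VNIR branch (DL-VNIR).** Five wavebands (375 points total) are reduced
  to within-band first derivatives sⱼ = (y_{j+1} − y_j)/(λ_{j+1} − λ_j)
  (370 slopes), classified by a dense network.
* **Fusion (LVDLNet).** Both branch extractors are linearly projected to a
  common dimension d and combined by elementwise addition,
  z = P_L h_LIBS + P_V h_VNIR, before the classification layer; training is
  end to end.
* **Protocol.** Stratified 7:1:2 split (1200 → 840/120/240), training-row
  white-noise augmentation (doubling), Adam at lr 5·10⁻⁴, batch 32,
  best-validation-epoch checkpointing. Metrics: accuracy and macro-averaged
  precision / recall / F-measure (Acc, Mac_P, Mac_R, Mac_F).

Details, parameter defaults and design rationale: `docs/methods.md`.

## Worked example

```python
import lvdlnet as lv
from lvdlnet.models import ModelConfig, LVDLNetClassifier

# 1200 paired spectra on the "complementary" preset: the class signal is
# split across the two modalities and each alone is noise-capped
ds = lv.generate_preset_dataset("complementary", spectra_per_level=200, seed=1)

model = LVDLNetClassifier.from_dataset(ds, config=ModelConfig(epochs=100, seed=1))
res = model.fit()
print(res.summary())
```

```
FusionNet fit results
============================================
train/val/test sizes : (840, 120, 240)
epochs run           : 100
best epoch (val acc) : 19 (0.7000)
final train loss     : 0.0575
--------------------------------------------
test Acc   : 0.7167
test Mac_P : 0.7211
test Mac_R : 0.7167
test Mac_F : 0.7064
============================================
```

The fused model reaches 0.72 test accuracy where the single-modality
models trained on the same split reach 0.46 (DL-LIBS) and 0.62 (DL-VNIR):
each branch is capped by its own noise, and because the two noise sources
are independent, Add-fusion recovers levels that either modality alone
confuses. `res.test_confusion` shows the remaining errors
are between adjacent adulteration levels, as expected for an ordinal
signal.

The same pipeline is scriptable from the shell:

```sh
lvdlnet simulate --preset complementary --per-level 200 --seed 1 --out data/demo
lvdlnet train data/demo --model lvdlnet --epochs 100 --seed 1 --out runs/fused
lvdlnet compare data/demo --seeds 0,1,2 --epochs 100 --out runs/comparison
```

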