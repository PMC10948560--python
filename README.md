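# teledermo

Store-and-forward teledermoscopy without shipping images: each dermoscopy
image is compressed into a **DermoFeature Profile (DP)** — a 7×7 diagonal
matrix holding seven selected lesion features — profiles of many patients
are collated into a **DMpDP**, and the collation is hidden inside the
clinician's recorded patient-information audio signal (**RPS**) by SVD
watermarking. The receiver filters the channel output, extracts the
profiles with shared side information, recovers the audio, and classifies
every profile into one of four lesion classes (benign keratosis, basal
cell carcinoma, melanoma, melanocytic nevus) with a second-order
polynomial SVM. One profile costs 392 bytes; 248 patients travel in less
space than a single compressed dermoscopy image.

The package is aimed at researchers studying payload embedding in
physiological/clinical media and at anyone who wants a fully synthetic,
reproducible end-to-end testbed for feature-profile telemedicine: every
stage (lesion rendering, hair removal, segmentation, feature extraction,
watermarking, channel attack, enhancement, classification) runs on
generated data with known ground truth.

## The method

**Features.** From the segmented lesion (gray image `I`, mask) the seven
selected features are the weighted intensity-difference frequency at
offset distance δ=10 and orientations θ ∈ {0°, 45°, 90°, 135°},

```
WIDF_{δ,θ} = Σ_{i=0}^{ξ−1} (ξ − i) f_i / ξ ,
```

with `f_i` the relative frequency of absolute intensity difference `i`
over in-mask pixel pairs and ξ = 256 levels; the maximum Feret diameter;
the box-counting geometric index `G_I = log N_B / log L_B` of the
boundary; and the contour steepness `C_T = Var(D_r) / mean(D_r)` of the
centroid-to-perimeter radial distances. Min-max scaled to [0, 1], the
seven values form the DP diagonal.

**Embedding.** The transformed carrier segment (time, DCT, DST, or the
single-level DWT approximation band), amplified by β and reshaped into a
matrix `R`, is watermarked through its singular values:

```
R = U S Vᵀ,   D = S + αP,   D = U_w S_w V_wᵀ,   R_w = U S_w Vᵀ,
```

and the receiver, holding `{U_w, V_w, S}`, inverts the chain:
`R_w* = U* S_w* V*ᵀ`, `D* = U_w S_w* V_wᵀ`, `P* = (D* − S)/α`, recovering
the carrier as `U* S V*ᵀ / β`. On a clean channel the round trip is exact
to floating point; under an additive white Gaussian noise attack, the
amplification β keeps the singular-value perturbation relatively small,
and receiver-side enhancement (Wiener, adaptive Wiener, power spectral
subtraction, wavelet shrinkage) substitutes for part of it.

## Worked example

```python
import numpy as np
import teledermo as td
from teledermo import classify, pipeline, profile
from teledermo.features import FEATURE_NAMES

corpus = td.generate_class_set(n_per_class=20, seed=11)
table, scaler, _ = pipeline.corpus_features(corpus)
model = classify.train(pipeline.scale_table(table, scaler), seed=0,
                       scaler=scaler)

subset = pipeline.scale_table(table, scaler).groupby("label",
                                                     sort=False).head(12)
dps = [profile.build_dp(r[list(FEATURE_NAMES)].to_numpy(dtype=float), f"p{i}")
       for i, (_, r) in enumerate(subset.iterrows())]
dmpdp = profile.assemble(dps, "sequential", grid_rows=4)

cfg = pipeline.RunConfig(form="sequential", domain="dwt", alpha=1.0,
                         beta=100.0, snr_db=-5.0,
                         filter_method="spectral_subtraction", seed=0)
rec = pipeline.run_channel_trial(dmpdp, td.default_carrier(seed=2), cfg,
                                 model=model,
                                 true_labels=subset["label"].to_list())
print(rec["c_w"], rec["accuracy"])
```

prints (from `examples/05_noisy_channel_classification.py`):

```
5-fold CV accuracy on 80 synthetic images: 0.950
beta=     1 filter=none                 C_w=0.735  accuracy=0.500
beta=   100 filter=none                 C_w=0.956  accuracy=0.938
beta=   100 filter=spectral_subtraction C_w=0.958  accuracy=0.938
```

Under a −5 dB channel attack the unamplified embedding loses half the
diagnoses; amplifying the embedding segment (β = 100) restores watermark
correlation C_w to 0.96 and accuracy to 0.94, and spectral subtraction
holds that performance at the lower amplification. The `examples/`
directory walks through each capability one script at a time; a thin
`teledermo` command-line tool (`synth`, `train`, `transmit`, `attack`,
`receive`, `evaluate`, `scenario`) wraps the same library calls for shell
use.

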