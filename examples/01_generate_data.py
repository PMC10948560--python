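"""Generate a small synthetic study: lesion images and a carrier signal.

Creates three dermoscopy-like images per class (with ground-truth masks and
hair strokes) plus a 22,000-sample speech-like patient-information carrier,
and prints what was made. All outputs are deterministic in the seed.
"""

import numpy as np

import teledermo as td

samples = td.generate_class_set(n_per_class=3, seed=0)
print(f"{len(samples)} images, classes: {', '.join(td.CLASS_LABELS)}")
for s in samples[::3]:
    p = s.params
    print(f"  {s.class_label:22s} radius {p.lesion_radius:5.1f} px, "
          f"border irregularity {p.border_irregularity:.2f}, "
          f"texture contrast {p.texture_contrast:4.1f}, "
          f"mask area {s.truth_mask.sum()} px")

carrier = td.generate_rps(n_samples=22000, sample_rate=8000, seed=0)
print(f"\ncarrier: {carrier.size} samples at 8 kHz, "
      f"peak {np.abs(carrier).max():.3f}, mean {carrier.mean():+.1e} "
      "(zero-mean, unit-peak speech-like signal)")
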