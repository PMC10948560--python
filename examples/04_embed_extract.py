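"""Hide a profile collation in an audio carrier and get it back exactly.

Embeds 12 random profiles (block-diagonal layout) into a synthetic carrier
in each transform domain, measures how much the carrier is disturbed, and
verifies the clean-channel extraction is exact given the side information.
The non-unitary DST spreads the fixed-size payload over a much larger
coefficient scale, which is why its carrier SNR is ~40 dB higher.
"""

import numpy as np

import teledermo as td
from teledermo import metrics, profile, watermark

rng = np.random.default_rng(0)
dps = [profile.build_dp(rng.uniform(0.05, 0.95, 7), f"dp{k}")
       for k in range(12)]
dmpdp = profile.assemble(dps, "diagonal")
carrier = td.default_carrier(n_samples=22000, seed=1)

print("domain   carrier SNR (dB)   spectral distortion   max |P - P*|")
for domain in watermark.DOMAINS:
    cfg = watermark.EmbedConfig(domain=domain, alpha=0.01, beta=1.0)
    wm, side = watermark.embed(carrier, dmpdp, cfg)
    p_star, recovered = watermark.extract(wm, side)
    snr = metrics.snr(carrier.samples, wm.samples)
    sd = metrics.spectral_distortion(carrier.samples, wm.samples)
    err = np.abs(p_star - dmpdp.matrix).max()
    print(f"{domain:6s}   {snr:13.2f}      {sd:14.6f}       {err:.2e}")

print("\nextraction is exact (errors ~1e-12): the singular-value chain is "
      "an algebraic identity on a clean channel, and the carrier itself is "
      "recovered bit-near-perfectly at the receiver.")
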