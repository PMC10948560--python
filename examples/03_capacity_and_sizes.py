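"""Capacity and transmission-size arithmetic of the three payload layouts.

How many profiles fit into a 22,000-sample recorded signal, how many
carrier samples each layout consumes, and what the payload costs in bytes
compared with shipping the dermoscopy images themselves.
"""

from teledermo import profile

CARRIER = 22000

print(f"carrier: {CARRIER} samples")
print(f"diagonal-form capacity:    {profile.capacity('diagonal', CARRIER):4d} DPs"
      "   (floor(sqrt(22000)) = 148 samples per side, /7)")
print(f"sequential-form capacity:  {profile.capacity('sequential', CARRIER):4d} DPs"
      "   (4 class rows, 785 samples per column, /7)")
print(f"horizontal-form capacity:  {profile.capacity('horizontal', CARRIER, spacing=25):4d} DPs"
      "   (49 samples per DP + 25-sample spacing)")

print("\nsamples required:")
for n in (1, 4, 12, 248):
    seq = profile.required_samples("sequential", n, mode="paper")
    print(f"  {n:3d} DPs sequential (size rule L = 49 (N/2)^2): {seq:9,d}")
print(f"  12 DPs diagonal (L = 49 N^2):                 "
      f"{profile.required_samples('diagonal', 12):9,d}")

print("\ntransmission size:")
print(f"  one DP:  {profile.serialized_size(1)} bytes (49 values x 8 bytes)")
kb = profile.serialized_size(248) / 1000
print(f"  248 DPs: {kb:.1f} KB — less than one ~150 KB dermoscopy image, "
      "for 248 patients' profiles")
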