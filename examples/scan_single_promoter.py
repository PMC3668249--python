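"""Scan one synthetic promoter and read off its window profile.

Builds a 1000-nt promoter with a planted 80-nt poly(dA) tract, runs the
default 30-nt / step-1 sliding scan, and prints the profile summary.
"""

import numpy as np

from kicscan import KicConfig, SynthConfig, TractSpec, generate, sliding_scan

config = KicConfig()  # window 30, step 1, promoter-relative CG
record = generate(
    SynthConfig(length=1000, tracts=(TractSpec(motif="A", copies=80),), seed=11),
    record_id="demo",
)
profile = sliding_scan(record, config)

print(f"promoter length      : {len(record.sequence)} nt")
print(f"windows scanned      : {len(profile)}")
print(f"whole-promoter (C+G)%: {profile.cg_total:.2f}")
print(f"mean window KIC      : {np.mean(profile.kic):.2f}")
print(f"max window KIC       : {np.max(profile.kic):.2f}")
print(f"windows with KIC > 90: {int(np.sum(profile.kic > 90))}")

# The max-KIC windows sit inside the poly(dA) tract: a 30-nt homopolymer
# window scores 100*(29-1)/29 = 96.55, far above the ~24 random baseline,
# while the background windows hover near 24 — that contrast is the whole
# detection principle.
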