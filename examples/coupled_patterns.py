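"""Recover a known coupling from a synthetic point pattern.

Simulates 300 spots per channel in a 10 x 10 um window, with half of the
channel-2 spots placed 50 +/- 10 nm from a channel-1 partner, then runs
the ring-wise Ripley coupling analysis and prints what it recovers.
"""

import numpy as np

from sodamap import SimScenario, run_soda, simulate_patterns

sc = SimScenario(coupled_fraction=0.5, coupling_distance_nm=50.0,
                 jitter_sd_nm=10.0, seed=3)
mask, spots1, spots2, truth = simulate_patterns(sc)

profile, result = run_soda(spots1, spots2, mask, n_resamples=200, seed=1)

print(f"true coupled fraction      : {sc.coupled_fraction:.2f}")
print(f"recovered fraction (ch2)   : {result.coupling_fraction_ch2:.3f}")
print(f"true coupling distance     : {sc.coupling_distance_nm:.0f} nm")
print(f"recovered distance         : {result.mean_distance:.1f} "
      f"+/- {result.sd_distance:.1f} nm")
print(f"expected number of couples : {result.n_coupled:.1f} "
      f"(truth: {(truth.partner >= 0).sum()})")
print(f"global p-value             : {result.p_value:.2e}")
print()
print("Per-ring coupling probabilities (excess pair fraction over CSR):")
for k in range(profile.rings.n_rings):
    lo, hi = profile.rings.radii[k], profile.rings.radii[k + 1]
    flag = "*" if result.significant[k] else " "
    print(f"  ring {lo:3.0f}-{hi:3.0f} nm {flag} z={result.z[k]:7.2f}  "
          f"p_k={result.p_ring[k]:.3f}")
print()
print("Rings marked * beat the Sidak-corrected CSR threshold; their excess")
print("pair fraction p_k is the probability that a pair at that distance")
print("is a true couple, and the weighted mean of pair distances is the")
print("coupling distance estimate above.")
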