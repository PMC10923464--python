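"""Localization-table workflow (SMLM regime) with a thin neurite mask.

SMLM data arrive as coordinate tables, not images, so spot detection is
bypassed: localizations are points already.  The mask comes from an
external binary TIFF.  This example uses a dilated random-walk "neurite"
mask, where most points sit near the boundary and the isotropic edge
correction does real work.
"""

import tempfile
from pathlib import Path

from sodamap import (
    RingSpec,
    SimScenario,
    filter_spots_to_mask,
    read_localizations,
    read_mask_tiff,
    run_soda,
    simulate_batch,
)

workdir = Path(tempfile.mkdtemp(prefix="sodamap_smlm_"))
sc = SimScenario(shape=(200, 200), mask_shape="neurite", n1=800, n2=800,
                 coupled_fraction=0.3, coupling_distance_nm=40.0,
                 jitter_sd_nm=10.0, seed=5)
simulate_batch([sc], workdir)

mask = read_mask_tiff(workdir / "sim000_mask.tif", pixel_size=100.0)
sets = read_localizations(workdir / "sim000_locs.csv")
spots1 = filter_spots_to_mask(sets["1"], mask)
spots2 = filter_spots_to_mask(sets["2"], mask)

profile, result = run_soda(spots1, spots2, mask,
                           rings=RingSpec.uniform(30.0, 10),
                           n_resamples=100, seed=9)

print(f"mask area                  : {mask.measure / 1e6:.1f} um^2 (thin neurite)")
print(f"localizations              : N1={spots1.n}, N2={spots2.n}")
print(f"recovered fraction (ch2)   : {result.coupling_fraction_ch2:.3f} (0.3 true)")
print(f"recovered distance         : {result.mean_distance:.1f} nm (40 true)")
print(f"p-value                    : {result.p_value:.2e}")
print()
print("With localizations crowding a thin ~8 um^2 mask - the regime where")
print("overlap-based colocalization inflates - the ring-wise excess over")
print("the edge-corrected CSR expectation isolates the true coupling.")
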