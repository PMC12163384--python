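"""Inspect the purity/ploidy goodness-of-fit ("sunrise") surface.

The grid search inverts the mixture model on every candidate (rho, psi)
and measures how close the implied allele-specific copy numbers fall to
integers.  The surface minimum is the fit; a soft constraint from the
pathologist's tumor-content estimate down-ranks implausible purities.
"""

import numpy as np

import hrdscar as h

genome = h.load_genome("hg19")
truth, track = h.simulate_sample(genome, h.SimConfig(seed=11, rho=0.45, psi_base=2.0))
raw = h.segment_track(track)

fit = h.grid_search(raw, h.FitConfig(pathology_tumor_content=0.5))
print(f"true (rho, psi) = (0.45, 2.00); fitted = ({fit.rho:.2f}, {fit.psi:.2f})")
print(f"surface shape {fit.fit_surface.shape} over rho {fit.rho_grid[0]:.2f}-"
      f"{fit.rho_grid[-1]:.2f} x psi {fit.psi_grid[0]:.2f}-{fit.psi_grid[-1]:.2f}")

i, j = np.unravel_index(np.argmin(fit.fit_surface), fit.fit_surface.shape)
print(f"minimum value {fit.fit_surface[i, j]:.4f} at grid point "
      f"rho={fit.rho_grid[i]:.2f}, psi={fit.psi_grid[j]:.2f}")

# the manual path: a reviewer can pin the parameters instead
manual = h.PloidyFit.fixed(0.45, 2.0)
profile = h.fit_profile(raw, manual, genome)
print(f"profile under user-fixed (0.45, 2.0): {len(profile)} segments; "
      "copy-number states are rounded from the same inversion.")
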