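"""Simulate synthetic gut communities from a generalized Lotka-Volterra
ground truth: batch growth, serial passaging, and noisy observations.

Prints the endpoint abundances of a 5-member community and the staircase
effect of 20-fold daily dilution.
"""

import numpy as np

import micos

# a 10-species ground truth with predominantly competitive interactions
params = micos.generate_ground_truth(
    10, third_order="mild", seed=1,
    a_offdiag_mean=-0.15, a_offdiag_sd=0.25, a_diag_range=(-2.0, -1.0))

pool = micos.DEFAULT_POOL[:10]
design = micos.CommunityDesign.from_species(["PC", "BV", "BT", "DP", "BU"], pool)

# 48 h batch culture sampled every 8 h
table = micos.simulate_glv(params, design, times=np.arange(0, 49, 8.0))
print("endpoint abundances (OD) of", "+".join(design.species))
for sp, x in zip(pool, table.X[-1]):
    if x > 0:
        print(f"  {sp}: {x:.4f}")

# serial passaging: 20-fold dilution into fresh medium every 24 h
passaged = micos.simulate_with_passaging(params, design, horizon=72,
                                         sample_every=12)
print("\ntotal community OD under daily 20-fold passaging:")
for t, row in zip(passaged.times, passaged.X):
    print(f"  t={t:5.1f} h  total OD {row.sum():.4f}")
print("samples at 24/48 h show the pre-dilution state; the community "
      "regrows between passages.")

# noisy observation of the same trajectory (absent species stay exactly 0)
noisy = micos.add_observation_noise(table, sigma=0.1, seed=7)
cv = np.std(noisy.X[table.X > 0] / table.X[table.X > 0])
print(f"\nmultiplicative log-normal noise: empirical CV {cv:.3f} "
      "(sigma=0.1), zeros preserved:",
      bool(np.all(noisy.X[:, ~design.mask()] == 0)))
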