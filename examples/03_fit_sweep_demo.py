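"""Fit neutral and sweep models to one simulated 1 Mb region.

Simulates a linked (recombining) sequence carrying a strong completed
sweep at its centre, builds blocks, maximizes the composite likelihoods
and converts the fitted parameters back to biological quantities.
"""

import numpy as np

from fusesweep import (
    fit_neutral,
    fit_sweep,
    simulate_linked_blockset,
    strong_sweep_scenario,
    to_biological,
)

# s = 0.005 at N_e = 5e5, fixed 250,000 generations ago (T_a = 0.25)
scenario = strong_sweep_scenario()
print(f"truth: theta = 0.66, log10(alpha) = {np.log10(scenario.alpha):.2f}, "
      f"T_a = {scenario.T_a}")

blocks = simulate_linked_blockset(scenario, seed=7)
print(f"simulated {blocks.n_blocks} blocks x 4 subsets "
      f"= {blocks.n_observations} observations\n")

neutral = fit_neutral(blocks, neutral_m=50_000)
sweep = fit_sweep(blocks, phi_m=20_000)

print(f"neutral model:  theta = {neutral.params['theta_block']:.3f}, "
      f"ln CL = {neutral.lnCL:.1f}")
p = sweep.params
print(f"sweep model:    theta = {p['theta_block']:.3f}, "
      f"log10(alpha) = {p['log10_alpha']:.2f}, T_a = {p['T_a']:.3f}")
print(f"delta ln CL per block = {sweep.delta_lnCL_per_block:.4f} "
      "(0.002 is the neutral-calibration ceiling)\n")

bio = to_biological(sweep, mu=2.9e-9, r=2.9e-9,
                    block_length_l=blocks.block_length_l)
print(f"implied N_e = {bio.N_e:.3g}, s = {bio.s:.2e}, "
      f"2*N_e*s = {bio.two_Ne_s:.0f}")
print(f"sweep completed ~{bio.T_generations:,.0f} generations ago")
print("\nA per-block gain this large, with a localized footprint")
print("(log10 alpha < -4), is what the scan classifies as a sweep; the")
print("neutral simulations never exceed 0.002 per block.")
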