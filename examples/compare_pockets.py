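"""Compare two binding pockets by their molecular interaction fields.

Builds a synthetic mixed-chemistry pocket, makes a structurally noisy copy
(0.8 A coordinate jitter, the scale of a modest conformational change),
and compares the two in a shared frame: per-probe Tanimoto on the
contoured H (shape), CRY (lipophilic), N1 (donor) and O (acceptor) fields,
combined into the Global-Sum score.
"""

import pocketmif as pm

params = pm.load_params()
config = pm.RunConfig(spacing=0.8, padding=2.5, cutoff=8.0)

structure, pocket = pm.make_toy_pocket(pm.FixtureSpec(seed=1, n_residues=10))
noisy = pm.perturb(structure, sigma=0.8, seed=7)

result = pm.compare_pockets(structure, pocket, noisy, pocket,
                            config=config, params=params)

print("per-probe Tanimoto similarity (1.0 = identical hotspots):")
for name, value in result.per_probe.items():
    print(f"  {name:>3s}  {value:.3f}   (contour {result.thresholds[name]:+.2f} kcal/mol)")
print(f"Global-Sum score: {result.global_sum:.3f}")
print()
print("The shape channel (H) degrades slowest under jitter because the"
      " steric envelope is broad; the tightly localised donor/acceptor"
      " hotspots (N1, O) are the most sensitive to geometry.")
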