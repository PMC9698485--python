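"""Predict and score a water network in a pocket.

Waters are placed greedily on the water-probe (OH2) field, each becoming
part of the receptor for the next; every water is scored by combining its
standalone enthalpy (OH2s), in-network enthalpy (OH2n), lipophilicity of
its site (CRY) and an entropy penalty (ENTR) into DG_WAT, a relative
free energy against bulk water, then classified happy / bulk-like /
unhappy / very-unhappy.
"""

import pocketmif as pm

params = pm.load_params()
structure, pocket = pm.make_toy_pocket(pm.FixtureSpec(seed=1, n_residues=12))

network = pm.place_waters(structure, pocket, params=params, spacing=0.6)

print(f"placed {len(network)} waters "
      f"(placement cutoff {network.config.e_place} kcal/mol on OH2s)")
print(f"{'#':>2s} {'OH2s':>7s} {'OH2n':>7s} {'CRY':>6s} {'ENTR':>5s} "
      f"{'DG_WAT':>7s}  class")
for s in network.sites:
    print(f"{s.order_placed:2d} {s.oh2s:7.2f} {s.oh2n:7.2f} {s.cry:6.2f} "
          f"{s.entr:5.2f} {s.dg_wat:7.2f}  {s.label}")
print()
print("Negative DG_WAT marks structural waters (displacing them costs"
      " binding energy); positive values mark waters happier in bulk"
      " solvent, i.e. displacement targets for ligand design.")
print()
print("PDB output (B-factor column carries DG_WAT):")
print(network.to_pdb(), end="")
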