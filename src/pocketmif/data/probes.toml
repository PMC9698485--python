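# Probe and atom parameters for the GRID-like empirical interaction model.
#
# Energy model (kcal/mol):
#   E = E_LJ + E_el + E_hb, clamped at +5 kcal/mol
#   E_LJ = eps_mix * [ (rmin_mix/r)^12 - 2 (rmin_mix/r)^6 ]
#          eps_mix  = sqrt(eps_probe * eps_atom)   (geometric)
#          rmin_mix = rmin_half_probe + rmin_half_atom  (arithmetic)
#   E_el = 332.0636 * q_probe * q_atom / (4 r^2)   (distance-dependent dielectric 4r)
#   E_hb = hbond_emax * [ 5 (d0/r)^12 - 6 (d0/r)^10 ] * cos^2(theta)
#          only between complementary donor/acceptor partners; d0 = 2.9 A
#
# Probe semantics: H maps pocket shape (steric only), CRY hydrophobic/lipophilic
# surfaces (LJ only, 25% epsilon against polar atoms), N1 is an H-bond donor
# probe (scores protein acceptors), O an H-bond acceptor probe (scores protein
# donors), OH2 a water probe (donor + acceptor).

[model]
hbond_d0 = 2.9            # A, H-bond radial optimum
coulomb_constant = 332.0636  # kcal*A/(mol*e^2)
dielectric_slope = 4.0    # eps(r) = dielectric_slope * r
clamp = 5.0               # kcal/mol positive clamp
cutoff = 8.0              # A, default pair cutoff
spacing = 0.5             # A, default grid spacing
padding = 3.0             # A, default grid padding
mask_shell = 3.0          # A added to vdw radius for the pocket envelope mask

[probes.H]
rmin_half = 1.2
eps = 0.02
charge = 0.0
hbond_role = "none"
hbond_emax = 0.0
contour = 0.10            # kcal/mol, shape contour

[probes.CRY]
rmin_half = 1.9
eps = 0.60
charge = 0.0
hbond_role = "none"
hbond_emax = 0.0
polar_eps_scale = 0.25    # reduced dispersion against polar-class atoms
contour = -0.6

[probes.N1]
rmin_half = 1.65
eps = 0.16
charge = 0.2
hbond_role = "donor"
hbond_emax = -6.0
contour = -4.5

[probes.O]
rmin_half = 1.7
eps = 0.20
charge = -0.2
hbond_role = "acceptor"
hbond_emax = -5.0
contour = -3.5

[probes.OH2]
rmin_half = 1.7
eps = 0.21
charge = 0.0
hbond_role = "both"
hbond_emax = -5.0
contour = -5.0

# Per-element Lennard-Jones parameters for protein heavy atoms
# (extended-atom model: hydrogens are implicit).
[elements.C]
rmin_half = 1.9
eps = 0.12
[elements.N]
rmin_half = 1.8
eps = 0.16
[elements.O]
rmin_half = 1.7
eps = 0.18
[elements.S]
rmin_half = 2.0
eps = 0.25
[elements.P]
rmin_half = 2.0
eps = 0.20
[elements.default]
rmin_half = 1.8
eps = 0.15

# Formal-charge model: only titratable termini carry net charge.
[charges]
cation = 0.5
anion = -0.5
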